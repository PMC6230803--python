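"""Cluster templates and nearest-centroid assignment of unclassified spikes.

Each final cluster is summarized by its centroid (mean waveform) and a total
spread sigma_T = sqrt(sum_i var(x_i)) over the waveform samples. Spikes that
did not take part in clustering (the subsample overflow, events from discarded
partitions, or events SPC left unlinked) are assigned to the nearest centroid
in raw waveform space, provided that distance is below 3 sigma_T of that
cluster; otherwise they remain unassigned (label 0, noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import SpikeSet
from .features import FeatureSelection

__all__ = ["Template", "SortResult", "compute_templates", "assign_unclassified"]


@dataclass
class Template:
    cluster_id: int
    centroid: np.ndarray
    sigma_t: float
    n_members: int
    origin: tuple[int, int] | None = None  # (temperature index, rank) provenance

    @property
    def degenerate(self) -> bool:
        """Singleton clusters have sigma_t = 0 and cannot gate by 3 sigma_T."""
        return self.n_members < 2 or self.sigma_t == 0.0


@dataclass
class SortResult:
    """Final sorter output: per-event labels (0 = unassigned/noise) + templates."""

    labels: np.ndarray
    templates: list[Template] = field(default_factory=list)
    selection: FeatureSelection | None = None
    t_border: int | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.templates)

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def compute_templates(
    s: SpikeSet,
    labels: np.ndarray,
    origins: dict[int, tuple[int, int]] | None = None,
) -> list[Template]:
    """Centroid and sigma_T per nonzero label.

    sigma_T uses the unbiased (n-1) per-sample variance summed over all
    waveform samples (64 per channel). Singleton clusters get sigma_t = 0 and
    are flagged via ``Template.degenerate``.
    """
    labels = np.asarray(labels)
    templates = []
    for cid in np.unique(labels[labels > 0]):
        w = s.waveforms[labels == cid]
        centroid = w.mean(axis=0)
        sigma_t = (float(np.sqrt(w.var(axis=0, ddof=1).sum()))
                   if w.shape[0] >= 2 else 0.0)
        templates.append(Template(
            cluster_id=int(cid), centroid=centroid, sigma_t=sigma_t,
            n_members=w.shape[0],
            origin=None if origins is None else origins.get(int(cid)),
        ))
    return templates


def assign_unclassified(
    s: SpikeSet,
    labels: np.ndarray,
    templates: list[Template],
    radius_multiplier: float = 3.0,
) -> SortResult:
    """Template matching of every label-0 spike.

    A spike goes to the cluster whose centroid is nearest in Euclidean
    distance over the raw concatenated waveform, if that distance is below
    ``radius_multiplier`` * sigma_T of that cluster; otherwise it stays 0.
    Already-labelled spikes are never touched. Distance ties go to the lowest
    cluster id (argmin convention). Deterministic and order-independent.
    """
    if not templates:
        raise ValueError("need at least one template")
    labels = np.asarray(labels).copy()
    unassigned = np.flatnonzero(labels == 0)
    if unassigned.size:
        order = sorted(templates, key=lambda t: t.cluster_id)
        centroids = np.vstack([t.centroid for t in order])
        radii = np.array([radius_multiplier * t.sigma_t for t in order])
        d = np.linalg.norm(
            s.waveforms[unassigned][:, None, :] - centroids[None, :, :], axis=2
        )
        best = np.argmin(d, axis=1)
        ok = d[np.arange(best.size), best] < radii[best]
        ids = np.array([t.cluster_id for t in order])
        labels[unassigned[ok]] = ids[best[ok]]
    return SortResult(labels=labels, templates=templates)
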