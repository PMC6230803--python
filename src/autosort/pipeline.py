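"""One-call orchestration of the full sorting chain.

filter -> detect -> realign -> Haar features -> Lilliefors knee selection ->
SPC over the temperature grid -> regime border / peak selection / inclusion
criterion -> templates -> nearest-centroid assignment of everything left over.

When more spikes are detected than ``subsample_cap`` (default 20,000), feature
screening and SPC run on a seeded uniform subsample; the overflow is assigned
afterwards by template matching, which keeps the Monte Carlo cost bounded
without sacrificing the large-sample events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from time import perf_counter

import numpy as np

from .detect import DetectionParams, Recording, SpikeSet, bandpass_filter, \
    detect_spikes, estimate_threshold, realign_spikes
from .features import FeatureSelection, feature_matrix, haar_decompose, \
    lilliefors_stat, select_coefficients
from .selection import SelectionParams, labels_from_clusters, select_clusters
from .spc import SPCParams, TemperatureMap, build_interaction_graph, run_spc
from .templates import SortResult, compute_templates, assign_unclassified

__all__ = ["PipelineConfig", "PipelineOutput", "run_pipeline", "sort_spikes",
           "stage_seed"]

log = logging.getLogger("autosort")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (stable across runs and platforms)."""
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF,
                                 int.from_bytes(stage.encode(), "little") & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    spc: SPCParams = field(default_factory=SPCParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    feature_mode: str = "variable"   # variable | fixed10 | all
    subsample_cap: int = 20000
    seed: int = 0


@dataclass
class PipelineOutput:
    """Sort result plus every intermediate needed to audit the run."""

    spikes: SpikeSet
    result: SortResult
    selection: FeatureSelection | None = None
    temperature_map: TemperatureMap | None = None
    t_border: int | None = None
    thresholds: np.ndarray | None = None
    clustered_indices: np.ndarray | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.result.labels


def _empty_output(spikes: SpikeSet, thresholds: np.ndarray) -> PipelineOutput:
    result = SortResult(labels=np.zeros(spikes.n_events, dtype=np.int64),
                        templates=[])
    return PipelineOutput(spikes=spikes, result=result, thresholds=thresholds)


def run_pipeline(rec: Recording, cfg: PipelineConfig | None = None) -> PipelineOutput:
    """Run the full automatic sorter on a continuous recording."""
    cfg = cfg or PipelineConfig()
    filtered = bandpass_filter(rec, cfg.detection)
    thresholds = np.array([
        estimate_threshold(ch, cfg.detection.thr_multiplier) for ch in filtered.data
    ])
    spikes = detect_spikes(filtered, cfg.detection, thresholds)
    log.info("detected %d spikes (thresholds %s)", spikes.n_events,
             np.round(thresholds, 4))
    if spikes.n_events == 0:
        return _empty_output(spikes, thresholds)
    spikes = realign_spikes(spikes, cfg.detection)
    out = sort_spikes(spikes, cfg)
    out.thresholds = thresholds
    return out


def sort_spikes(spikes: SpikeSet, cfg: PipelineConfig | None = None) -> PipelineOutput:
    """Sort an already-detected, aligned spike set (features onward).

    Entry point for pre-detected waveform matrices; ``run_pipeline`` delegates
    here after detection.
    """
    cfg = cfg or PipelineConfig()
    t0 = perf_counter()
    thresholds = None
    n = spikes.n_events
    if n == 0:
        return _empty_output(spikes, thresholds)
    if n > cfg.subsample_cap:
        rng = np.random.default_rng(stage_seed(cfg.seed, "subsample"))
        sub = np.sort(rng.choice(n, size=cfg.subsample_cap, replace=False))
    else:
        sub = np.arange(n)

    coeffs = haar_decompose(spikes)
    ks = np.array([lilliefors_stat(coeffs[sub, j]) for j in range(coeffs.shape[1])])
    order = np.argsort(ks, kind="stable")
    if cfg.feature_mode == "variable":
        try:
            sel = select_coefficients(ks, n_channels=spikes.n_channels)
        except ValueError:
            log.warning("no informative features; nothing to cluster")
            return _empty_output(spikes, thresholds)
    elif cfg.feature_mode == "fixed10":
        k = min(10 * spikes.n_channels, ks.size)
        sel = FeatureSelection(ks_stat=ks, sorted_order=order, knee_index=-1,
                               selected=np.sort(order[-k:]).astype(np.int64))
    elif cfg.feature_mode == "all":
        sel = FeatureSelection(ks_stat=ks, sorted_order=order, knee_index=-1,
                               selected=np.arange(ks.size, dtype=np.int64))
    else:
        raise ValueError(f"unknown feature mode {cfg.feature_mode!r}")
    log.info("selected %d/%d wavelet coefficients (knee index %d)",
             sel.n_selected, ks.size, sel.knee_index)

    feats = feature_matrix(coeffs[sub], sel)
    if sub.size < cfg.spc.knn + 1:
        log.warning("too few spikes (%d) for SPC; all left unassigned", sub.size)
        return _empty_output(spikes, thresholds)

    spc_params = SPCParams(**{**cfg.spc.__dict__,
                              "seed": stage_seed(cfg.seed, "cluster")})
    graph = build_interaction_graph(feats, spc_params)
    tmap = run_spc(graph, spc_params)
    clusters, t_b = select_clusters(tmap, cfg.selection)
    log.info("T_B at temperature index %d; %d clusters survive overlap resolution",
             t_b, len(clusters))

    labels = np.zeros(n, dtype=np.int64)
    labels[sub] = labels_from_clusters(clusters, sub.size)
    origins = {k: (c.t_index, c.rank) for k, c in enumerate(clusters, start=1)}

    if not clusters:
        result = SortResult(labels=labels, templates=[])
    else:
        templates = compute_templates(spikes, labels, origins)
        result = assign_unclassified(spikes, labels, templates)
    result.selection = sel
    result.t_border = t_b
    log.info("done in %.1f s: %d clusters, sizes %s", perf_counter() - t0,
             result.n_clusters, result.cluster_sizes())
    return PipelineOutput(
        spikes=spikes, result=result, selection=sel, temperature_map=tmap,
        t_border=t_b, thresholds=thresholds, clustered_indices=sub,
    )
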