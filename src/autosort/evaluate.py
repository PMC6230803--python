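"""Scoring of sorter output against simulation ground truth.

Detected events are matched to true spikes by time (+-1 ms by default, greedy
nearest-first, one-to-one). Each cluster is then attributed to the source
contributing the plurality of its spikes. A cluster is a *hit* for unit u when
more than half of its spikes are true spikes of u and no larger cluster
already claimed u; clusters that are not hits are *false positives*, except
clusters whose spikes are at least half multiunit, which are ignored (they
reflect genuinely unresolvable background units, not sorter errors). Misses
are simulated units without a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GroundTruth

__all__ = ["EvalReport", "match_events", "score_solution"]

MULTIUNIT = -1
UNMATCHED = -2


@dataclass
class EvalReport:
    hits: int
    false_positives: int
    misses: int
    n_units: int
    table: pd.DataFrame = field(repr=False, default=None)
    cluster_to_unit: dict[int, int] = field(default_factory=dict)

    @property
    def total_errors(self) -> int:
        return self.misses + self.false_positives


def match_events(
    event_times: np.ndarray,
    gt_times: np.ndarray,
    fs: float,
    tol_ms: float = 1.0,
) -> np.ndarray:
    """One-to-one greedy matching of detected events to ground-truth spikes.

    Returns, per event, the index of the matched ground-truth spike or -1.
    Events are processed in order of increasing distance to their nearest
    available true spike, so each true spike is claimed by its closest event.
    """
    event_times = np.asarray(event_times, dtype=np.int64)
    gt_times = np.asarray(gt_times, dtype=np.int64)
    tol = int(round(tol_ms * 1e-3 * fs))
    match = np.full(event_times.size, -1, dtype=np.int64)
    if event_times.size == 0 or gt_times.size == 0:
        return match
    gt_order = np.argsort(gt_times, kind="stable")
    gt_sorted = gt_times[gt_order]
    # candidate pairs within tolerance
    pos = np.searchsorted(gt_sorted, event_times)
    cands = []
    for e, p in enumerate(pos):
        for g in (p - 1, p, p + 1):
            if 0 <= g < gt_sorted.size:
                dt = abs(int(event_times[e]) - int(gt_sorted[g]))
                if dt <= tol:
                    cands.append((dt, e, g))
    used_gt = np.zeros(gt_sorted.size, dtype=bool)
    for dt, e, g in sorted(cands):
        if match[e] == -1 and not used_gt[g]:
            match[e] = gt_order[g]
            used_gt[g] = True
    return match


def score_solution(
    labels: np.ndarray,
    event_times: np.ndarray,
    gt: GroundTruth,
    tol_ms: float = 1.0,
    hit_threshold: float = 0.5,
) -> EvalReport:
    """Hit / false-positive / miss counts plus a per-cluster purity table.

    ``hit_threshold`` is the fraction of a cluster's spikes that must come
    from a single unit for a hit (default 0.5, i.e. ">50%"; alternative 0.7
    or 0.8 gives qualitatively similar scores). Invariant under relabeling of
    clusters or units.
    """
    labels = np.asarray(labels)
    event_times = np.asarray(event_times)
    matched = match_events(event_times, gt.times, gt.fs, tol_ms)
    sources = np.where(matched >= 0, gt.units[np.clip(matched, 0, None)], UNMATCHED)

    rows = []
    cluster_ids = np.unique(labels[labels > 0])
    comp: dict[int, tuple[int, float, float, int]] = {}
    for cid in cluster_ids:
        src = sources[labels == cid]
        size = src.size
        vals, counts = np.unique(src, return_counts=True)
        best = int(vals[np.argmax(counts)])
        best_frac = counts.max() / size
        mu_frac = float((src == MULTIUNIT).sum() / size)
        # the dominant *unit* (ignoring multiunit/unmatched) decides hits
        unit_mask = vals >= 0
        if unit_mask.any():
            u_counts = counts[unit_mask]
            u_vals = vals[unit_mask]
            top_unit = int(u_vals[np.argmax(u_counts)])
            top_unit_frac = float(u_counts.max() / size)
        else:
            top_unit, top_unit_frac = -1, 0.0
        comp[int(cid)] = (size, top_unit, top_unit_frac, mu_frac, best, best_frac)

    hits = 0
    fps = 0
    claimed: set[int] = set()
    cluster_to_unit: dict[int, int] = {}
    # larger clusters claim units first so duplicates cannot double-count
    for cid in sorted(comp, key=lambda c: -comp[c][0]):
        size, top_unit, top_unit_frac, mu_frac, _, _ = comp[cid]
        if top_unit >= 0 and top_unit_frac > hit_threshold and top_unit not in claimed:
            hits += 1
            claimed.add(top_unit)
            cluster_to_unit[cid] = top_unit
            outcome = "hit"
        elif mu_frac >= 0.5:
            outcome = "multiunit"  # neither hit nor false positive
        else:
            fps += 1
            outcome = "false_positive"
        rows.append({
            "cluster": cid, "size": size, "outcome": outcome,
            "top_unit": top_unit if top_unit >= 0 else None,
            "top_unit_fraction": top_unit_frac,
            "multiunit_fraction": mu_frac,
        })

    table = pd.DataFrame(rows, columns=["cluster", "size", "outcome", "top_unit",
                                        "top_unit_fraction", "multiunit_fraction"])
    return EvalReport(
        hits=hits,
        false_positives=fps,
        misses=gt.n_units - hits,
        n_units=gt.n_units,
        table=table,
        cluster_to_unit=cluster_to_unit,
    )
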