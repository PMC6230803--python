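"""Automatic cluster selection from the SPC temperature map.

Three heuristics mimic what an expert does on a temperature plot:

1. *Regime border*: find the lowest temperature T_B where the principal
   cluster shatters beyond what a new relevant cluster can explain, and
   discard every partition at T >= T_B (the paramagnetic/overclustered zone).
2. *Peak selection*: at every surviving temperature, a cluster whose size
   grows by at least N_inc spikes relative to the same rank at the previous
   temperature registers as a peak; it is selected together with every larger
   cluster at that temperature.
3. *Inclusion criterion*: the same physical cluster appears at several
   temperatures; candidate pairs with overlap coefficient
   |A n B| / min(|A|, |B|) at or above k_O are deduplicated keeping the
   higher-temperature (more refined) member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spc import TemperatureMap

__all__ = [
    "SelectionParams",
    "CandidateCluster",
    "detect_regime_border",
    "select_peaks",
    "overlap_coefficient",
    "resolve_overlaps",
    "select_clusters",
    "labels_from_clusters",
]


@dataclass
class SelectionParams:
    n_inc: int = 20          # minimum spike increment for a peak
    thr_border: float = 0.4  # regime-border ratio threshold
    k_o: float = 0.9         # overlap cutoff of the inclusion criterion

    def __post_init__(self) -> None:
        if self.n_inc < 1:
            raise ValueError("n_inc must be >= 1")
        if not 0.0 < self.thr_border < 1.0:
            raise ValueError("thr_border must be in (0, 1)")
        if not 0.0 < self.k_o <= 1.0:
            raise ValueError("k_o must be in (0, 1]")


@dataclass(frozen=True)
class CandidateCluster:
    """A cluster C_rank^{T_i} pulled from the temperature map."""

    t_index: int
    rank: int  # 1-based size rank at its temperature
    members: frozenset

    @property
    def size(self) -> int:
        return len(self.members)


def detect_regime_border(tm: TemperatureMap, p: SelectionParams | None = None) -> int:
    """Index of the superparamagnetic regime border T_B.

    T_B is the smallest i >= 1 with
    (|C_1^{T_i}| + LI^{T_i}) / |C_1^{T_{i-1}}| < thr_border, where LI^{T_i} is
    the largest size increment among non-principal ranks (j > 1, missing ranks
    counting as size 0, negative increments as 0). When the condition never
    holds, the border is one past the last temperature and nothing is
    discarded.
    """
    p = p or SelectionParams()
    if tm.n_temperatures == 0:
        raise ValueError("empty temperature map")
    for i in range(1, tm.n_temperatures):
        prev_c1 = tm.size_of(i - 1, 1)
        if prev_c1 == 0:
            continue
        max_rank = max(len(tm.sizes[i]), len(tm.sizes[i - 1]))
        li = 0
        for j in range(2, max_rank + 1):
            li = max(li, tm.size_of(i, j) - tm.size_of(i - 1, j))
        if (tm.size_of(i, 1) + li) / prev_c1 < p.thr_border:
            return i
    return tm.n_temperatures


def select_peaks(
    tm: TemperatureMap,
    p: SelectionParams | None = None,
    t_b: int | None = None,
) -> list[CandidateCluster]:
    """Clusters that grow by at least N_inc, plus all larger ones at that T.

    Sizes are compared rank against rank between consecutive temperatures,
    with every size at the virtual temperature before T_0 being 0. Only
    temperatures strictly below the regime border are scanned. Duplicate
    selections within one temperature are collapsed.
    """
    p = p or SelectionParams()
    if t_b is None:
        t_b = detect_regime_border(tm, p)
    out: list[CandidateCluster] = []
    for n in range(min(t_b, tm.n_temperatures)):
        n_ranks = len(tm.sizes[n])
        max_peak_rank = 0
        for i in range(1, n_ranks + 1):
            prev = tm.size_of(n - 1, i) if n > 0 else 0
            if tm.size_of(n, i) - prev >= p.n_inc:
                max_peak_rank = max(max_peak_rank, i)
        for i in range(1, max_peak_rank + 1):
            out.append(CandidateCluster(
                t_index=n, rank=i, members=frozenset(tm.members(n, i).tolist()),
            ))
    return out


def overlap_coefficient(a, b) -> float:
    """|A n B| / min(|A|, |B|): 1 when one set contains the other, 0 when disjoint."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap coefficient of an empty set is undefined")
    return len(sa & sb) / min(len(sa), len(sb))


def resolve_overlaps(
    candidates: list[CandidateCluster],
    p: SelectionParams | None = None,
) -> list[CandidateCluster]:
    """Deduplicate candidates across temperatures (inclusion criterion).

    Temperatures are walked from high to low; a candidate survives only if its
    overlap coefficient against every already-kept candidate from a strictly
    higher temperature stays below k_O. The surviving list is returned sorted
    by size descending (final cluster numbering order). The result does not
    depend on the input order.
    """
    p = p or SelectionParams()
    kept: list[CandidateCluster] = []
    for cand in sorted(candidates, key=lambda c: (-c.t_index, c.rank)):
        drop = False
        for other in kept:
            if other.t_index <= cand.t_index:
                continue
            if overlap_coefficient(cand.members, other.members) >= p.k_o:
                drop = True
                break
        if not drop:
            kept.append(cand)
    return sorted(kept, key=lambda c: (-c.size, c.t_index, c.rank))


def select_clusters(
    tm: TemperatureMap,
    p: SelectionParams | None = None,
) -> tuple[list[CandidateCluster], int]:
    """Full selection chain: border detection, peak selection, deduplication.

    Returns the final clusters (size-descending) and the border index T_B.
    """
    p = p or SelectionParams()
    t_b = detect_regime_border(tm, p)
    peaks = select_peaks(tm, p, t_b)
    return resolve_overlaps(peaks, p), t_b


def labels_from_clusters(clusters: list[CandidateCluster], n_events: int) -> np.ndarray:
    """Per-event labels 1..K (0 = unassigned).

    When surviving clusters from different temperatures share events, the
    highest-temperature (most refined) cluster wins the shared events.
    """
    labels = np.zeros(n_events, dtype=np.int64)
    best_t = np.full(n_events, -1, dtype=np.int64)
    for k, c in enumerate(clusters, start=1):
        idx = np.fromiter(c.members, dtype=np.int64)
        take = c.t_index > best_t[idx]
        labels[idx[take]] = k
        best_t[idx[take]] = c.t_index
    return labels
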