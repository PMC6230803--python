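"""Haar wavelet feature extraction and unsupervised coefficient selection.

Each 64-sample waveform block is decomposed with a four-scale orthonormal Haar
multiresolution transform (periodized, so exactly 64 coefficients per channel
block result). Coefficients whose distribution across spikes deviates from
normality carry cluster structure: deviation is quantified per coefficient with
the Lilliefors statistic (a Kolmogorov-Smirnov statistic against a normal
distribution with estimated mean and SD), and the number of coefficients kept
is chosen automatically at the "knee" of the ascending sorted statistic curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.stats import norm

from .detect import SpikeSet

__all__ = [
    "FeatureSelection",
    "haar_decompose",
    "lilliefors_stat",
    "select_coefficients",
    "feature_matrix",
    "extract_features",
]

HAAR_LEVELS = 4
KNEE_SPAN = 10          # sliding-window span of the derivative estimate
KNEE_RUN = 3            # consecutive samples with estimate > 1
FALLBACK_PER_CHANNEL = 10  # fixed coefficient count when no knee exists


@dataclass
class FeatureSelection:
    """Outcome of the automatic coefficient-selection step.

    ``ks_stat`` holds one Lilliefors statistic per wavelet coefficient;
    ``sorted_order`` sorts them ascending; ``knee_index`` is the 0-based
    position of the detected knee in the sorted sequence (-1 when the
    fixed-count fallback was used); ``selected`` are the chosen coefficient
    indices, i.e. those with ks_stat strictly above the knee value.
    """

    ks_stat: np.ndarray
    sorted_order: np.ndarray
    knee_index: int
    selected: np.ndarray

    @property
    def n_selected(self) -> int:
        return self.selected.size

    @property
    def knee_value(self) -> float:
        if self.knee_index < 0:
            return float("nan")
        return float(self.ks_stat[self.sorted_order[self.knee_index]])


def _haar_matrix(n: int, levels: int) -> np.ndarray:
    """Orthonormal periodized Haar analysis matrix (oracle-friendly, explicit)."""
    w = pywt.Wavelet("haar")
    eye = np.eye(n)
    rows = []
    for basis in eye:
        coeffs = pywt.wavedec(basis, w, level=levels, mode="periodization")
        rows.append(np.concatenate(coeffs))
    return np.asarray(rows).T  # analysis: c = H @ x


def haar_decompose(s: SpikeSet | np.ndarray) -> np.ndarray:
    """Four-scale Haar coefficients per spike, 64 per channel block.

    Returns an (n_events, 64 * n_channels) array: for each channel block the
    coefficients are ordered approximation-first (a4, d4, d3, d2, d1), and
    blocks are concatenated in channel order. The periodized orthonormal
    transform preserves energy exactly.
    """
    if isinstance(s, SpikeSet):
        waveforms = s.waveforms
    else:
        waveforms = np.atleast_2d(np.asarray(s, dtype=np.float64))
    if waveforms.shape[1] % 64 != 0:
        raise ValueError("per-channel waveform block length must be 64")
    n_blocks = waveforms.shape[1] // 64
    out = np.empty_like(waveforms)
    for b in range(n_blocks):
        block = waveforms[:, b * 64:(b + 1) * 64]
        coeffs = pywt.wavedec(block, "haar", level=HAAR_LEVELS,
                              mode="periodization", axis=1)
        out[:, b * 64:(b + 1) * 64] = np.concatenate(coeffs, axis=1)
    return out


def lilliefors_stat(values: np.ndarray, min_retained: int = 10) -> float:
    """Lilliefors normality statistic of one coefficient across spikes.

    Values outside mean +- 3 SD are removed once (a single trimming pass with
    the plain sample SD) to limit the influence of outliers. The statistic is
    the sup distance between the empirical CDF of the retained values and the
    normal CDF with their sample mean and SD (ddof=1). Degenerate columns
    (fewer than ``min_retained`` values retained, or zero variance) return 0:
    they carry no cluster information.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < min_retained:
        return 0.0
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0
    mu = x.mean()
    x = x[np.abs(x - mu) <= 3.0 * sd]
    if x.size < min_retained:
        return 0.0
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0
    xs = np.sort(x)
    f = norm.cdf((xs - x.mean()) / sd)
    n = xs.size
    i = np.arange(1, n + 1)
    return float(max((i / n - f).max(), (f - (i - 1) / n).max()))


def select_coefficients(ks_stat: np.ndarray, n_channels: int = 1) -> FeatureSelection:
    """Choose the clustering coefficients at the knee of the sorted statistics.

    The ks_stat values are sorted ascending into s(1..M). A smoothed first
    derivative is estimated by the difference quotient over a 10-sample
    sliding window, d(j) = [s(j+9) - s(j)] / 10, normalized by M / max(s).
    The knee is the first j where d exceeds 1 for three consecutive samples;
    all coefficients with ks_stat strictly above s(knee) are selected. When no
    knee exists (the sequence has no super-linear rise) the selection falls
    back to the 10 largest statistics per channel, the former fixed-count
    behaviour.
    """
    ks = np.asarray(ks_stat, dtype=np.float64).ravel()
    m = ks.size
    if m < KNEE_SPAN + KNEE_RUN:
        raise ValueError(f"need at least {KNEE_SPAN + KNEE_RUN} coefficients")
    if not np.any(ks > 0):
        raise ValueError("no informative features: all ks_stat are zero")
    order = np.argsort(ks, kind="stable")
    s = ks[order]
    d = (s[KNEE_SPAN - 1:] - s[:m - KNEE_SPAN + 1]) / KNEE_SPAN * m / s[-1]
    above = d > 1.0
    knee = -1
    for j in range(d.size - KNEE_RUN + 1):
        if above[j:j + KNEE_RUN].all():
            knee = j
            break
    if knee >= 0:
        selected = np.flatnonzero(ks > s[knee])
        if selected.size == 0:  # knee at the very top: nothing strictly above
            knee = -1
    if knee < 0:
        k = min(FALLBACK_PER_CHANNEL * n_channels, m)
        selected = np.sort(order[-k:])
    return FeatureSelection(
        ks_stat=ks, sorted_order=order, knee_index=knee,
        selected=np.asarray(selected, dtype=np.int64),
    )


def feature_matrix(coefficients: np.ndarray, selection: FeatureSelection) -> np.ndarray:
    """Events x selected-coefficients matrix used for clustering."""
    return np.ascontiguousarray(coefficients[:, selection.selected])


def extract_features(
    s: SpikeSet,
    mode: str = "variable",
) -> tuple[np.ndarray, FeatureSelection]:
    """Full feature chain: Haar coefficients, Lilliefors screening, selection.

    mode "variable" uses the knee criterion; "fixed10" keeps the 10 (per
    channel) largest-statistic coefficients; "all" keeps every coefficient.
    Returns (feature matrix, FeatureSelection).
    """
    coeffs = haar_decompose(s)
    ks = np.array([lilliefors_stat(coeffs[:, j]) for j in range(coeffs.shape[1])])
    order = np.argsort(ks, kind="stable")
    if mode == "variable":
        sel = select_coefficients(ks, n_channels=s.n_channels)
    elif mode == "fixed10":
        k = min(FALLBACK_PER_CHANNEL * s.n_channels, ks.size)
        sel = FeatureSelection(ks_stat=ks, sorted_order=order, knee_index=-1,
                               selected=np.sort(order[-k:]).astype(np.int64))
    elif mode == "all":
        sel = FeatureSelection(ks_stat=ks, sorted_order=order, knee_index=-1,
                               selected=np.arange(ks.size, dtype=np.int64))
    else:
        raise ValueError(f"unknown feature mode {mode!r}")
    return feature_matrix(coeffs, sel), sel
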