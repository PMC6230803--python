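"""Ground-truthed synthetic extracellular recordings.

A recording is the superposition of (i) spike trains of a few single units,
each a fixed template with peak amplitude normalized to 1, fired at Poisson
times (exponential inter-spike intervals, 2 ms absolute refractory floor),
(ii) an optional multiunit layer of low-amplitude spikes (peak 0.4-0.6, the
unresolvable neurons 50-150 um from the tip), and (iii) background noise
built as a dense train of tiny spike shapes band-passed to the detection band
and rescaled to exactly the requested SD, mimicking the spectral footprint of
distant neural activity rather than white noise.

Templates come from a parametric bank of biphasic/triphasic shapes (main
depolarization lobe + after-hyperpolarization, optional leading lobe) so any
number of distinct units can be drawn reproducibly from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionParams, Recording, bandpass_filter

__all__ = ["SimConfig", "GroundTruth", "template_bank", "make_template",
           "simulate_recording"]

REFRACTORY_S = 0.002  # absolute refractory floor between spikes of one unit
_W_PRE, _W_POST = 19, 44  # template window layout, peak on sample 20 (1-based)

#: (main rise ms, main decay ms, ahp amp, ahp delay ms, ahp width ms,
#:  pre amp, pre delay ms, pre width ms, late amp, late delay ms,
#:  late width ms, sign). The eight fixed shapes span fast/broad biphasic,
#: triphasic, deep-AHP and slow-overshoot waveforms of both polarities, with
#: pairwise L2 distance >= 1.7 between peak-normalized templates.
_BANK_PARAMS: list[tuple] = [
    (0.10, 0.14, 0.70, 0.30, 0.30, 0.0, 0.0, 0.0, 0.00, 0.0, 0.0, +1),
    (0.30, 0.55, 0.20, 1.30, 0.80, 0.0, 0.0, 0.0, 0.00, 0.0, 0.0, +1),
    (0.12, 0.18, 0.45, 0.40, 0.35, 0.45, 0.30, 0.15, 0.00, 0.0, 0.0, -1),
    (0.18, 0.25, 0.60, 0.80, 0.90, 0.0, 0.0, 0.0, 0.25, 1.8, 0.6, +1),
    (0.22, 0.30, 0.90, 0.35, 0.25, 0.0, 0.0, 0.0, 0.00, 0.0, 0.0, -1),
    (0.45, 0.70, 0.35, 1.00, 0.50, 0.20, 0.55, 0.30, 0.00, 0.0, 0.0, -1),
    (0.14, 0.20, 0.30, 0.60, 0.45, 0.0, 0.0, 0.0, 0.45, 1.4, 1.0, -1),
    (0.25, 0.35, 0.85, 0.45, 0.30, 0.50, 0.35, 0.18, 0.00, 0.0, 0.0, +1),
]


def _agauss(t: np.ndarray, center: float, w_left: float, w_right: float) -> np.ndarray:
    """Asymmetric Gaussian lobe (different rise and decay time constants)."""
    w = np.where(t < center, w_left, w_right)
    return np.exp(-((t - center) / w) ** 2)


def make_template(
    fs: float,
    main_rise_ms: float = 0.15,
    main_decay_ms: float = 0.25,
    ahp_amplitude: float = 0.45,
    ahp_delay_ms: float = 0.55,
    ahp_width_ms: float = 0.45,
    pre_amplitude: float = 0.0,
    pre_delay_ms: float = 0.3,
    pre_width_ms: float = 0.15,
    late_amplitude: float = 0.0,
    late_delay_ms: float = 1.5,
    late_width_ms: float = 0.8,
    sign: int = 1,
) -> np.ndarray:
    """One 64-sample spike template, peak amplitude 1 at sample index 19.

    The shape is an asymmetric depolarization lobe with an opposite-sign
    after-hyperpolarization, an optional leading lobe (triphasic waveforms)
    and an optional slow late overshoot. ``sign`` flips the whole waveform
    for negative-going spikes.
    """
    t_ms = (np.arange(-_W_PRE, _W_POST + 1) / fs) * 1e3
    w = _agauss(t_ms, 0.0, main_rise_ms, main_decay_ms)
    w -= ahp_amplitude * _agauss(t_ms, ahp_delay_ms,
                                 0.7 * ahp_width_ms, 1.3 * ahp_width_ms)
    if pre_amplitude:
        w -= pre_amplitude * _agauss(t_ms, -pre_delay_ms, pre_width_ms, pre_width_ms)
    if late_amplitude:
        w += late_amplitude * _agauss(t_ms, late_delay_ms, late_width_ms, late_width_ms)
    w = sign * w / np.abs(w).max()
    return w


def _random_shape_params(rng: np.random.Generator) -> tuple:
    rise = rng.uniform(0.08, 0.45)
    return (
        rise,
        rise * rng.uniform(1.2, 1.9),
        rng.uniform(0.15, 0.9),
        rng.uniform(0.3, 1.3),
        rng.uniform(0.25, 0.9),
        0.0 if rng.random() < 0.5 else rng.uniform(0.15, 0.5),
        rng.uniform(0.25, 0.6),
        rng.uniform(0.12, 0.3),
        0.0 if rng.random() < 0.6 else rng.uniform(0.2, 0.45),
        rng.uniform(1.2, 2.0),
        rng.uniform(0.5, 1.0),
        1 if rng.random() < 0.5 else -1,
    )


def _similar_shape_params(rng: np.random.Generator) -> tuple:
    """Realistic-library regime: canonical negative biphasic spikes that differ
    only in subtle width/AHP details, like average waveforms of real neurons."""
    rise = rng.uniform(0.10, 0.18)
    return (
        rise,
        rise * rng.uniform(1.3, 1.7),
        rng.uniform(0.35, 0.60),
        rng.uniform(0.45, 0.80),
        rng.uniform(0.35, 0.60),
        0.0,
        0.3,
        0.15,
        0.0 if rng.random() < 0.5 else rng.uniform(0.05, 0.15),
        rng.uniform(1.4, 1.8),
        rng.uniform(0.6, 0.9),
        -1,
    )


def template_bank(fs: float, n: int, rng: np.random.Generator | None = None,
                  min_distance: float = 0.9, style: str = "diverse") -> np.ndarray:
    """``n`` distinct 64-sample templates (peak 1 at index 19).

    ``style="diverse"``: the first eight are the fixed parametric bank;
    beyond that, new shapes are drawn from broad parameter ranges with
    ``rng`` (required for n > 8). This emulates easily separable units with
    very different waveforms. ``style="similar"``: all shapes are canonical
    negative biphasic spikes differing only in width/AHP details (the
    realistic-library regime, where units are hard to tell apart); here a
    smaller ``min_distance`` (0.25) applies. Draws closer than the minimum
    distance (L2 between peak-normalized shapes) to any shape already in the
    bank are rejected so every unit stays separable in principle.
    """
    if style == "diverse":
        shapes = [make_template(fs, *p)
                  for p in _BANK_PARAMS[:min(n, len(_BANK_PARAMS))]]
        draw = _random_shape_params
    elif style == "similar":
        shapes = []
        draw = _similar_shape_params
        min_distance = min(min_distance, 0.25)
    else:
        raise ValueError(f"unknown template style {style!r}")
    while len(shapes) < n:
        if rng is None:
            raise ValueError("rng required for randomly drawn templates")
        for _ in range(100):
            cand = make_template(fs, *draw(rng))
            if all(np.linalg.norm(cand - s) >= min_distance for s in shapes):
                break
        shapes.append(cand)  # accept the last draw if rejection keeps failing
    return np.vstack(shapes)


@dataclass
class SimConfig:
    n_units: int = 3
    noise_sd: float = 0.1
    rate_hz: float = 3.0
    duration_s: float = 60.0
    fs: float = 24000.0
    n_channels: int = 1
    multiunit_fraction: float = 0.0
    multiunit_amplitude: tuple[float, float] = (0.4, 0.6)
    noise_event_rate_hz: float = 20000.0  # density of the background spike train
    jitter: bool = False                 # sub-sample spike-time jitter
    template_style: str = "diverse"      # "diverse" (easy) | "similar" (hard)
    seed: int = 0
    templates: np.ndarray | None = None  # user-supplied (n_units, 64) bank

    def __post_init__(self) -> None:
        if not 1 <= self.n_units <= 20:
            raise ValueError("n_units must be in 1..20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_channels not in (1, 4):
            raise ValueError("1 (single electrode) or 4 (tetrode) channels")
        if not 0.0 <= self.multiunit_fraction < 1.0:
            raise ValueError("multiunit_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """True spike times (alignment samples), source units and multiunit flags."""

    times: np.ndarray        # sample index of each true spike peak
    units: np.ndarray        # unit id (0..n_units-1); -1 for multiunit events
    n_units: int
    fs: float
    templates: np.ndarray = field(repr=False, default=None)
    channel_gains: np.ndarray | None = field(repr=False, default=None)

    @property
    def is_multiunit(self) -> np.ndarray:
        return self.units < 0

    @property
    def times_s(self) -> np.ndarray:
        return self.times / self.fs

    def unit_times(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]


def _poisson_train(rng, rate_hz: float, duration_s: float,
                   refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Spike times (s) with exponential ISIs and an absolute refractory floor."""
    if rate_hz <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate_hz
    free = max(mean_isi - refractory_s, 1e-4)
    n_guess = int(duration_s * rate_hz * 2 + 50)
    isis = refractory_s + rng.exponential(free, size=n_guess)
    t = np.cumsum(isis)
    while t.size and t[-1] < duration_s:
        extra = refractory_s + rng.exponential(free, size=n_guess)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < duration_s]


def _insert(trace: np.ndarray, template: np.ndarray, samples: np.ndarray,
            gains: np.ndarray, amplitudes: np.ndarray | None = None) -> None:
    """Add ``template`` (scaled per channel) at every alignment sample in place."""
    n = trace.shape[1]
    for k, t in enumerate(samples):
        lo, hi = t - _W_PRE, t + _W_POST + 1
        if lo < 0 or hi > n:
            continue
        amp = 1.0 if amplitudes is None else amplitudes[k]
        for ch in range(trace.shape[0]):
            trace[ch, lo:hi] += gains[ch] * amp * template


def _jittered(template: np.ndarray, frac: float) -> np.ndarray:
    """Template shifted by a sub-sample fraction via FFT-free cubic resampling."""
    from scipy.interpolate import CubicSpline
    grid = np.arange(template.size, dtype=float)
    return CubicSpline(grid, template)(np.clip(grid + frac, 0, template.size - 1))


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate one reproducible recording plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    trace = np.zeros((cfg.n_channels, n_samples))

    if cfg.templates is not None:
        bank = np.atleast_2d(np.asarray(cfg.templates, dtype=float))
        if bank.shape != (cfg.n_units, 64):
            raise ValueError("templates must have shape (n_units, 64)")
    else:
        bank = template_bank(cfg.fs, cfg.n_units, rng, style=cfg.template_style)

    if cfg.n_channels > 1:
        gains = rng.uniform(0.2, 1.0, size=(cfg.n_units, cfg.n_channels))
        # each unit is strongest on one channel so it stays detectable
        lead = rng.integers(cfg.n_channels, size=cfg.n_units)
        gains[np.arange(cfg.n_units), lead] = 1.0
    else:
        gains = np.ones((cfg.n_units, 1))

    all_times, all_units = [], []
    margin_lo, margin_hi = _W_PRE, n_samples - _W_POST - 1
    for u in range(cfg.n_units):
        t_s = _poisson_train(rng, cfg.rate_hz, cfg.duration_s)
        samples = np.round(t_s * cfg.fs).astype(np.int64)
        samples = samples[(samples >= margin_lo) & (samples <= margin_hi)]
        if cfg.jitter:
            for t in samples:
                frac = rng.uniform(-0.5, 0.5)
                _insert(trace, _jittered(bank[u], frac), np.array([t]), gains[u])
        else:
            _insert(trace, bank[u], samples, gains[u])
        all_times.append(samples)
        all_units.append(np.full(samples.size, u, dtype=np.int64))

    # multiunit layer: low-amplitude spikes from extra shapes
    if cfg.multiunit_fraction > 0:
        f = cfg.multiunit_fraction
        mu_rate = f / (1.0 - f) * cfg.n_units * cfg.rate_hz
        if mu_rate > 200.0:
            raise ValueError("multiunit_fraction infeasible for the given rates")
        mu_bank = template_bank(cfg.fs, min(4, len(_BANK_PARAMS)))
        t_s = _poisson_train(rng, mu_rate, cfg.duration_s, refractory_s=0.0)
        samples = np.round(t_s * cfg.fs).astype(np.int64)
        samples = samples[(samples >= margin_lo) & (samples <= margin_hi)]
        amps = rng.uniform(*cfg.multiunit_amplitude, size=samples.size)
        mu_gain = np.ones(cfg.n_channels)
        for k, t in enumerate(samples):
            shape = mu_bank[rng.integers(mu_bank.shape[0])]
            _insert(trace, shape, np.array([t]), mu_gain,
                    amplitudes=np.array([amps[k]]))
        all_times.append(samples)
        all_units.append(np.full(samples.size, -1, dtype=np.int64))

    # background noise: dense low-amplitude spike train, band-passed, rescaled
    if cfg.noise_sd > 0:
        noise = np.zeros_like(trace)
        noise_bank = template_bank(cfg.fs, len(_BANK_PARAMS))
        for ch in range(cfg.n_channels):
            acc = np.zeros(n_samples)
            for shape in noise_bank:
                n_ev = rng.poisson(cfg.noise_event_rate_hz / noise_bank.shape[0]
                                   * cfg.duration_s)
                pos = rng.integers(_W_PRE, n_samples - _W_POST - 1, size=n_ev)
                amps = rng.uniform(-1.0, 1.0, size=n_ev)
                impulses = np.zeros(n_samples)
                np.add.at(impulses, pos, amps)
                acc += np.convolve(impulses, shape, mode="same")
            noise[ch] = acc
        noise = bandpass_filter(Recording(noise, cfg.fs), DetectionParams()).data
        for ch in range(cfg.n_channels):
            noise[ch] *= cfg.noise_sd / noise[ch].std()
        trace = trace + noise

    times = np.concatenate(all_times) if all_times else np.empty(0, np.int64)
    units = np.concatenate(all_units) if all_units else np.empty(0, np.int64)
    order = np.argsort(times, kind="stable")
    gt = GroundTruth(times=times[order], units=units[order],
                     n_units=cfg.n_units, fs=cfg.fs, templates=bank,
                     channel_gains=gains if cfg.n_channels > 1 else None)
    return Recording(trace, cfg.fs), gt
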