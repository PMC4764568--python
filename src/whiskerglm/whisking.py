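"""Free-whisking analyses: amplitude/phase decomposition and tuning.

Rhythmic whisking occupies the 6-30 Hz band.  Band-pass filtering the
whisker angle and taking the Hilbert transform yields the instantaneous
whisking amplitude (envelope, degrees) and phase (radians, zero at maximum
protraction of the band-passed angle, by convention).  Firing-rate tuning
to amplitude, phase or angular acceleration is summarised with
equi-populated bins — quantile bins whose occupancies differ by at most
one sample — so every point of a tuning curve rests on the same amount of
data.

Sensitivity tests follow the shuffle/regression recipes used for primary
whisker afferents: a regression-slope t-test for amplitude tuning, a
circular-shift null distribution for phase tuning, and a rectified
two-sided regression for acceleration tuning that allows asymmetric
responses to positive and negative acceleration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "WhiskingState",
    "TuningCurve",
    "AccelRegression",
    "decompose_whisking",
    "equi_populated_tuning",
    "amplitude_sensitivity",
    "phase_tuning_test",
    "acceleration_regression",
]


@dataclass
class WhiskingState:
    """Instantaneous whisking amplitude (deg) and phase (radians, (-pi, pi])."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must be aligned")


@dataclass
class TuningCurve:
    """Equi-populated tuning curve: mean rate (spikes/s) +/- SEM per bin."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_rate: np.ndarray
    sem: np.ndarray
    n: np.ndarray


@dataclass
class AccelRegression:
    """Rectified acceleration-regression fit and the resulting unit class.

    Fits r_i = mu0 + mu1*g(a_i) + mu2*Delta_i*g(a_i) with Delta_i = 1 for
    a_i < 0, where g(a) = |a| by default.  Classes: 'negative_pref' when
    mu2 is significantly positive, 'positive_pref' when significantly
    negative, 'no_preferred_direction' when mu1 is significantly positive
    with mu2 indistinguishable from zero, otherwise 'not_sensitive'.
    """

    mu0: float
    mu1: float
    mu2: float
    p_mu1: float
    p_mu2: float
    classification: str


def decompose_whisking(angle_series, band=(6.0, 30.0), fs_hz: float = 1000.0,
                       order: int = 3, trial_bounds=None) -> WhiskingState:
    """Band-pass (zero-phase) + analytic-signal amplitude/phase decomposition.

    Filtering and the Hilbert transform are applied per trial so that no
    transient crosses a trial boundary; each segment must exceed the
    forward-backward filter's padding length.
    """
    x = np.asarray(angle_series, dtype=float)
    bounds = trial_bounds if trial_bounds is not None else [(0, x.shape[0])]
    sos = butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    padlen = 6 * (order + 1)  # sosfiltfilt default padding for this sos shape
    amp = np.empty_like(x)
    phase = np.empty_like(x)
    for start, stop in bounds:
        if stop - start <= padlen:
            raise ValueError(f"segment [{start},{stop}) shorter than filter transient")
        seg = sosfiltfilt(sos, x[start:stop])
        analytic = hilbert(seg)
        amp[start:stop] = np.abs(analytic)
        ph = np.angle(analytic)
        ph[ph == -np.pi] = np.pi
        phase[start:stop] = ph
    return WhiskingState(amplitude=amp, phase=phase)


def equi_populated_tuning(variable_series, spikes, n_bins: int,
                          fs_hz: float = 1000.0) -> TuningCurve:
    """Tuning curve over quantile (equi-populated) bins of a variable.

    Bin occupancies differ by at most one sample by construction (samples
    are rank-split).  Heavy ties that straddle a bin boundary make the
    nominal edges degenerate; this is flagged with a warning.
    """
    v = np.asarray(variable_series, dtype=float)
    n = np.asarray(getattr(spikes, "counts", spikes), dtype=float)
    if v.shape != n.shape:
        raise ValueError("variable and spikes must be aligned")
    if v.shape[0] < n_bins:
        raise ValueError("fewer samples than bins")
    order = np.argsort(v, kind="stable")
    splits = np.array_split(order, n_bins)
    edges = [v[splits[0]].min()] + [v[s].max() for s in splits]
    if len(set(np.round(edges, 12))) < len(edges):
        warnings.warn("massive ties: quantile bin edges are degenerate",
                      RuntimeWarning, stacklevel=2)
    centers, rate, sem, counts = [], [], [], []
    for s in splits:
        centers.append(v[s].mean())
        rate.append(n[s].mean() * fs_hz)
        sem.append(n[s].std(ddof=1) / np.sqrt(s.size) * fs_hz if s.size > 1 else 0.0)
        counts.append(s.size)
    return TuningCurve(
        bin_edges=np.asarray(edges), bin_centers=np.asarray(centers),
        mean_rate=np.asarray(rate), sem=np.asarray(sem), n=np.asarray(counts),
    )


def _wls_pvalues(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares with a guard for (near-)perfect fits.

    When the residual variance vanishes the usual t statistics are 0/0;
    coefficients numerically distinct from zero are then treated as
    infinitely significant (p=0) and the rest as non-significant (p=1).
    """
    res = sm.WLS(y, X, weights=w).fit()
    params = np.asarray(res.params, dtype=float)
    scale_y = max(float(np.std(y)), 1e-300)
    if res.mse_resid < (1e-10 * scale_y) ** 2 + 1e-300:
        pvals = np.where(np.abs(params) > 1e-8 * scale_y, 0.0, 1.0)
        return params, pvals
    pvals = np.asarray(res.pvalues, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return params, pvals


def amplitude_sensitivity(tuning_curve: TuningCurve, p: float = 0.0025):
    """Slope of a regression line through the amplitude tuning curve.

    Returns ``(slope, p_value, significant)``.  The regression is weighted
    by per-bin sample counts and the slope is t-tested against zero at the
    (Bonferroni-corrected) threshold ``p``.
    """
    if tuning_curve.bin_centers.size < 3:
        raise ValueError("need at least 3 bins for a slope test")
    X = sm.add_constant(tuning_curve.bin_centers)
    params, pvals = _wls_pvalues(X, tuning_curve.mean_rate, tuning_curve.n)
    return float(params[1]), float(pvals[1]), bool(pvals[1] < p)


def phase_tuning_test(
    state: WhiskingState,
    spikes,
    amp_threshold: float = 2.0,
    n_bins: int = 8,
    n_shuffles: int = 500,
    shift_range_ms=(3000, 8000),
    seed=None,
    fs_hz: float = 1000.0,
):
    """Shuffle test for phase tuning during high-amplitude whisking.

    Bins with whisking amplitude below ``amp_threshold`` are excluded; the
    remaining phases are discretised into equi-populated bins and the
    tuning-curve maximum compared with the 95th percentile of maxima
    obtained after circularly shifting the spike train by random
    3000-8000 ms offsets.  Returns a dict with the observed maximum, the
    null 95th percentile, the tuning curve and the significance flag.
    """
    n = np.asarray(getattr(spikes, "counts", spikes), dtype=float)
    if n.shape != state.phase.shape:
        raise ValueError("spikes must be aligned with the whisking state")
    lo, hi = int(shift_range_ms[0]), int(shift_range_ms[1])
    if lo <= 0 or hi < lo:
        raise ValueError("shift range must be positive and ordered")
    if n.shape[0] <= hi:
        raise ValueError("recording shorter than the maximum shift")
    mask = state.amplitude >= amp_threshold
    if mask.sum() < n_bins * 2:
        raise ValueError("insufficient supra-threshold bins for phase tuning")
    curve = equi_populated_tuning(state.phase[mask], n[mask], n_bins, fs_hz)
    observed = float(curve.mean_rate.max())
    # the phase->bin assignment is fixed; only the spikes are shifted, so the
    # null maxima reduce to per-shift bincounts of shifted spikes
    order = np.argsort(state.phase[mask], kind="stable")
    bin_id_masked = np.empty(mask.sum(), dtype=np.int64)
    for b, s in enumerate(np.array_split(order, n_bins)):
        bin_id_masked[s] = b
    occupancy = np.bincount(bin_id_masked, minlength=n_bins)
    masked_idx = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shift = int(rng.integers(lo, hi + 1))
        shifted = n[(masked_idx - shift) % n.shape[0]]
        counts = np.bincount(bin_id_masked, weights=shifted, minlength=n_bins)
        maxima[i] = (counts / occupancy).max() * fs_hz
    # order-statistic quantile: exactly valid for a discrete permutation null
    # (linear interpolation between atoms would over-reject slightly)
    null95 = float(np.percentile(maxima, 95, method="higher"))
    return {
        "max_rate": observed,
        "null_95": null95,
        "significant": observed > null95,
        "curve": curve,
        "null_maxima": maxima,
    }


def acceleration_regression(tuning_curve: TuningCurve, p: float = 0.05,
                            form: str = "rectified") -> AccelRegression:
    """Two-sided acceleration regression and direction classification.

    ``form="rectified"`` (default) regresses the rate on g(a) = |a| and
    Delta*g(a), which makes the three canonical selectivity classes
    (positive-only, negative-only, direction-blind rectifier) map cleanly
    onto the signs of mu1 and mu2.  ``form="printed"`` uses g(a) = a.
    """
    a = tuning_curve.bin_centers
    if not (np.any(a < 0) and np.any(a > 0)):
        raise ValueError("acceleration tuning curve must span both signs")
    g = np.abs(a) if form == "rectified" else a
    if form not in ("rectified", "printed"):
        raise ValueError(f"unknown form {form!r}")
    delta = (a < 0).astype(float)
    X = np.column_stack([np.ones_like(a), g, delta * g])
    params, pvals = _wls_pvalues(X, tuning_curve.mean_rate, tuning_curve.n)
    mu0, mu1, mu2 = params
    sig1, sig2 = pvals[1] < p, pvals[2] < p
    if sig2 and mu2 > 0:
        label = "negative_pref"
    elif sig2 and mu2 < 0:
        label = "positive_pref"
    elif sig1 and mu1 > 0 and not sig2:
        label = "no_preferred_direction"
    else:
        label = "not_sensitive"
    return AccelRegression(
        mu0=float(mu0), mu1=float(mu1), mu2=float(mu2),
        p_mu1=float(pvals[1]), p_mu2=float(pvals[2]), classification=label,
    )
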