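"""Single-trial spike-prediction scoring.

Prediction accuracy of an encoding model is measured without any trial
averaging: trials are split at random into a training and a testing half,
the model is fitted on the training trials, a spike train is sampled from
it on the testing trials, both recorded and predicted trains are smoothed
with a box-car (100 ms by default), and the Pearson correlation coefficient
(PCC) is computed over the concatenated test set.  The whole procedure is
repeated for 10 random splits and the median PCC reported.

Chance level is estimated by circularly shifting the recorded spike train
by a random 3000-8000 ms (breaking the stimulus-response alignment while
preserving the firing rate exactly) and re-running the full fit/evaluate
procedure.  A unit is called sensitive to a feature when its actual PCCs
beat the chance PCCs in a signed-rank test at the Bonferroni-corrected
threshold (p = 0.0025 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import glm as _glm
from .glm import GLMConfig

__all__ = [
    "EvalResult",
    "split_trials",
    "smooth_boxcar",
    "pcc",
    "cross_validated_pcc",
    "chance_pcc",
    "significance",
    "evaluate_unit",
    "episode_rates",
    "cross_correlation",
]


@dataclass
class EvalResult:
    """Outcome of the cross-validated prediction-accuracy procedure."""

    pcc_per_repeat: np.ndarray
    median_pcc: float
    chance_pccs: np.ndarray = field(default_factory=lambda: np.array([]))
    significant: bool | None = None
    p_value: float | None = None
    smoothing_ms: int = 100
    seed: int | None = None
    subseeds: list = field(default_factory=list)

    def report(self) -> str:
        lines = [
            f"median PCC           {self.median_pcc: .4f}",
            f"per-repeat PCCs      {np.array2string(np.asarray(self.pcc_per_repeat), precision=3)}",
        ]
        if self.chance_pccs.size:
            lines.append(
                f"chance median PCC    {np.median(self.chance_pccs): .4f}"
            )
            lines.append(f"significant          {self.significant} (p={self.p_value:.4g})")
        lines.append(f"smoothing            {self.smoothing_ms} ms")
        return "\n".join(lines)


def split_trials(n_trials: int, fraction: float = 0.5, seed=None):
    """Random disjoint, exhaustive train/test split of trial indices."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    n_train = int(round(n_trials * fraction))
    n_train = min(max(n_train, 1), n_trials - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def smooth_boxcar(series, width_ms: int = 100, trial_bounds=None, fs_hz: float = 1000.0):
    """Moving average with a box-car of ``width_ms``, applied within trials only.

    Within a trial the value at bin t is the mean of the samples under the
    kernel, normalised by the actual kernel overlap at the trial edges, so
    a constant series is unchanged and the mean is preserved; for signals
    supported away from the edges the sum is preserved too.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(width_ms * fs_hz / 1000.0))
    if w < 1:
        raise ValueError("width must be >= 1 ms")
    kernel = np.ones(w)
    bounds = trial_bounds if trial_bounds is not None else [(0, x.shape[0])]
    out = x.copy()  # bins outside the given bounds pass through unsmoothed
    for start, stop in bounds:
        if stop - start < w:
            raise ValueError("smoothing width exceeds trial length")
        seg = x[start:stop]
        overlap = np.convolve(np.ones_like(seg), kernel, mode="same")
        out[start:stop] = np.convolve(seg, kernel, mode="same") / overlap
    return out


def pcc(a, b) -> float:
    """Pearson correlation coefficient between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _subset_bounds(trial_bounds, idx):
    return [trial_bounds[i] for i in idx]


def _eval_mask(trial_bounds, margin: int, n_bins: int) -> np.ndarray:
    """Global-bin mask excluding the first ``margin`` bins of each trial."""
    mask = np.zeros(n_bins, dtype=bool)
    for start, stop in trial_bounds:
        mask[start + margin : stop] = True
    return mask


def _one_repeat(session, counts, features, config, smoothing_ms, rng,
                bin_mask=None, n_pred_samples=1):
    """Fit on a random half of trials, sample a prediction on the other half,
    and score the smoothed trains with the PCC over the concatenated test set."""
    train_idx, test_idx = split_trials(session.n_trials, 0.5, rng)
    train_bounds = _subset_bounds(session.trial_bounds, train_idx)
    test_bounds = _subset_bounds(session.trial_bounds, test_idx)
    design = _glm.build_design(features, counts, train_bounds, config)
    model = _glm.fit(design)
    preds = []
    for _ in range(n_pred_samples):
        _, pred = _glm.predict(model, features, test_bounds,
                               mode="sampled", seed=int(rng.integers(2**31)))
        preds.append(pred.astype(float))
    margin = max(config.L_k, config.L_h)
    mask = _eval_mask(test_bounds, margin, counts.shape[0])
    if bin_mask is not None:
        mask &= np.asarray(bin_mask, dtype=bool)
    rec_s = smooth_boxcar(counts.astype(float), smoothing_ms, test_bounds)
    pred_s = smooth_boxcar(np.mean(preds, axis=0), smoothing_ms, test_bounds)
    return pcc(rec_s[mask], pred_s[mask]), model


def cross_validated_pcc(
    session,
    spikes,
    features="curvature_change",
    config: GLMConfig = None,
    n_repeats: int = 10,
    smoothing_ms: int = 100,
    seed=None,
    bin_mask=None,
    n_pred_samples: int = 1,
) -> EvalResult:
    """Cross-validated single-trial prediction accuracy of a GLM.

    ``features`` may be a session feature name, an aligned array, or a list
    of either (multi-stimulus model).  ``bin_mask`` optionally restricts
    the PCC to a subset of bins (e.g. touch-only or non-touch-only
    episodes); fitting always uses all valid training bins.
    ``n_pred_samples`` sampled trains are averaged before smoothing
    (default one, the single-trial convention).  One master seed expands
    into per-repeat sub-seeds, recorded in the result for replay.
    """
    config = config or GLMConfig()
    counts = np.asarray(getattr(spikes, "counts", spikes))
    feats = _resolve_features(session, features)
    master = np.random.default_rng(seed)
    subseeds = [int(master.integers(2**31)) for _ in range(n_repeats)]
    pccs = []
    for i, s in enumerate(subseeds):
        try:
            r, _ = _one_repeat(session, counts, feats, config, smoothing_ms,
                               np.random.default_rng(s), bin_mask, n_pred_samples)
        except _glm.DegenerateFitError as exc:
            raise RuntimeError(f"fit failed on repeat {i}: {exc}") from exc
        pccs.append(r)
    pccs = np.array(pccs)
    return EvalResult(
        pcc_per_repeat=pccs, median_pcc=float(np.median(pccs)),
        smoothing_ms=smoothing_ms, seed=_int_or_none(seed), subseeds=subseeds,
    )


def chance_pcc(
    session,
    spikes,
    features="curvature_change",
    config: GLMConfig = None,
    n: int = 10,
    shift_range_ms=(3000, 8000),
    smoothing_ms: int = 100,
    seed=None,
) -> np.ndarray:
    """Chance-level PCCs from circularly time-shifted spike trains.

    Each of the ``n`` draws shifts the whole spike sequence circularly by a
    uniform amount in ``shift_range_ms`` (rate exactly preserved) and runs
    one full fit/evaluate repeat on a fresh train/test split.
    """
    config = config or GLMConfig()
    counts = np.asarray(getattr(spikes, "counts", spikes))
    lo, hi = int(shift_range_ms[0]), int(shift_range_ms[1])
    if lo <= 0 or hi < lo:
        raise ValueError("shift range must be positive and ordered")
    if counts.shape[0] <= hi:
        raise ValueError("recording shorter than the maximum shift")
    feats = _resolve_features(session, features)
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        shift = int(master.integers(lo, hi + 1))
        shifted = np.roll(counts, shift)
        r, _ = _one_repeat(session, shifted, feats, config, smoothing_ms, master)
        out.append(r)
    return np.array(out)


def significance(actual_pccs, chance_pccs, p: float = 0.0025):
    """Signed-rank comparison of paired actual vs chance PCCs.

    Returns ``(significant, p_value)``.  The default threshold is the
    Bonferroni-corrected 0.05/20.  Identical pairs (no signal at all) are
    never significant.
    """
    a = np.asarray(actual_pccs, dtype=float)
    c = np.asarray(chance_pccs, dtype=float)
    if a.shape != c.shape:
        raise ValueError("actual and chance sets must have equal size")
    d = a - c
    if np.allclose(d, 0):
        return False, 1.0
    stat = stats.wilcoxon(a, c, zero_method="wilcox", method="auto")
    return bool(stat.pvalue < p), float(stat.pvalue)


def evaluate_unit(
    session,
    spikes,
    features="curvature_change",
    config: GLMConfig = None,
    n_repeats: int = 10,
    n_chance: int = None,
    smoothing_ms: int = 100,
    shift_range_ms=(3000, 8000),
    p: float = 0.0025,
    seed=None,
) -> EvalResult:
    """Full per-unit battery: CV PCCs, chance PCCs and the significance flag.

    ``n_chance`` defaults to ``n_repeats`` since the signed-rank comparison
    pairs the two sets.
    """
    if n_chance is None:
        n_chance = n_repeats
    master = np.random.default_rng(seed)
    res = cross_validated_pcc(
        session, spikes, features, config, n_repeats, smoothing_ms,
        seed=int(master.integers(2**31)),
    )
    res.chance_pccs = chance_pcc(
        session, spikes, features, config, n_chance, shift_range_ms,
        smoothing_ms, seed=int(master.integers(2**31)),
    )
    res.significant, res.p_value = significance(res.pcc_per_repeat, res.chance_pccs, p)
    res.seed = _int_or_none(seed)
    return res


def episode_rates(spikes, touch_labels, fs_hz: float = 1000.0):
    """Mean firing rate (spikes/s) during touch and non-touch episodes.

    ``spikes`` may be a binary train or a predicted-probability series
    (expected rates).  Raises if either class is empty.
    """
    x = np.asarray(getattr(spikes, "counts", spikes), dtype=float)
    touch = np.asarray(touch_labels).astype(bool)
    if x.shape != touch.shape:
        raise ValueError("labels must be aligned with the spike series")
    if touch.all() or not touch.any():
        raise ValueError("both touch and non-touch episodes required")
    return float(x[touch].mean() * fs_hz), float(x[~touch].mean() * fs_hz)


def cross_correlation(a, b, max_lag_ms: int, fs_hz: float = 1000.0):
    """Pearson correlation of ``a`` against ``b`` shifted by each integer lag.

    Returns ``(lags_ms, corr)`` for lags in [-max_lag, +max_lag]; the value
    at positive lag L is corr(a_t, b_{t+L}), so a copy of ``a`` delayed by
    d ms peaks at lag +d.  Each lag is a plain Pearson correlation over the
    overlapping samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    L = int(round(max_lag_ms * fs_hz / 1000.0))
    lags = np.arange(-L, L + 1)
    out = np.empty(lags.shape[0])
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: a.shape[0] - lag] if lag else a, b[lag:]
        else:
            x, y = a[-lag:], b[:lag]
        out[i] = pcc(x, y)
    return lags, out


def _resolve_features(session, features):
    if isinstance(features, str):
        return [session.feature(features)]
    if isinstance(features, (list, tuple)):
        return [session.feature(f) if isinstance(f, str) else np.asarray(f, float)
                for f in features]
    return [np.asarray(features, dtype=float)]


def _int_or_none(seed):
    return int(seed) if isinstance(seed, (int, np.integer)) else None
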