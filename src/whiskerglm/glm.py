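"""Bernoulli point-process GLM for spike-train encoding.

The model: in each 1 ms bin t the spike count n_t in {0, 1} is Bernoulli
with probability

    y_t = f( sum_i k_i . x_t(i) + h . n_(<t) + b ),    f(z) = 1/(1 + e^-z)

where each k_i is a stimulus filter applied to the recent history of sensory
input i (the window *includes* bin t: x_{t-Lk+1}..x_t), h is a spike-history
filter applied to the Lh bins strictly before t (so prediction is causal),
and b is a bias setting the spontaneous rate.  Fitting minimises the
Bernoulli negative log-likelihood plus a ridge penalty alpha*||k||^2 on the
stimulus filters only; the problem is convex, so a gradient-based optimiser
with the exact analytic gradient finds the global optimum.

A quadratic variant appends the squared (z-scored) stimulus history to the
design, capturing U-shaped tuning such as responses to angular acceleration
of either sign.

Histories never cross trial boundaries: the first max(Lk, Lh) bins of every
trial are masked out of the likelihood, and during spike generation /
sampled prediction the missing history at a trial start is zero-padded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "GLMConfig",
    "GLMModel",
    "DesignData",
    "DegenerateFitError",
    "build_design",
    "penalized_nll",
    "fit",
    "predict",
    "stimulus_drive",
    "preferred_direction",
    "tune_bias_to_rate",
]

Z_CLIP = 30.0  # |z| clip inside the link when producing probabilities


class DegenerateFitError(RuntimeError):
    """Raised when the response is all-spike or all-silence and the MLE diverges."""


@dataclass
class GLMConfig:
    """Fitting configuration. Defaults: 5-tap stimulus filter, 2-tap history
    filter, ridge weight 0.01, linear stimulus dependence."""

    L_k: int = 5
    L_h: int = 2
    alpha: float = 0.01
    quadratic: bool = False

    def __post_init__(self) -> None:
        if self.L_k < 1 or self.L_h < 1:
            raise ValueError("filter lengths must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class GLMModel:
    """Fitted (or constructed) encoding model.

    ``stimulus_filters[i][j]`` weights stimulus i at lag L_k-1-j, i.e. the
    filters are stored oldest-bin-first with the last element acting on the
    current bin.  For linear models the filters are in raw stimulus units.
    For quadratic models the stimulus is z-scored (constants stored in
    ``zscore_mean``/``zscore_sd``) before the linear and squared terms are
    formed, and ``quad_filters`` holds the weights on the squared history.
    """

    stimulus_filters: list
    history_filter: np.ndarray
    bias: float
    alpha: float = 0.01
    quadratic: bool = False
    quad_filters: list = field(default_factory=list)
    zscore_mean: list = field(default_factory=list)
    zscore_sd: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stimulus_filters = [np.asarray(k, dtype=float) for k in self.stimulus_filters]
        self.history_filter = np.asarray(self.history_filter, dtype=float)
        self.quad_filters = [np.asarray(k, dtype=float) for k in self.quad_filters]
        self.bias = float(self.bias)
        for k in self.stimulus_filters + [self.history_filter]:
            if not np.all(np.isfinite(k)):
                raise ValueError("model parameters must be finite")
        if not np.isfinite(self.bias):
            raise ValueError("bias must be finite")

    @property
    def L_k(self) -> int:
        return len(self.stimulus_filters[0])

    @property
    def L_h(self) -> int:
        return len(self.history_filter)

    @property
    def n_params(self) -> int:
        n = sum(len(k) for k in self.stimulus_filters) + len(self.history_filter) + 1
        n += sum(len(k) for k in self.quad_filters)
        return n

    def to_json(self) -> str:
        return json.dumps(
            {
                "stimulus_filters": [k.tolist() for k in self.stimulus_filters],
                "history_filter": self.history_filter.tolist(),
                "bias": self.bias,
                "alpha": self.alpha,
                "quadratic": self.quadratic,
                "quad_filters": [k.tolist() for k in self.quad_filters],
                "zscore_mean": list(self.zscore_mean),
                "zscore_sd": list(self.zscore_sd),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GLMModel":
        d = json.loads(text)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as f:
            f.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GLMModel":
        with open(path) as f:
            return cls.from_json(f.read())


@dataclass
class DesignData:
    """Row-per-valid-bin design for the penalised Bernoulli likelihood.

    Column layout: for each stimulus, L_k history columns (oldest first),
    then (if quadratic) L_k squared-history columns per stimulus, then L_h
    spike-history columns (oldest first).  The bias is handled separately.
    Stimulus columns are z-scored for optimiser conditioning; the constants
    are recorded so fitted filters can be mapped back to raw units.
    """

    X: np.ndarray
    y: np.ndarray
    valid_idx: np.ndarray
    config: GLMConfig
    n_stimuli: int
    zscore_mean: list
    zscore_sd: list
    trial_bounds: list

    @property
    def n_params(self) -> int:
        return self.X.shape[1] + 1

    def stimulus_col_mask(self) -> np.ndarray:
        """Boolean mask over columns selecting stimulus (incl. quadratic) columns."""
        mask = np.zeros(self.X.shape[1], dtype=bool)
        per_stim = self.config.L_k * (2 if self.config.quadratic else 1)
        mask[: self.n_stimuli * per_stim] = True
        return mask


def _as_feature_list(features) -> list:
    if isinstance(features, (list, tuple)):
        return [np.asarray(f, dtype=float) for f in features]
    return [np.asarray(features, dtype=float)]


def build_design(features, spikes, trial_bounds, config: GLMConfig = None) -> DesignData:
    """Assemble the design matrix for one or more aligned stimulus series.

    For every valid bin t the row holds the stimulus history
    (x_{t-Lk+1}, ..., x_t) for each stimulus, optionally the squared z-scored
    history, and the spike history (n_{t-Lh}, ..., n_{t-1}).  The first
    max(L_k, L_h) bins of each trial are masked out so no history window
    crosses a trial boundary.
    """
    config = config or GLMConfig()
    feats = _as_feature_list(features)
    n = np.asarray(spikes, dtype=float)
    T = n.shape[0]
    for f in feats:
        if f.shape[0] != T:
            raise ValueError("features and spikes must have equal length")
    L_k, L_h = config.L_k, config.L_h
    margin = max(L_k, L_h)

    # z-score each stimulus over the whole recording for conditioning
    means = [float(f.mean()) for f in feats]
    sds = []
    for f, m in zip(feats, means):
        sd = float(f.std())
        sds.append(sd if sd > 0 else 1.0)
    zfeats = [(f - m) / s for f, m, s in zip(feats, means, sds)]

    X_blocks, y_rows, idx_rows = [], [], []
    for start, stop in trial_bounds:
        if stop - start <= margin:
            continue
        t_idx = np.arange(start + margin, stop)
        blocks = []
        for z in zfeats:
            win = sliding_window_view(z[start:stop], L_k)  # row j = bins j..j+L_k-1
            stim = win[t_idx - start - L_k + 1]
            blocks.append(stim)
            if config.quadratic:
                blocks.append(stim**2)
        hwin = sliding_window_view(n[start:stop], L_h)
        blocks.append(hwin[t_idx - start - L_h])  # bins t-L_h .. t-1
        X_blocks.append(np.hstack(blocks))
        y_rows.append(n[t_idx])
        idx_rows.append(t_idx)
    if not X_blocks:
        raise ValueError("no trial longer than max(L_k, L_h); empty design")
    return DesignData(
        X=np.vstack(X_blocks),
        y=np.concatenate(y_rows),
        valid_idx=np.concatenate(idx_rows),
        config=config,
        n_stimuli=len(feats),
        zscore_mean=means,
        zscore_sd=sds,
        trial_bounds=list(trial_bounds),
    )


def _cost_grad(w: np.ndarray, design: DesignData, alpha: float):
    X, y = design.X, design.y
    z = X @ w[:-1] + w[-1]
    # stable Bernoulli NLL: sum softplus(z) - y z
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    p = expit(z)
    resid = p - y
    grad = np.empty_like(w)
    grad[:-1] = X.T @ resid
    grad[-1] = resid.sum()
    mask = design.stimulus_col_mask()
    nll += alpha * float(np.sum(w[:-1][mask] ** 2))
    grad[:-1][mask] += 2 * alpha * w[:-1][mask]
    return nll, grad


def penalized_nll(model: GLMModel, design: DesignData):
    """Penalised negative log-likelihood and its exact gradient at ``model``.

    The parameter vector is ordered as the design columns (stimulus blocks
    in z-scored space, then spike history) followed by the bias.
    """
    w = _model_to_vector(model, design)
    return _cost_grad(w, design, model.alpha)


def _model_to_vector(model: GLMModel, design: DesignData) -> np.ndarray:
    cfg = design.config
    parts = []
    bias = model.bias
    for i, k in enumerate(model.stimulus_filters):
        if model.quadratic or model.zscore_mean:
            kz = np.asarray(k, dtype=float)
        else:
            # raw-unit filter -> z-space columns
            kz = np.asarray(k, dtype=float) * design.zscore_sd[i]
            bias = bias + float(np.sum(k)) * design.zscore_mean[i]
        parts.append(kz)
        if cfg.quadratic:
            parts.append(np.asarray(model.quad_filters[i], dtype=float))
    parts.append(model.history_filter)
    return np.concatenate([np.concatenate(parts), [bias]])


def fit(design: DesignData, alpha: float = None, init: np.ndarray = None,
        gtol: float = 1e-8, maxiter: int = 1000) -> GLMModel:
    """Fit the GLM by convex minimisation of the penalised NLL.

    Deterministic given ``init`` (default: all-zero parameters).  Linear
    models are returned with filters converted back to raw stimulus units;
    quadratic models keep z-scored filters together with the z-scoring
    constants, which prediction re-applies.
    """
    if alpha is None:
        alpha = design.config.alpha
    y = design.y
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateFitError("response is all-zero or all-one; MLE diverges")
    P = design.X.shape[1] + 1
    w0 = np.zeros(P) if init is None else np.asarray(init, dtype=float)
    res = minimize(
        _cost_grad, w0, args=(design, alpha), jac=True, method="L-BFGS-B",
        options={"gtol": gtol, "maxiter": maxiter, "ftol": 1e-12},
    )
    return _vector_to_model(res.x, design, alpha)


def _vector_to_model(w: np.ndarray, design: DesignData, alpha: float) -> GLMModel:
    cfg = design.config
    L_k, L_h = cfg.L_k, cfg.L_h
    pos = 0
    stim_filters, quad_filters = [], []
    for _ in range(design.n_stimuli):
        stim_filters.append(w[pos : pos + L_k].copy())
        pos += L_k
        if cfg.quadratic:
            quad_filters.append(w[pos : pos + L_k].copy())
            pos += L_k
    h = w[pos : pos + L_h].copy()
    pos += L_h
    bias = float(w[pos])
    if cfg.quadratic:
        return GLMModel(
            stimulus_filters=stim_filters, history_filter=h, bias=bias, alpha=alpha,
            quadratic=True, quad_filters=quad_filters,
            zscore_mean=list(design.zscore_mean), zscore_sd=list(design.zscore_sd),
        )
    # map z-space filters back to raw stimulus units
    raw_filters = []
    for i, kz in enumerate(stim_filters):
        raw_filters.append(kz / design.zscore_sd[i])
        bias -= float(np.sum(kz)) * design.zscore_mean[i] / design.zscore_sd[i]
    return GLMModel(stimulus_filters=raw_filters, history_filter=h, bias=bias, alpha=alpha)


def stimulus_drive(model: GLMModel, features, trial_bounds) -> np.ndarray:
    """Stimulus contribution sum_i k_i . x_t(i) per bin, zero-padded at trial starts.

    The pad acts in the space the filters apply to (raw units for linear
    models, z-scored units for quadratic ones), i.e. missing history is
    treated as stimulus-at-rest.
    """
    feats = _as_feature_list(features)
    if len(feats) != len(model.stimulus_filters):
        raise ValueError("number of features does not match model stimulus filters")
    T = feats[0].shape[0]
    L_k = model.L_k
    drive = np.zeros(T)
    for i, f in enumerate(feats):
        if f.shape[0] != T:
            raise ValueError("features must be aligned (equal lengths)")
        if model.quadratic or model.zscore_mean:
            f = (f - model.zscore_mean[i]) / model.zscore_sd[i]
        k = model.stimulus_filters[i]
        for start, stop in trial_bounds:
            seg = np.concatenate([np.zeros(L_k - 1), f[start:stop]])
            win = sliding_window_view(seg, L_k)
            drive[start:stop] += win @ k
            if model.quadratic:
                drive[start:stop] += win**2 @ model.quad_filters[i]
    return drive


@njit(cache=False)
def _sample_recursive(drive, h, b, u):  # pragma: no cover - numba-compiled
    T = drive.shape[0]
    Lh = h.shape[0]
    n = np.zeros(T, dtype=np.uint8)
    y = np.empty(T)
    for t in range(T):
        z = drive[t] + b
        for j in range(Lh):
            idx = t - Lh + j
            if idx >= 0 and n[idx] == 1:
                z += h[j]
        if z > 30.0:
            z = 30.0
        elif z < -30.0:
            z = -30.0
        p = 1.0 / (1.0 + np.exp(-z))
        y[t] = p
        if u[t] < p:
            n[t] = 1
    return y, n


def predict(model: GLMModel, features, trial_bounds, mode: str = "sampled", seed=None):
    """Predicted spike probabilities (and spikes, in sampled mode).

    ``mode="sampled"``: recursive Bernoulli generation in which the spike
    history term is driven by the *sampled* spikes — this is how a
    'predicted spike train' is produced for single-trial evaluation, and
    also how spike trains are generated from a known model.  Returns
    ``(probs, spikes)``.

    ``mode="expected"``: deterministic probability series with the history
    filter switched off (all-zero history), for diagnostics.  Returns
    ``probs``.
    """
    drive = stimulus_drive(model, features, trial_bounds)
    if mode == "expected":
        z = np.clip(drive + model.bias, -Z_CLIP, Z_CLIP)
        return expit(z)
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    T = drive.shape[0]
    probs = np.empty(T)
    spikes = np.zeros(T, dtype=np.uint8)
    h = np.asarray(model.history_filter, dtype=float)
    for start, stop in trial_bounds:
        u = rng.random(stop - start)
        y, n = _sample_recursive(drive[start:stop], h, float(model.bias), u)
        probs[start:stop] = y
        spikes[start:stop] = n
    return probs, spikes


def preferred_direction(model: GLMModel) -> str:
    """Direction selectivity of an instantaneous (L_k = 1) model.

    Positive stimulus-filter gain makes positive stimuli trigger spikes.
    """
    if model.L_k != 1 or len(model.stimulus_filters) != 1:
        raise ValueError("preferred_direction requires a single length-1 stimulus filter")
    k = float(model.stimulus_filters[0][0])
    if k > 0:
        return "positive"
    if k < 0:
        return "negative"
    return "undetermined"


def tune_bias_to_rate(drive, history_filter, target_rate_hz: float,
                      fs_hz: float = 1000.0, tol_hz: float = 2.5, seed: int = 0) -> float:
    """Bias b such that the model's mean firing rate matches ``target_rate_hz``.

    Bisects on b against the *sampled* mean rate (recursive generation with
    spike-history feedback), using common random numbers across bisection
    steps so the rate curve is monotone up to feedback effects and the
    search is deterministic.  Raises if the target cannot be reached within
    ``tol_hz`` (or 5% of the target, whichever is larger).
    """
    drive = np.asarray(drive, dtype=float)
    h = np.asarray(history_filter, dtype=float)
    target_p = target_rate_hz / fs_hz
    u = np.random.default_rng(seed).random(drive.shape[0])

    def rate(b: float) -> float:
        _, n = _sample_recursive(drive, h, b, u)
        return float(n.mean())

    lo, hi = -300.0, 20.0  # wide bracket: strongly driven units need b ~ -(gain)
    for _ in range(70):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_p:
            lo = mid
        else:
            hi = mid
        if (hi - lo) < 1e-9:
            break
    b = 0.5 * (lo + hi)
    if abs(rate(b) * fs_hz - target_rate_hz) > max(tol_hz, 0.05 * target_rate_hz):
        raise RuntimeError("bias tuning failed to reach the target rate")
    return b
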