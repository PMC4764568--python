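"""Synthetic whisker sessions and spike trains.

Emulates the two recording situations the analyses need, at 1 kHz:

* **Active pole exploration** (``active_pole``): trials of ~3 s in which a
  pole sits at one of 11 rostro-caudal positions spanning +/- 6 mm.  The
  whisker performs rhythmic whisking (6-30 Hz carrier with slowly varying
  amplitude and setpoint).  Touch begins when the protracting whisker angle
  crosses a pole-position-dependent contact threshold and ends when it
  retracts below it.  During touch the pole partly arrests the base angle
  (only a compliance fraction of the free rotation still appears in the
  angle) while the remainder is absorbed as bending: curvature change
  follows the blocked rotation with a pole-position-dependent gain,
  growing while the whisker pushes forward and relaxing as it retracts.
  The coupling sign flips for the most caudal pole positions, where pushing
  straightens the intrinsically curved shaft instead of bending it further.
  Outside touch only a small torsion-like ripple remains.  Angle and
  curvature change are therefore only loosely correlated over a session
  (~0.2) — the signature of active touch.

* **Passive deflection** (``passive_trapezoid``, ``passive_whitenoise``):
  the whisker is driven by an actuator, either a 10 Hz trapezoid (amplitude
  8 deg, 3 s) or Gaussian white noise smoothed with a decaying exponential
  (time constant 10 ms) and rescaled to SD 2.1 deg.  Because a passively
  deflected whisker behaves like a loaded cantilever, curvature change is a
  near-linear function of angle: we construct it as a rescaled copy of the
  angle mixed with independent frame-wise (white) noise so that the
  angle-curvature correlation hits a configurable target (default 0.96).

Spike trains are generated from a known Bernoulli GLM by recursive sampling
(the spike-history term sees the sampled spikes).  All generators are
bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from . import glm as _glm
from .mechanics import curvature_change, touch_episodes

__all__ = [
    "Session",
    "SpikeTrain",
    "PROTOCOLS",
    "generate_whisking_angle",
    "generate_session",
    "generate_spikes_from_glm",
    "ACTIVE_DEFAULTS",
    "PASSIVE_DEFAULTS",
]

FS_HZ = 1000.0
PROTOCOLS = ("active_pole", "passive_trapezoid", "passive_whitenoise")

#: Defaults for active pole exploration.  Geometry (contact threshold and its
#: dependence on pole position, coupling gain) is chosen so that touches
#: occupy a realistic ~15-25% of a trial, curvature change spans the ~0.05
#: mm^-1 scale seen on video, and the session-level angle-curvature
#: correlation lands near the loose coupling (~0.2) characteristic of
#: active touch.
ACTIVE_DEFAULTS = {
    "trial_len_ms": 3000,
    "pole_onset_ms": 500,
    "whisk_freq_hz": 8.0,
    "amp_envelope": {"mean": 15.0, "mod_depth": 5.0, "mod_freq_hz": 0.5},
    "setpoint": {"mean": 10.0, "drift": 5.0, "drift_freq_hz": 0.2},
    "angle_noise_sd": 0.3,
    "pole_range_mm": 6.0,
    "n_pole_positions": 11,
    "contact_offset_deg": 18.0,
    "contact_slope_deg_per_mm": 1.2,
    "touch_compliance": 0.1,       # fraction of free rotation reaching the base angle in touch
    "coupling_gain": 0.004,        # mm^-1 per degree of blocked rotation at pole 0
    "coupling_sign_split_mm": -3.0,  # caudal of this, pushing straightens the whisker (negative gain)
    "coupling_gain_slope": 0.5,    # fractional gain change across the pole range
    "touch_noise_sd": 0.0005,      # mm^-1
    "ripple_sd": 0.001,            # mm^-1, non-touch torsion-like ripple
    "ripple_tau_ms": 20.0,
    "intrinsic_curvature": -0.02,  # mm^-1
    "intrinsic_jitter_sd": 0.002,
}

#: Defaults for passive deflection protocols.
PASSIVE_DEFAULTS = {
    "trial_len_ms": 3000,
    "quiet_ms": 100,               # actuator-off lead used to estimate intrinsic curvature
    "noise_tau_ms": 10.0,
    "angle_sd_deg": 2.1,
    "trapezoid_freq_hz": 10.0,
    "trapezoid_amp_deg": 8.0,
    "corr_target": 0.96,
    "dkappa_sd": 0.0084,           # mm^-1; +/-3 SD spans the ~0.05 mm^-1 video scale
    "intrinsic_curvature": -0.02,
    "intrinsic_jitter_sd": 0.002,
}


@dataclass
class Session:
    """Aligned 1 kHz traces for one recording session.

    ``trial_bounds`` are half-open [start, stop) bin intervals that tile the
    recording; ``pole_pos_mm`` holds one rostro-caudal pole position per
    trial (NaN when no pole is present, as in passive protocols).
    """

    angle_deg: np.ndarray
    curvature_invmm: np.ndarray
    curvature_change_invmm: np.ndarray
    trial_bounds: list
    pole_pos_mm: np.ndarray
    touch: np.ndarray
    protocol: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.curvature_invmm = np.asarray(self.curvature_invmm, dtype=float)
        self.curvature_change_invmm = np.asarray(self.curvature_change_invmm, dtype=float)
        self.touch = np.asarray(self.touch).astype(np.uint8)
        self.pole_pos_mm = np.asarray(self.pole_pos_mm, dtype=float)
        self.trial_bounds = [(int(a), int(b)) for a, b in self.trial_bounds]
        self.validate()

    def validate(self) -> None:
        T = self.angle_deg.shape[0]
        for name in ("curvature_invmm", "curvature_change_invmm", "touch"):
            if getattr(self, name).shape[0] != T:
                raise ValueError(f"{name} length differs from angle_deg")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if len(self.pole_pos_mm) != len(self.trial_bounds):
            raise ValueError("one pole position per trial required")
        prev = 0
        for start, stop in self.trial_bounds:
            if start != prev or stop <= start:
                raise ValueError("trial bounds must be ordered, non-overlapping and tiling")
            prev = stop
        if prev != T:
            raise ValueError("trial bounds must cover all bins")
        for (start, stop), pole in zip(self.trial_bounds, self.pole_pos_mm):
            if np.isnan(pole) and self.touch[start:stop].any():
                raise ValueError("touch labelled while pole absent")

    @property
    def n_bins(self) -> int:
        return self.angle_deg.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trial_bounds)

    @property
    def session_id(self) -> str:
        return f"{self.protocol}-{self.seed}"

    def trial_index(self) -> np.ndarray:
        """Per-bin trial number."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for i, (start, stop) in enumerate(self.trial_bounds):
            out[start:stop] = i
        return out

    def feature(self, name: str) -> np.ndarray:
        """Named feature trace: 'angle', 'curvature', 'curvature_change'."""
        table = {
            "angle": self.angle_deg,
            "angle_deg": self.angle_deg,
            "curvature": self.curvature_invmm,
            "curvature_invmm": self.curvature_invmm,
            "curvature_change": self.curvature_change_invmm,
            "curvature_change_invmm": self.curvature_change_invmm,
            "dkappa": self.curvature_change_invmm,
        }
        if name not in table:
            raise KeyError(f"unknown feature {name!r}")
        return table[name]


@dataclass
class SpikeTrain:
    """Binary spike counts per 1 ms bin, aligned to a session."""

    counts: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.isin(c, (0, 1)).all():
            raise ValueError("spike counts must be binary")
        self.counts = c.astype(np.uint8)

    @property
    def n_spikes(self) -> int:
        return int(self.counts.sum())

    def rate_hz(self, fs_hz: float = FS_HZ) -> float:
        return self.n_spikes / self.counts.size * fs_hz


def _exp_smooth(x: np.ndarray, tau_ms: float, fs_hz: float = FS_HZ) -> np.ndarray:
    """Convolution with a causal decaying exponential, time constant tau."""
    a = np.exp(-1.0 / (tau_ms * fs_hz / 1000.0))
    return lfilter([1.0], [1.0, -a], x)


def generate_whisking_angle(
    duration_ms: int,
    whisk_freq_hz: float = 8.0,
    amp_envelope_params: dict = None,
    setpoint_params: dict = None,
    noise_sd: float = 0.3,
    freq_jitter_sd: float = 1.0,
    freq_jitter_tau_ms: float = 500.0,
    seed=None,
) -> np.ndarray:
    """Free-whisking angle trace: slow setpoint + amplitude-modulated carrier + noise.

    The carrier frequency must lie in the 6-30 Hz whisking band.  Whisking
    is rhythmic but not metronomic: the instantaneous carrier frequency
    wanders around ``whisk_freq_hz`` as a mean-reverting random walk (SD
    ``freq_jitter_sd`` Hz, correlation time ``freq_jitter_tau_ms``),
    clipped to the band.  Set ``freq_jitter_sd=0`` for a strictly periodic
    carrier.  Envelope and setpoint vary on a slow (sub-Hz) time scale;
    random phases make different seeds produce different traces while a
    fixed seed is bit-reproducible.
    """
    if not (6.0 <= whisk_freq_hz <= 30.0):
        raise ValueError("whisk_freq_hz must lie in the 6-30 Hz whisking band")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    amp = dict(ACTIVE_DEFAULTS["amp_envelope"])
    amp.update(amp_envelope_params or {})
    setp = dict(ACTIVE_DEFAULTS["setpoint"])
    setp.update(setpoint_params or {})
    rng = np.random.default_rng(seed)
    n = int(duration_ms)
    t = np.arange(n) / FS_HZ
    ph = rng.uniform(0, 2 * np.pi, size=3)
    envelope = amp["mean"] + amp["mod_depth"] * np.sin(2 * np.pi * amp["mod_freq_hz"] * t + ph[0])
    envelope = np.maximum(envelope, 0.0)
    setpoint = setp["mean"] + setp["drift"] * np.sin(2 * np.pi * setp["drift_freq_hz"] * t + ph[1])
    if freq_jitter_sd > 0:
        # Ornstein-Uhlenbeck frequency wander (AR(1)): stationary SD = freq_jitter_sd
        a = 1.0 - 1.0 / freq_jitter_tau_ms
        sigma = freq_jitter_sd * np.sqrt(1.0 - a**2)
        wander = lfilter([sigma], [1.0, -a], rng.normal(size=n))
        freq = np.clip(whisk_freq_hz + wander, 6.0, 30.0)
    else:
        freq = np.full(n, whisk_freq_hz)
    carrier = np.sin(2 * np.pi * np.cumsum(freq) / FS_HZ + ph[2])
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    return setpoint + envelope * carrier + noise


def _trapezoid_wave(n_bins: int, freq_hz: float, amp_deg: float) -> np.ndarray:
    """Periodic trapezoid between 0 and amp: rise 15%, hold 35%, fall 15%, rest 35%."""
    phase = (np.arange(n_bins) / FS_HZ * freq_hz) % 1.0
    xp = [0.0, 0.15, 0.50, 0.65, 1.0]
    fp = [0.0, 1.0, 1.0, 0.0, 0.0]
    return amp_deg * np.interp(phase, xp, fp)


def _pole_positions(rng, n_trials: int, p: dict) -> np.ndarray:
    """Draw pole positions in shuffled blocks over the 11-position grid."""
    grid = np.linspace(-p["pole_range_mm"], p["pole_range_mm"], p["n_pole_positions"])
    out = []
    while len(out) < n_trials:
        out.extend(grid[rng.permutation(len(grid))])
    return np.array(out[:n_trials])


def _generate_active(n_trials: int, p: dict, seed) -> Session:
    rng = np.random.default_rng(seed)
    L = int(p["trial_len_ms"])
    T = n_trials * L
    pole = _pole_positions(rng, n_trials, p)
    angle = np.empty(T)
    dk_true = np.zeros(T)
    touch = np.zeros(T, dtype=np.uint8)
    for i in range(n_trials):
        start = i * L
        a = generate_whisking_angle(
            L, p["whisk_freq_hz"], p["amp_envelope"], p["setpoint"],
            p["angle_noise_sd"], seed=rng,
        )
        angle[start : start + L] = a
        thresh = p["contact_offset_deg"] + p["contact_slope_deg_per_mm"] * pole[i]
        over = a > thresh
        over[: int(p["pole_onset_ms"])] = False  # pole not yet in the whisker field
        # coupling magnitude grows rostrally; the sign flips for caudal poles,
        # where pushing straightens the intrinsically curved whisker shaft
        gain = p["coupling_gain"] * (
            1.0 + p["coupling_gain_slope"] * pole[i] / p["pole_range_mm"]
        )
        if pole[i] < p["coupling_sign_split_mm"]:
            gain = -gain
        compliance = p["touch_compliance"]
        for ep_start, ep_stop in touch_episodes(over):
            if ep_start == 0:
                continue  # no pre-onset reference frame (cannot happen after onset mask)
            free_push = a[ep_start:ep_stop] - a[ep_start - 1]
            # the pole arrests most of the rotation; the blocked part bends the whisker
            angle[start + ep_start : start + ep_stop] = (
                a[ep_start - 1] + compliance * free_push
            )
            dk_true[start + ep_start : start + ep_stop] = (
                gain * (1.0 - compliance) * free_push
                + rng.normal(0.0, p["touch_noise_sd"], size=free_push.shape)
            )
            touch[start + ep_start : start + ep_stop] = 1
    # non-touch torsion-like ripple
    ripple = _exp_smooth(rng.normal(size=T), p["ripple_tau_ms"])
    ripple *= p["ripple_sd"] / ripple.std()
    dk_true = np.where(touch == 1, dk_true, ripple)
    trial_bounds = [(i * L, (i + 1) * L) for i in range(n_trials)]
    kappa_int = p["intrinsic_curvature"] + rng.normal(0, p["intrinsic_jitter_sd"], n_trials)
    kappa = dk_true.copy()
    for i, (a0, b0) in enumerate(trial_bounds):
        kappa[a0:b0] += kappa_int[i]
    dk = curvature_change(kappa, trial_bounds)
    return Session(
        angle_deg=angle, curvature_invmm=kappa, curvature_change_invmm=dk,
        trial_bounds=trial_bounds, pole_pos_mm=pole, touch=touch,
        protocol="active_pole", seed=_seed_int(seed), params=dict(p),
    )


def _generate_passive(protocol: str, n_trials: int, p: dict, seed) -> Session:
    rng = np.random.default_rng(seed)
    L = int(p["trial_len_ms"])
    quiet = int(p["quiet_ms"])
    T = n_trials * L
    stim_mask = np.zeros(T, dtype=bool)
    for i in range(n_trials):
        stim_mask[i * L + quiet : (i + 1) * L] = True

    def smoothed_noise() -> np.ndarray:
        out = np.zeros(T)
        for i in range(n_trials):
            seg = _exp_smooth(rng.normal(size=L - quiet), p["noise_tau_ms"])
            out[i * L + quiet : (i + 1) * L] = seg - seg.mean()
        return out

    if protocol == "passive_whitenoise":
        angle = smoothed_noise()
        angle[stim_mask] *= p["angle_sd_deg"] / angle[stim_mask].std()
    else:  # passive_trapezoid
        angle = np.zeros(T)
        wave = _trapezoid_wave(L - quiet, p["trapezoid_freq_hz"], p["trapezoid_amp_deg"])
        for i in range(n_trials):
            angle[i * L + quiet : (i + 1) * L] = wave

    # curvature change = scaled angle + independent frame-wise noise, mixed so
    # that corr(angle, dkappa) over stimulus bins equals the target.  The
    # decoupling noise is white at 1 kHz (frame-by-frame, as tracking noise on
    # a curvature estimate is), not smoothed like the actuator signal.
    rho = float(p["corr_target"])
    if not (0.0 <= rho <= 1.0):
        raise ValueError("corr_target must be in [0, 1]")
    u = np.zeros(T)
    sd = angle[stim_mask].std()
    if sd > 0:
        u[stim_mask] = (angle[stim_mask] - angle[stim_mask].mean()) / sd
    v = np.zeros(T)
    v[stim_mask] = rng.normal(size=int(stim_mask.sum()))
    v[stim_mask] -= v[stim_mask].mean()
    if v[stim_mask].std() > 0:
        v[stim_mask] /= v[stim_mask].std()
    dk_true = np.zeros(T)
    dk_true[stim_mask] = p["dkappa_sd"] * (rho * u[stim_mask] + np.sqrt(1 - rho**2) * v[stim_mask])

    trial_bounds = [(i * L, (i + 1) * L) for i in range(n_trials)]
    kappa_int = p["intrinsic_curvature"] + rng.normal(0, p["intrinsic_jitter_sd"], n_trials)
    kappa = dk_true.copy()
    for i, (a0, b0) in enumerate(trial_bounds):
        kappa[a0:b0] += kappa_int[i]
    dk = curvature_change(kappa, trial_bounds, intrinsic_window_ms=quiet)
    return Session(
        angle_deg=angle, curvature_invmm=kappa, curvature_change_invmm=dk,
        trial_bounds=trial_bounds, pole_pos_mm=np.full(n_trials, np.nan),
        touch=np.zeros(T, dtype=np.uint8), protocol=protocol,
        seed=_seed_int(seed), params=dict(p),
    )


def _seed_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return -1  # generator or None: no single integer seed to record


def generate_session(protocol: str, n_trials: int, params: dict = None, seed=None) -> Session:
    """Generate a synthetic session under one of the three protocols.

    ``params`` overrides entries of :data:`ACTIVE_DEFAULTS` or
    :data:`PASSIVE_DEFAULTS`.  Deterministic given an integer ``seed``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if protocol == "active_pole":
        p = dict(ACTIVE_DEFAULTS)
        p.update(params or {})
        return _generate_active(n_trials, p, seed)
    if protocol in ("passive_trapezoid", "passive_whitenoise"):
        p = dict(PASSIVE_DEFAULTS)
        p.update(params or {})
        return _generate_passive(protocol, n_trials, p, seed)
    raise ValueError(f"unknown protocol {protocol!r}")


def generate_spikes_from_glm(model, session: Session, feature="curvature_change", seed=None) -> SpikeTrain:
    """Sample a spike train from a known GLM driven by a session feature.

    ``feature`` is a feature name, an array aligned with the session, or a
    list of either (for multi-stimulus models).  Sampling is recursive: the
    history term sees the spikes actually drawn, and histories never cross
    trial boundaries.
    """
    if isinstance(feature, str):
        feats = [session.feature(feature)]
    elif isinstance(feature, (list, tuple)):
        feats = [session.feature(f) if isinstance(f, str) else np.asarray(f, float) for f in feature]
    else:
        feats = [np.asarray(feature, dtype=float)]
    for f in feats:
        if f.shape[0] != session.n_bins:
            raise ValueError("feature length does not match session")
    if model.L_k > min(b - a for a, b in session.trial_bounds):
        raise ValueError("model filter longer than the shortest trial")
    _, spikes = _glm.predict(model, feats, session.trial_bounds, mode="sampled", seed=seed)
    return SpikeTrain(counts=spikes, session_id=session.session_id)
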