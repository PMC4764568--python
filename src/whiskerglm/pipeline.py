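"""End-to-end orchestration: simulate (or load) a session, extract
mechanical features, fit and evaluate encoding models per feature set, run
the free-whisking battery, and emit a per-unit report table.

Every stage derives its randomness from one master seed; the expanded seed
tree is logged in the report so any stochastic output can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import evaluate as _ev
from . import glm as _glm
from . import whisking as _wh
from .glm import GLMConfig
from .mechanics import angular_acceleration, push_angle
from .studies import make_constrained_unit
from .synth import Session, SpikeTrain, generate_session, generate_spikes_from_glm

__all__ = ["RunConfig", "run_pipeline", "format_report"]

FEATURE_SETS = ("curvature", "angle", "both", "push_angle", "acceleration_quadratic")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run.

    Defaults follow the standard analysis settings: 5-tap stimulus filter,
    2-tap history filter, alpha = 0.01, 10 train/test repeats, 100 ms
    smoothing, 3000-8000 ms chance shifts, 500 phase shuffles, 2 deg
    whisking-amplitude threshold.
    """

    protocol: str = "active_pole"
    n_trials: int = 20
    session_params: dict = field(default_factory=dict)
    L_k: int = 5
    L_h: int = 2
    alpha: float = 0.01
    n_repeats: int = 10
    n_chance: int = 10
    smoothing_ms: int = 100
    shift_range_ms: tuple = (3000, 8000)
    n_shuffles: int = 500
    amp_threshold_deg: float = 2.0
    significance_p: float = 0.0025
    feature_sets: tuple = FEATURE_SETS
    unit_gain_z: float = 3.0
    unit_rate_hz: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if not (0 < self.significance_p < 1):
            raise ValueError("significance_p must be in (0, 1)")
        lo, hi = self.shift_range_ms
        if lo <= 0 or hi < lo:
            raise ValueError("shift_range_ms must be positive and ordered")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets {sorted(unknown)}")
        GLMConfig(self.L_k, self.L_h, self.alpha)  # validates filter/alpha settings

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)


def _features_for(name: str, session: Session):
    """Aligned input series (list) and GLM config overrides for a feature set."""
    dk = session.curvature_change_invmm
    angle = session.angle_deg
    if name == "curvature":
        return [dk], {}
    if name == "angle":
        return [angle], {}
    if name == "both":
        return [dk, angle], {}
    if name == "push_angle":
        pa = push_angle(angle, session.touch)
        return [np.nan_to_num(pa, nan=0.0)], {}  # zero outside touch
    if name == "acceleration_quadratic":
        acc = np.empty(session.n_bins)
        for a0, b0 in session.trial_bounds:
            acc[a0:b0] = angular_acceleration(angle[a0:b0])
        return [acc], {"quadratic": True}
    raise ValueError(f"unknown feature set {name!r}")


def run_pipeline(config: RunConfig, session: Session = None, spikes: SpikeTrain = None):
    """Run the full analysis and return a structured report dict.

    When no session/spikes are given, a synthetic session is generated under
    ``config.protocol`` and a curvature-tuned model unit provides the spike
    train, so the pipeline exercises every stage with known ground truth.
    """
    master = np.random.default_rng(config.seed)
    seeds = {
        "session": int(master.integers(2**31)),
        "unit": int(master.integers(2**31)),
        "evaluation": {name: int(master.integers(2**31)) for name in config.feature_sets},
        "whisking": int(master.integers(2**31)),
    }
    if session is None:
        session = generate_session(
            config.protocol, config.n_trials, config.session_params, seeds["session"]
        )
    if spikes is None:
        unit = make_constrained_unit(
            session.curvature_change_invmm, session.trial_bounds,
            target_rate_hz=config.unit_rate_hz, gain_z=config.unit_gain_z,
        )
        spikes = generate_spikes_from_glm(unit, session, "curvature_change", seeds["unit"])

    report = {"seeds": seeds, "protocol": session.protocol,
              "n_trials": session.n_trials, "n_bins": session.n_bins,
              "n_spikes": int(np.asarray(spikes.counts).sum()), "features": {}}
    for name in config.feature_sets:
        feats, overrides = _features_for(name, session)
        cfg = GLMConfig(config.L_k, config.L_h, config.alpha, **overrides)
        try:
            res = _ev.evaluate_unit(
                session, spikes, feats, cfg,
                n_repeats=config.n_repeats, n_chance=config.n_chance,
                smoothing_ms=config.smoothing_ms,
                shift_range_ms=config.shift_range_ms, p=config.significance_p,
                seed=seeds["evaluation"][name],
            )
        except (RuntimeError, _glm.DegenerateFitError, ValueError) as exc:
            raise RuntimeError(
                f"stage 'evaluate/{name}' failed (seed {seeds['evaluation'][name]}): {exc}"
            ) from exc
        report["features"][name] = {
            "median_pcc": res.median_pcc,
            "pcc_per_repeat": res.pcc_per_repeat.tolist(),
            "chance_median_pcc": float(np.median(res.chance_pccs)),
            "significant": bool(res.significant),
            "p_value": res.p_value,
        }
    if session.touch.any() and not session.touch.all():
        tr, ntr = _ev.episode_rates(spikes, session.touch)
        report["touch_rate_hz"], report["nontouch_rate_hz"] = tr, ntr

    report["whisking"] = _whisking_battery(session, spikes, config, seeds["whisking"])
    return report


def _whisking_battery(session: Session, spikes: SpikeTrain, config: RunConfig, seed: int):
    """Amplitude, phase and acceleration tuning on non-touch data."""
    state = _wh.decompose_whisking(session.angle_deg, trial_bounds=session.trial_bounds)
    counts = np.asarray(spikes.counts, dtype=float)
    non_touch = session.touch == 0
    out = {}
    amp_curve = _wh.equi_populated_tuning(state.amplitude[non_touch], counts[non_touch], 30)
    slope, pval, sig = _wh.amplitude_sensitivity(amp_curve, config.significance_p)
    out["amplitude"] = {"slope": slope, "p_value": pval, "significant": sig}
    try:
        phase = _wh.phase_tuning_test(
            state, counts, amp_threshold=config.amp_threshold_deg,
            n_shuffles=config.n_shuffles, shift_range_ms=config.shift_range_ms,
            seed=seed,
        )
        out["phase"] = {"max_rate": phase["max_rate"], "null_95": phase["null_95"],
                        "significant": bool(phase["significant"])}
    except ValueError as exc:
        out["phase"] = {"error": str(exc)}
    acc = np.empty(session.n_bins)
    for a0, b0 in session.trial_bounds:
        acc[a0:b0] = angular_acceleration(session.angle_deg[a0:b0])
    acc_curve = _wh.equi_populated_tuning(acc[non_touch], counts[non_touch], 30)
    reg = _wh.acceleration_regression(acc_curve)
    out["acceleration"] = {"mu0": reg.mu0, "mu1": reg.mu1, "mu2": reg.mu2,
                           "class": reg.classification}
    return out


def format_report(report: dict) -> str:
    """Human-readable per-unit summary table."""
    lines = [
        f"protocol {report['protocol']}  trials {report['n_trials']}  "
        f"bins {report['n_bins']}  spikes {report['n_spikes']}",
        "",
        f"{'feature set':<26}{'median PCC':>12}{'chance':>10}{'significant':>13}",
    ]
    for name, r in report["features"].items():
        lines.append(
            f"{name:<26}{r['median_pcc']:>12.3f}{r['chance_median_pcc']:>10.3f}"
            f"{str(r['significant']):>13}"
        )
    if "touch_rate_hz" in report:
        lines.append("")
        lines.append(
            f"touch rate {report['touch_rate_hz']:.1f} spikes/s   "
            f"non-touch rate {report['nontouch_rate_hz']:.1f} spikes/s"
        )
    wh = report.get("whisking", {})
    if wh:
        lines.append("")
        a = wh["amplitude"]
        lines.append(f"amplitude tuning: slope {a['slope']:.3f} Hz/deg "
                     f"(p={a['p_value']:.3g}, significant={a['significant']})")
        if "error" not in wh.get("phase", {}):
            p = wh["phase"]
            lines.append(f"phase tuning: max {p['max_rate']:.1f} Hz vs null95 "
                         f"{p['null_95']:.1f} Hz (significant={p['significant']})")
        c = wh["acceleration"]
        lines.append(f"acceleration tuning: class {c['class']} "
                     f"(mu1={c['mu1']:.3g}, mu2={c['mu2']:.3g})")
    return "\n".join(lines)
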