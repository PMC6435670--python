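"""Calibration of instrument and high-sensitivity damping parameters.

The model is fitted to measured BCG morphology through six scalar wave
amplitudes: I, J, K of the scale displacement beat and J, K, L of the wrist
acceleration beat.  The penalty is the sum of squared relative amplitude
errors,

    J = sum_w ((A_w^model - A_w^target) / A_w^target)^2,

decomposable into scale and wrist partial sums.  By default the free
parameters are the spinal damping c14 and the instrument damping/stiffness
c5, k5 — the parameters that are both unknown a priori and highly influential
on the BCG shape — while the physically grounded masses and stiffnesses stay
fixed.  Optimization runs in log-parameter space (parameters are positive and
span orders of magnitude) with a seeded multistart to guard against local
minima; trials where a wave becomes undetectable receive a large finite
penalty instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .aortic_input import AorticPressureSet
from .body_dynamics import BodyParameters
from .fiducials import MissingWaveError, NoWavesError, detect_acceleration_waves, detect_displacement_waves
from .force_model import AortaGeometry, compute_force_bcg
from .experiments import extract_period_force, roll_to_onset, simulate_steady_beat

__all__ = [
    "AmplitudeTargets",
    "CalibrationProblem",
    "CalibrationResult",
    "penalty",
    "penalty_components",
    "model_amplitudes",
    "calibrate",
    "UNDETECTABLE_PENALTY",
]

UNDETECTABLE_PENALTY = 1e6

_SCALE_WAVES = ("I", "J", "K")
_WRIST_WAVES = ("J", "K", "L")


@dataclass(frozen=True)
class AmplitudeTargets:
    """Six wave amplitudes: scale displacement in m, wrist acceleration in m/s^2."""

    scale_i: float
    scale_j: float
    scale_k: float
    wrist_j: float
    wrist_k: float
    wrist_l: float
    note: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "scale_i": self.scale_i,
            "scale_j": self.scale_j,
            "scale_k": self.scale_k,
            "wrist_j": self.wrist_j,
            "wrist_k": self.wrist_k,
            "wrist_l": self.wrist_l,
        }

    def validate(self) -> None:
        for name, v in self.as_dict().items():
            if v <= 0:
                raise ValueError(f"target amplitude {name} must be strictly positive")


def penalty_components(model: AmplitudeTargets, target: AmplitudeTargets) -> tuple[float, float]:
    """Scale and wrist partial sums of the squared-relative-error penalty."""
    target.validate()
    m, t = model.as_dict(), target.as_dict()

    def term(key: str) -> float:
        if t[key] == 0:
            raise ZeroDivisionError(f"zero target amplitude for {key}")
        return ((m[key] - t[key]) / t[key]) ** 2

    j_scale = sum(term(k) for k in ("scale_i", "scale_j", "scale_k"))
    j_wrist = sum(term(k) for k in ("wrist_j", "wrist_k", "wrist_l"))
    return j_scale, j_wrist


def penalty(model: AmplitudeTargets, target: AmplitudeTargets) -> float:
    """Total penalty: sum of the six squared relative amplitude errors."""
    j_scale, j_wrist = penalty_components(model, target)
    return j_scale + j_wrist


def model_amplitudes(
    body: BodyParameters,
    bp: AorticPressureSet,
    geom: AortaGeometry,
    _cache: dict | None = None,
) -> AmplitudeTargets | None:
    """Forward model: steady-state beat -> six wave amplitudes.

    Returns ``None`` when any of the six waves is undetectable.  The force and
    beat window depend only on the pressure set and geometry, so repeated calls
    during optimization may share a cache dict.
    """
    if _cache is not None and "force" in _cache:
        force, onset = _cache["force"], _cache["onset"]
    else:
        force, onset = roll_to_onset(extract_period_force(compute_force_bcg(bp, geom), bp.period))
        if _cache is not None:
            _cache["force"], _cache["onset"] = force, onset
    beat = simulate_steady_beat(bp, geom, body, force_override=force, onset=0)
    t = beat.outputs.time
    try:
        scale = detect_displacement_waves(t, beat.outputs.scale_displacement, "scale_disp")
        wrist = detect_acceleration_waves(t, beat.outputs.wrist_acceleration, "wrist_acc")
        return AmplitudeTargets(
            scale_i=scale.amplitude("I"),
            scale_j=scale.amplitude("J"),
            scale_k=scale.amplitude("K"),
            wrist_j=wrist.amplitude("J"),
            wrist_k=wrist.amplitude("K"),
            wrist_l=wrist.amplitude("L"),
            note="model",
        )
    except (NoWavesError, MissingWaveError):
        return None


@dataclass(frozen=True)
class CalibrationProblem:
    """Specification of one calibration run."""

    bp: AorticPressureSet
    geom: AortaGeometry
    body: BodyParameters
    targets: AmplitudeTargets
    free: tuple = ("c14", "c5", "k5")
    bounds_factor: tuple = (0.05, 20.0)  # multiplicative bounds around nominal

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter set must be non-empty")
        lo, hi = self.bounds_factor
        if not (0 < lo < hi):
            raise ValueError("bounds must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class CalibrationResult:
    fitted: BodyParameters
    final_penalty: float
    trace: tuple = field(default_factory=tuple)  # per-start (x0, x_best, penalty)
    n_flagged: int = 0  # trials with undetectable waves


def calibrate(
    problem: CalibrationProblem,
    initial_guess: dict[str, float] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    xatol: float = 1e-6,
    fatol: float = 1e-12,
) -> CalibrationResult:
    """Fit the free parameters by seeded multistart Nelder-Mead in log-space.

    The first start is the initial guess (nominal values by default); the
    remaining starts jitter it by seeded log-uniform factors in [1/3, 3],
    clipped to the bounds.  Trials where any wave becomes undetectable are
    penalized with a large finite value and counted, not raised.
    """
    free = problem.free
    nominal = np.array([getattr(problem.body, name) for name in free])
    guess = np.array([(initial_guess or {}).get(name, getattr(problem.body, name)) for name in free])
    lo, hi = problem.bounds_factor
    log_bounds = [(np.log(v * lo), np.log(v * hi)) for v in nominal]

    cache: dict = {}
    flagged = 0

    def objective(log_x: np.ndarray) -> float:
        nonlocal flagged
        body = problem.body
        for name, lx in zip(free, log_x):
            body = body.with_value(name, float(np.exp(lx)))
        amps = model_amplitudes(body, problem.bp, problem.geom, _cache=cache)
        if amps is None:
            flagged += 1
            return UNDETECTABLE_PENALTY
        return penalty(amps, problem.targets)

    rng = np.random.default_rng(seed)
    starts = [np.log(guess)]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(np.log(1 / 3), np.log(3), size=len(free))
        starts.append(
            np.clip(
                np.log(guess) + jitter,
                [b[0] for b in log_bounds],
                [b[1] for b in log_bounds],
            )
        )

    trace = []
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=log_bounds,
            options={"xatol": xatol, "fatol": fatol, "maxiter": 2000},
        )
        trace.append((np.exp(x0), np.exp(res.x), float(res.fun)))
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)

    fitted = problem.body
    for name, lx in zip(free, best_x):
        fitted = fitted.with_value(name, float(np.exp(lx)))
    return CalibrationResult(
        fitted=fitted, final_penalty=best_f, trace=tuple(trace), n_flagged=flagged
    )
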