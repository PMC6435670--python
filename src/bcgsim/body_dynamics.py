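"""5-DOF lumped-parameter model of BCG transmission through the body.

The body is represented by four lumped masses along the head-to-foot axis —
upper torso (m1), upper limbs (m2), internal organs (m3), lower limbs (m4) —
coupled by viscoelastic (damper + spring) elements on the pairs (1,2), (1,3),
(1,4), (3,4).  A fifth mass m5 models the weighing-scale instrument, coupled to
the lower limbs through (c45, k45) and to the ground through (c5, k5); the
ground spring is the model's only connection to a fixed frame.

The force BCG acts on coordinate 1.  The model's outputs are the scale
displacement (coordinate 5), the wrist displacement (coordinate 2), and the
wrist acceleration (second derivative of coordinate 2).  Positive displacement
is headward.

Parameter defaults are the calibrated values of the underlying experimental
study (stiffnesses printed in kN/m, stored here in N/m).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .force_model import ForceWaveform

__all__ = [
    "OutputChannel",
    "BodyParameters",
    "SecondOrderSystem",
    "assemble",
    "frequency_response",
    "simulate_time",
    "simulate_periodic",
    "ode_oracle",
    "PARAMETER_NAMES",
    "write_bcg_csv",
    "read_body_config",
]

OutputChannel = Literal["scale_disp", "wrist_disp", "wrist_acc"]

#: The 17 tunable parameters of the transfer functions, in canonical order.
PARAMETER_NAMES = (
    "m1", "m2", "m3", "m4", "m5",
    "k12", "k13", "k14", "k34", "k45",
    "c12", "c13", "c14", "c34", "c45",
    "k5", "c5",
)

#: Damper/spring connection topology: coordinate pairs (1-based); 0 = ground.
CONNECTIONS = {
    "12": (1, 2), "13": (1, 3), "14": (1, 4), "34": (3, 4), "45": (4, 5), "5": (5, 0),
}


@dataclass(frozen=True)
class BodyParameters:
    """Masses [kg], dampers [N*s/m] and springs [N/m] of the 5-DOF model."""

    m1: float = 9.0
    m2: float = 8.0
    m3: float = 23.0
    m4: float = 25.0
    m5: float = 2.5
    c12: float = 271.0
    c13: float = 53.0
    c14: float = 1056.0
    c34: float = 32.0
    c45: float = 1141.0
    c5: float = 722.0
    k12: float = 40.7e3
    k13: float = 3.15e3
    k14: float = 31.3e3
    k34: float = 2.28e3
    k45: float = 425.3e3
    k5: float = 833.0e3

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive")

    def with_value(self, name: str, value: float) -> "BodyParameters":
        if name not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: value})


@dataclass(frozen=True)
class SecondOrderSystem:
    """Matrices of M q'' + C q' + K q = b F and the model's output maps."""

    M: np.ndarray  # 5x5 diagonal
    C: np.ndarray  # 5x5 symmetric
    K: np.ndarray  # 5x5 symmetric positive definite
    input_map: np.ndarray  # force enters coordinate 1
    output_maps: dict  # channel -> selection vector over q

    def first_order_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """State-space (A, B) with state [q; q']."""
        minv = 1.0 / np.diag(self.M)
        A = np.zeros((10, 10))
        A[:5, 5:] = np.eye(5)
        A[5:, :5] = -self.K * minv[:, None]
        A[5:, 5:] = -self.C * minv[:, None]
        B = np.zeros(10)
        B[5:] = self.input_map * minv
        return A, B

    def output_matrix(self, channel: OutputChannel) -> np.ndarray:
        """Row vector mapping the first-order state to the requested output."""
        sel = self.output_maps[channel]
        row = np.zeros(10)
        if channel in ("scale_disp", "wrist_disp"):
            row[:5] = sel
            return row
        # acceleration: q'' = M^-1 (-K q - C q' + b F); the force feeds only
        # coordinate 1, so the feedthrough to coordinate 2 is zero.
        minv = 1.0 / np.diag(self.M)
        row[:5] = -(sel * minv) @ self.K
        row[5:] = -(sel * minv) @ self.C
        return row


def _structure_matrix(i: int, j: int) -> np.ndarray:
    """Contribution pattern of a unit spring/damper between coordinates i, j (1-based; j=0 ground)."""
    S = np.zeros((5, 5))
    S[i - 1, i - 1] += 1.0
    if j != 0:
        S[j - 1, j - 1] += 1.0
        S[i - 1, j - 1] -= 1.0
        S[j - 1, i - 1] -= 1.0
    return S


def parameter_structure(name: str) -> tuple[str, np.ndarray]:
    """Which matrix (``M``/``C``/``K``) a parameter enters, and its pattern.

    The derivative of that matrix with respect to the parameter is exactly the
    returned pattern; this is what makes the analytic sensitivity exact.
    """
    if name.startswith("m"):
        i = int(name[1])
        S = np.zeros((5, 5))
        S[i - 1, i - 1] = 1.0
        return "M", S
    kind = "C" if name.startswith("c") else "K"
    pair = CONNECTIONS[name[1:]]
    return kind, _structure_matrix(*pair)


def assemble(params: BodyParameters) -> SecondOrderSystem:
    """Build the mass, damping and stiffness matrices from the parameter set.

    The stiffness row/column structure follows the connection topology: e.g.
    ``K[4,4] = k45 + k5`` (0-based), off-diagonals ``-k_ij`` on connected
    pairs; the damping matrix is identically structured.  The force input
    enters coordinate 1 only.
    """
    params.validate()
    M = np.diag([params.m1, params.m2, params.m3, params.m4, params.m5])
    C = np.zeros((5, 5))
    K = np.zeros((5, 5))
    for suffix, pair in CONNECTIONS.items():
        C += getattr(params, "c" + suffix) * _structure_matrix(*pair)
        K += getattr(params, "k" + suffix) * _structure_matrix(*pair)
    input_map = np.zeros(5)
    input_map[0] = 1.0
    e2 = np.zeros(5)
    e2[1] = 1.0
    e5 = np.zeros(5)
    e5[4] = 1.0
    return SecondOrderSystem(
        M=M,
        C=C,
        K=K,
        input_map=input_map,
        output_maps={"scale_disp": e5, "wrist_disp": e2, "wrist_acc": e2},
    )


def frequency_response(
    sys: SecondOrderSystem, output: OutputChannel, omega: np.ndarray
) -> np.ndarray:
    """Complex gain H(j*omega) from the force to the requested output.

    Evaluates ``out^T (-omega^2 M + j omega C + K)^{-1} in`` by a batched
    linear solve (no explicit inverse); the acceleration channel carries the
    additional ``(j omega)^2 = -omega^2`` factor.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if not np.all(np.isfinite(omega)) or np.any(omega < 0):
        raise ValueError("omega grid must be finite and non-negative")
    Z = (
        -(omega[:, None, None] ** 2) * sys.M
        + 1j * omega[:, None, None] * sys.C
        + sys.K
    )
    x = np.linalg.solve(Z, np.broadcast_to(sys.input_map, (len(omega), 5))[..., None])
    H = (sys.output_maps[output] * x[..., 0]).sum(axis=1)
    if output == "wrist_acc":
        H = H * -(omega**2)
    return H


@dataclass(frozen=True)
class BCGOutputs:
    """Time series of the three model outputs on the driving force's grid."""

    time: np.ndarray
    scale_displacement: np.ndarray  # m, coordinate 5
    wrist_displacement: np.ndarray  # m, coordinate 2
    wrist_acceleration: np.ndarray  # m/s^2, coordinate 2

    def channel(self, name: OutputChannel) -> np.ndarray:
        return {
            "scale_disp": self.scale_displacement,
            "wrist_disp": self.wrist_displacement,
            "wrist_acc": self.wrist_acceleration,
        }[name]


def _check_uniform(time: np.ndarray) -> float:
    dts = np.diff(time)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise ValueError("force grid must be uniform")
    return float(dts[0])


def simulate_time(sys: SecondOrderSystem, force: ForceWaveform) -> BCGOutputs:
    """Simulate the response to a sampled force from rest.

    Uses the exact zero-order-hold discretization (matrix exponential of the
    augmented system), so the result is exact for a piecewise-constant force at
    the sample rate and bit-reproducible at fixed dt.
    """
    dt = _check_uniform(force.time)
    A, B = sys.first_order_matrices()
    aug = np.zeros((11, 11))
    aug[:10, :10] = A
    aug[:10, 10] = B
    Phi = expm(aug * dt)
    Ad, Bd = Phi[:10, :10], Phi[:10, 10]
    u = force.total
    x = np.zeros(10)
    states = np.empty((len(u), 10))
    for k in range(len(u)):
        states[k] = x
        x = Ad @ x + Bd * u[k]
    return _outputs_from_states(sys, force.time, states, u)


def _outputs_from_states(
    sys: SecondOrderSystem, time: np.ndarray, states: np.ndarray, u: np.ndarray
) -> BCGOutputs:
    rows = {ch: sys.output_matrix(ch) for ch in ("scale_disp", "wrist_disp", "wrist_acc")}
    return BCGOutputs(
        time=time,
        scale_displacement=states @ rows["scale_disp"],
        wrist_displacement=states @ rows["wrist_disp"],
        wrist_acceleration=states @ rows["wrist_acc"],
    )


def simulate_periodic(
    sys: SecondOrderSystem, force_one_period: ForceWaveform, period: float
) -> BCGOutputs:
    """Steady-state response to a strictly periodic force, one beat long.

    Computed in the frequency domain: the discrete Fourier coefficients of the
    sampled force are multiplied by the transfer gain at each harmonic
    omega_k = 2*pi*k/period and inverse-transformed.  The gains are those of
    the zero-order-hold discretization, H_d(z_k) = C (z_k I - A_d)^{-1} B_d
    with z_k = exp(j*omega_k*dt), so the result is exactly the long-run limit
    of :func:`simulate_time` (the hold-equivalent gain differs from the
    continuous H(j*omega) only at O(dt)).
    """
    dt = _check_uniform(force_one_period.time)
    n = len(force_one_period.total)
    if abs(period - n * dt) > 1e-9 * period:
        raise ValueError("period must equal an integer number of samples")
    A, B = sys.first_order_matrices()
    aug = np.zeros((11, 11))
    aug[:10, :10] = A
    aug[:10, 10] = B
    Phi = expm(aug * dt)
    Ad, Bd = Phi[:10, :10], Phi[:10, 10]
    spec = np.fft.rfft(force_one_period.total)
    z = np.exp(2j * np.pi * np.arange(n // 2 + 1) / n)
    # batched resolvent: X_k = (z_k I - Ad)^{-1} Bd
    lhs = z[:, None, None] * np.eye(10) - Ad
    X = np.linalg.solve(lhs, np.broadcast_to(Bd, (len(z), 10))[..., None])[..., 0]
    out = {}
    for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
        Hd = X @ sys.output_matrix(ch)
        out[ch] = np.fft.irfft(spec * Hd, n=n)
    return BCGOutputs(
        time=force_one_period.time,
        scale_displacement=out["scale_disp"],
        wrist_displacement=out["wrist_disp"],
        wrist_acceleration=out["wrist_acc"],
    )


def ode_oracle(
    sys: SecondOrderSystem,
    force: ForceWaveform,
    rtol: float = 1e-9,
    atol: float = 1e-14,
    t_eval: np.ndarray | None = None,
) -> BCGOutputs:
    """Adaptive-step integration of the first-order form; verification only.

    Holds the force piecewise-constant between samples (matching the
    zero-order-hold convention) and integrates with an adaptive Runge-Kutta
    scheme; ``max_step`` is capped at the sample interval so no step straddles
    more than one input discontinuity.  Non-authoritative: an independent
    cross-check of :func:`simulate_time`.  ``t_eval`` restricts the output
    grid (a subset of the force grid) to keep long verification runs cheap.
    """
    dt = _check_uniform(force.time)
    A, B = sys.first_order_matrices()
    u = force.total
    t0 = float(force.time[0])
    if t_eval is None:
        t_eval = force.time

    def u_of_t(t: float) -> float:
        k = min(int(np.floor((t - t0) / dt + 1e-12)), len(u) - 1)
        return u[max(k, 0)]

    def rhs(t, x):
        return A @ x + B * u_of_t(t)

    sol = solve_ivp(
        rhs,
        (t0, float(force.time[-1])),
        np.zeros(10),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=dt,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    idx = np.searchsorted(force.time, sol.t)
    return _outputs_from_states(sys, np.asarray(sol.t), sol.y.T, u[idx])


def write_bcg_csv(out: BCGOutputs, path) -> None:
    pd.DataFrame(
        {
            "time_s": out.time,
            "scale_disp_m": out.scale_displacement,
            "wrist_disp_m": out.wrist_displacement,
            "wrist_acc_mps2": out.wrist_acceleration,
        }
    ).to_csv(path, index=False, float_format="%.12e")


def read_body_config(mapping: dict) -> BodyParameters:
    """Build parameters from a flat key-value mapping in printed units.

    Keys are the canonical names (``m1..m5``, ``c12..c5``, ``k12..k5``); masses
    in kg, dampers in N*s/m, springs in kN/m (converted to N/m at load time).
    Missing keys keep their defaults.
    """
    kwargs = {}
    valid = {f.name for f in fields(BodyParameters)}
    for key, value in mapping.items():
        if key not in valid:
            raise KeyError(f"unknown body parameter {key!r}")
        value = float(value)
        if key.startswith("k"):
            value *= 1e3
        kwargs[key] = value
    return BodyParameters(**kwargs)
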