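"""Synthesis, perturbation, standardization and I/O of aortic blood-pressure waves.

The body model is driven by three blood-pressure (BP) waveforms sampled along the
aorta: at the aortic inlet (``P0``), the aortic arch (``P1``) and the aortic outlet
(``P2``).  Clinical recordings of this triple are rarely available, so this module
provides a parametric generator that emulates their salient features: periodic
beats, site-specific diastolic level and pulse amplitude, inlet-to-arch and
inlet-to-outlet transit delays, pulse-pressure amplification toward the outlet,
and optional seeded inter-subject variability.

Pressures are expressed in mmHg throughout; conversion to SI happens only inside
the force computation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "PressureWave",
    "AorticPressureSet",
    "BPGeneratorParams",
    "generate_bp_set",
    "perturb_pwv",
    "perturb_ppa",
    "rescale_wave",
    "beat_template",
    "read_bp_csv",
    "write_bp_csv",
]

SITES = ("inlet", "arch", "outlet")

#: Relative amplitude of the smooth sin^2 diastolic-baseline term of the beat
#: template.  Gives the wave a unique per-period minimum located exactly at the
#: beat foot (see :func:`beat_template`).
DIASTOLIC_CURVATURE = 0.05


class DelayOverlapError(ValueError):
    """Transit delay reaches or exceeds the cardiac period."""


class ResolutionError(ValueError):
    """Sampling interval too coarse to resolve the beat."""


class NonUniformGridError(ValueError):
    """Time grid is not uniformly sampled."""


class FormatError(ValueError):
    """CSV file does not conform to the documented dialect."""


class DegenerateScalingError(ValueError):
    """Constant pressure wave cannot be rescaled to distinct mean/diastolic targets."""


@dataclass(frozen=True)
class PressureWave:
    """A sampled periodic pressure waveform at one aortic site.

    Attributes
    ----------
    time : ndarray
        Uniform time grid in seconds covering one or more full cardiac periods.
    values : ndarray
        Pressure in mmHg, strictly positive.
    period : float
        Cardiac period in seconds.
    site : str
        One of ``inlet``, ``arch``, ``outlet``.
    """

    time: np.ndarray
    values: np.ndarray
    period: float
    site: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.time.shape != self.values.shape or self.time.ndim != 1:
            raise ValueError("time and values must be 1-D arrays of equal length")
        dts = np.diff(self.time)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise NonUniformGridError(f"non-uniform time grid for site {self.site}")
        if np.any(self.values <= 0):
            raise ValueError("pressure values must be strictly positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def samples_per_period(self) -> int:
        return int(round(self.period / self.dt))


@dataclass(frozen=True)
class AorticPressureSet:
    """The inlet/arch/outlet pressure triple on a shared time grid."""

    p0: PressureWave
    p1: PressureWave
    p2: PressureWave

    def __post_init__(self) -> None:
        for w in (self.p1, self.p2):
            if w.time.shape != self.p0.time.shape or not np.array_equal(w.time, self.p0.time):
                raise ValueError("all three waves must share the same time grid")
            if w.period != self.p0.period:
                raise ValueError("all three waves must share the same period")

    @property
    def time(self) -> np.ndarray:
        return self.p0.time

    @property
    def period(self) -> float:
        return self.p0.period

    @property
    def dt(self) -> float:
        return self.p0.dt

    def waves(self) -> tuple[PressureWave, PressureWave, PressureWave]:
        return (self.p0, self.p1, self.p2)


def _default_site_map(inlet: float, arch: float, outlet: float) -> dict[str, float]:
    return {"inlet": inlet, "arch": arch, "outlet": outlet}


@dataclass(frozen=True)
class BPGeneratorParams:
    """Parameters of the synthetic aortic-pressure generator.

    Defaults emulate a representative resting adult: 60 bpm, diastolic 70 mmHg at
    all sites, pulse pressure rising from 40 mmHg at the inlet to 48 mmHg at the
    outlet (pulse-pressure amplification), and beat feet delayed by 20 ms
    (inlet to arch) and 90 ms (inlet to outlet) — transit times consistent with
    aortic pulse wave velocities of a few m/s.
    """

    heart_rate: float = 60.0  # beats/min
    diastolic: Mapping[str, float] = field(
        default_factory=lambda: _default_site_map(70.0, 70.0, 70.0)
    )  # mmHg
    pulse_pressure: Mapping[str, float] = field(
        default_factory=lambda: _default_site_map(40.0, 42.0, 48.0)
    )  # mmHg
    tau01: float = 0.020  # s, inlet -> arch foot delay
    tau02: float = 0.090  # s, inlet -> outlet foot delay
    time_to_peak: Mapping[str, float] = field(
        default_factory=lambda: _default_site_map(0.10, 0.10, 0.11)
    )  # s
    dicrotic_fraction: Mapping[str, float] = field(
        default_factory=lambda: _default_site_map(0.2, 0.2, 0.2)
    )
    n_beats: int = 10
    dt: float = 0.001  # s
    variability_cv: float = 0.0
    seed: int = 0

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def validate(self) -> None:
        if not (0.0 < self.tau01 < self.tau02):
            raise ValueError("delays must satisfy 0 < tau01 < tau02")
        if self.tau02 >= self.period:
            raise DelayOverlapError(
                f"tau02={self.tau02} s reaches the cardiac period {self.period} s"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt >= self.period / 50:
            raise ResolutionError(
                f"dt={self.dt} s too coarse: need at least 50 samples per period"
            )
        if self.variability_cv < 0:
            raise ValueError("variability_cv must be non-negative")
        if any(self.pulse_pressure[s] < 0 for s in SITES):
            raise ValueError("pulse_pressure must be non-negative at every site")
        if any(self.time_to_peak[s] <= 0 for s in SITES):
            raise ValueError("time_to_peak must be strictly positive at every site")
        if any(self.diastolic[s] <= 0 for s in SITES):
            raise ValueError("diastolic must be strictly positive at every site")


def _raised_cosine(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Raised-cosine lobe: peak 1 at `center`, support [center-hw, center+hw]."""
    x = (t - center) / half_width
    lobe = 0.5 * (1.0 + np.cos(np.pi * x))
    return np.where(np.abs(x) < 1.0, lobe, 0.0)


def beat_template(
    t: np.ndarray, period: float, time_to_peak: float, dicrotic_fraction: float
) -> np.ndarray:
    """Unit-amplitude pressure-beat shape, periodic with the cardiac period.

    The template is the sum of three smooth terms, evaluated at ``t mod period``:

    * a systolic raised-cosine lobe peaking at ``time_to_peak`` with support
      ``[0, 2*time_to_peak]``;
    * a dicrotic raised-cosine lobe of relative amplitude ``dicrotic_fraction``
      peaking at ``2.2*time_to_peak`` with the same width;
    * a low sin^2(pi*t/period) diastolic-baseline term (relative amplitude
      0.05) which is C1-periodic and vanishes only at the beat foot ``t = 0``,
      so each period has a unique minimum located exactly at the foot.

    The sum is normalized so its maximum is 1 and its minimum 0; a wave built as
    ``diastolic + pulse_pressure * template`` therefore has exactly the requested
    diastolic level and pulse amplitude.
    """
    tm = np.mod(t, period)
    g = _raised_cosine(tm, time_to_peak, time_to_peak)
    g = g + dicrotic_fraction * _raised_cosine(tm, 2.2 * time_to_peak, time_to_peak)
    g = g + DIASTOLIC_CURVATURE * np.sin(np.pi * tm / period) ** 2
    peak = np.max(g) if g.size else 1.0
    if peak > 0:
        g = g / peak
    return g


def _draw_subject_factors(params: BPGeneratorParams) -> dict[str, float]:
    """Seeded multiplicative log-normal factors (mean 1, CV=variability_cv)."""
    rng = np.random.default_rng(params.seed)
    cv = params.variability_cv
    names = [f"pp_{s}" for s in SITES] + ["tau01", "tau02"] + [f"ttp_{s}" for s in SITES]
    if cv == 0.0:
        return {n: 1.0 for n in names}
    sigma = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sigma**2  # mean-1 log-normal
    draws = rng.lognormal(mean=mu, sigma=sigma, size=len(names))
    return dict(zip(names, draws))


def generate_bp_set(params: BPGeneratorParams) -> AorticPressureSet:
    """Generate the inlet/arch/outlet pressure triple from generator parameters.

    Each site's wave is ``diastolic + pulse_pressure * g(t - tau_site)`` where
    ``g`` is :func:`beat_template` and ``tau_site`` is 0, ``tau01``, ``tau02``
    for the inlet, arch and outlet.  With ``variability_cv > 0``, the pulse
    pressures, delays and times-to-peak are scaled by seeded log-normal factors
    before synthesis (identical seed, identical output).
    """
    params.validate()
    f = _draw_subject_factors(params)
    tau01 = params.tau01 * f["tau01"]
    tau02 = params.tau02 * f["tau02"]
    if not (0.0 < tau01 < tau02 < params.period):
        raise DelayOverlapError("subject-level delay draw violates 0 < tau01 < tau02 < period")

    n = int(round(params.period * params.n_beats / params.dt))
    t = np.arange(n) * params.dt
    delays = {"inlet": 0.0, "arch": tau01, "outlet": tau02}
    waves = {}
    for site in SITES:
        pp = params.pulse_pressure[site] * f[f"pp_{site}"]
        ttp = params.time_to_peak[site] * f[f"ttp_{site}"]
        g = beat_template(t - delays[site], params.period, ttp, params.dicrotic_fraction[site])
        waves[site] = PressureWave(
            time=t,
            values=params.diastolic[site] + pp * g,
            period=params.period,
            site=site,
        )
    return AorticPressureSet(p0=waves["inlet"], p1=waves["arch"], p2=waves["outlet"])


def perturb_pwv(params: BPGeneratorParams, fraction: float) -> BPGeneratorParams:
    """Scale both transit delays by ``(1 - fraction)``.

    A positive fraction shortens the delays, i.e. emulates a faster aortic pulse
    wave velocity; all other generator fields are unchanged.
    """
    if abs(fraction) > 0.5:
        raise ValueError("|fraction| must be <= 0.5")
    scale = 1.0 - fraction
    new_tau01 = params.tau01 * scale
    new_tau02 = params.tau02 * scale
    if new_tau01 <= 0:
        raise ValueError("perturbation drives tau01 non-positive")
    return replace(params, tau01=new_tau01, tau02=new_tau02)


def perturb_ppa(params: BPGeneratorParams, fraction: float) -> BPGeneratorParams:
    """Scale the outlet pulse pressure by ``(1 + fraction)``.

    Emulates a change in pulse-pressure amplification: the outlet pulse
    amplitude changes while the inlet and arch pulse amplitudes, all delays and
    all diastolic levels are unchanged.
    """
    if abs(fraction) > 0.5:
        raise ValueError("|fraction| must be <= 0.5")
    pp = dict(params.pulse_pressure)
    pp["outlet"] = pp["outlet"] * (1.0 + fraction)
    return replace(params, pulse_pressure=pp)


def rescale_wave(
    wave: PressureWave, target_mean: float, target_diastolic: float
) -> PressureWave:
    """Affinely standardize a wave to a target mean and diastolic (minimum) level.

    Returns ``a*P + b`` with ``a > 0`` chosen so the output mean equals
    ``target_mean`` and the output minimum equals ``target_diastolic``.
    """
    if target_mean <= target_diastolic:
        raise ValueError("target_mean must exceed target_diastolic")
    mean = float(np.mean(wave.values))
    vmin = float(np.min(wave.values))
    if mean - vmin < 1e-12 * max(1.0, abs(mean)):
        raise DegenerateScalingError("constant wave cannot be rescaled")
    a = (target_mean - target_diastolic) / (mean - vmin)
    b = target_diastolic - a * vmin
    return replace(wave, values=a * wave.values + b)


# ---------------------------------------------------------------------------
# CSV dialect: header `time_s,p0_mmhg,p1_mmhg,p2_mmhg`, optional metadata line
# `# period_s=<float>` before the header.
# ---------------------------------------------------------------------------

_BP_COLUMNS = ("time_s", "p0_mmhg", "p1_mmhg", "p2_mmhg")


def write_bp_csv(bp: AorticPressureSet, path) -> None:
    """Write a pressure set in the documented CSV dialect."""
    df = pd.DataFrame(
        {
            "time_s": bp.time,
            "p0_mmhg": bp.p0.values,
            "p1_mmhg": bp.p1.values,
            "p2_mmhg": bp.p2.values,
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# period_s={bp.period!r}\n")
        df.to_csv(fh, index=False, float_format="%.12e")


def read_bp_csv(path) -> AorticPressureSet:
    """Read a pressure set written by :func:`write_bp_csv`.

    Columns are matched by name (any order).  The time grid must be uniform;
    violations raise :class:`FormatError` or :class:`NonUniformGridError`
    naming the offending row or column.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    period = None
    lines = text.splitlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("# ").strip()
            if stripped.startswith("period_s="):
                period = float(stripped.split("=", 1)[1])
        else:
            data_start = i
            break
    try:
        df = pd.read_csv(io.StringIO("\n".join(lines[data_start:])))
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"cannot parse CSV body: {exc}") from exc
    missing = [c for c in _BP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    for col in _BP_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.argmax((numeric.isna()).to_numpy()))
            raise FormatError(f"non-numeric cell in column {col!r} at data row {row}")
        df[col] = numeric
    t = df["time_s"].to_numpy(float)
    dts = np.diff(t)
    if len(dts) == 0:
        raise FormatError("file contains fewer than two samples")
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        row = int(np.argmax(~np.isclose(dts, dts[0], rtol=1e-9, atol=1e-12))) + 1
        raise NonUniformGridError(f"non-uniform time grid at data row {row}")
    if period is None:
        period = float(t[-1] + dts[0] - t[0])
    waves = {}
    for site, col in zip(SITES, _BP_COLUMNS[1:]):
        waves[site] = PressureWave(
            time=t, values=df[col].to_numpy(float), period=period, site=site
        )
    return AorticPressureSet(p0=waves["inlet"], p1=waves["arch"], p2=waves["outlet"])
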