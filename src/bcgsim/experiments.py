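"""End-to-end studies: steady-state beats, decomposition, PWV/PPA sweeps, cohorts.

This module wires the pipeline together: generate (or accept) aortic pressure
waves, evaluate the force model, simulate the steady-state beat of the 5-DOF
body model, detect the named BCG waves and tabulate morphometry.  On top of the
pipeline it implements the three analyses of interest:

* gradient decomposition — by linearity, the limb BCG splits exactly into the
  responses to the ascending (P0-P1) and descending (P1-P2) aortic pressure
  gradients simulated one at a time;
* pulse-wave-velocity (PWV) and pulse-pressure-amplification (PPA) sweeps —
  regenerate the pressure waves with delays / outlet amplitude perturbed by a
  fraction grid and track how wave intervals and amplitudes respond;
* cohort simulation — seeded inter-subject variability, summarized as
  mean +/- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .aortic_input import (
    AorticPressureSet,
    BPGeneratorParams,
    generate_bp_set,
    perturb_ppa,
    perturb_pwv,
)
from .body_dynamics import BCGOutputs, BodyParameters, assemble, simulate_periodic
from .fiducials import (
    FiducialSet,
    MissingWaveError,
    MorphometryTable,
    NoWavesError,
    detect_acceleration_waves,
    detect_displacement_waves,
    intervals_amplitudes,
    summarize_cohort,
)
from .force_model import AortaGeometry, ForceWaveform, compute_force_bcg, decompose_force

__all__ = [
    "BeatResult",
    "DecompositionResult",
    "SweepResult",
    "CohortResult",
    "extract_period_force",
    "roll_to_onset",
    "simulate_steady_beat",
    "detect_beat_waves",
    "beat_morphometry",
    "run_decomposition",
    "run_sweep",
    "run_cohort",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(-0.2, 0.2001, 0.05), 10))

CHANNELS = ("scale_disp", "wrist_disp", "wrist_acc")


def extract_period_force(force: ForceWaveform, period: float) -> ForceWaveform:
    """First full period of a (periodic) force waveform."""
    n = int(round(period / force.dt))
    if n > len(force.total):
        raise ValueError("force shorter than one period")
    return ForceWaveform(
        time=force.time[:n] - force.time[0],
        total=force.total[:n],
        ascending_component=force.ascending_component[:n],
        descending_component=force.descending_component[:n],
    )


def roll_to_onset(force: ForceWaveform, onset: int | None = None) -> tuple[ForceWaveform, int]:
    """Roll a one-period force so the beat starts at the force onset.

    The window is anchored on the global maximum of the pulsatile
    (mean-removed) total force — the main systolic force peak — placed at 15%
    of the window, so the window opens in the quiescent diastolic stretch just
    before the systolic recoil dip.  This keeps the whole I-J-K response
    sequence inside one window (hence "preceding/following" well defined for
    wave labeling) and, unlike a zero-crossing anchor, stays continuous under
    timing and amplitude perturbations of the pressure waves.  An explicit
    onset index may be supplied to align component forces with the total's
    window.
    """
    if onset is None:
        fp = force.total - np.mean(force.total)
        n = len(fp)
        onset = (int(np.argmax(fp)) - int(round(0.15 * n))) % n
    return (
        ForceWaveform(
            time=force.time,
            total=np.roll(force.total, -onset),
            ascending_component=np.roll(force.ascending_component, -onset),
            descending_component=np.roll(force.descending_component, -onset),
        ),
        onset,
    )


@dataclass(frozen=True)
class BeatResult:
    """One steady-state beat: rolled force, zero-mean outputs, period."""

    force: ForceWaveform
    outputs: BCGOutputs
    period: float
    onset: int


def _zero_mean(out: BCGOutputs) -> BCGOutputs:
    return BCGOutputs(
        time=out.time,
        scale_displacement=out.scale_displacement - np.mean(out.scale_displacement),
        wrist_displacement=out.wrist_displacement - np.mean(out.wrist_displacement),
        wrist_acceleration=out.wrist_acceleration - np.mean(out.wrist_acceleration),
    )


def simulate_steady_beat(
    bp: AorticPressureSet,
    geom: AortaGeometry,
    body: BodyParameters,
    force_override: ForceWaveform | None = None,
    onset: int | None = None,
) -> BeatResult:
    """Simulate one steady-state BCG beat from a pressure set.

    The force is evaluated, truncated to one period, rolled to the force onset
    and fed to the frequency-domain steady-state solver; output channels are
    returned zero-mean (displacements oscillate about static equilibrium).
    """
    force = force_override if force_override is not None else compute_force_bcg(bp, geom)
    one = extract_period_force(force, bp.period)
    rolled, onset = roll_to_onset(one, onset)
    out = simulate_periodic(assemble(body), rolled, bp.period)
    return BeatResult(force=rolled, outputs=_zero_mean(out), period=bp.period, onset=onset)


def detect_beat_waves(beat: BeatResult) -> dict[str, FiducialSet]:
    """Label the named waves on all three channels of a steady-state beat."""
    t = beat.outputs.time
    return {
        "scale_disp": detect_displacement_waves(t, beat.outputs.scale_displacement, "scale_disp"),
        "wrist_disp": detect_displacement_waves(t, beat.outputs.wrist_displacement, "wrist_disp"),
        "wrist_acc": detect_acceleration_waves(t, beat.outputs.wrist_acceleration, "wrist_acc"),
    }


#: Wave-to-wave pairs tabulated per channel in sweeps and cohorts.
_PAIRS = {
    "scale_disp": (("I", "J"), ("J", "K"), ("I", "K")),
    "wrist_acc": (("J", "K"), ("K", "L"), ("J", "L")),
}
_SINGLE = {"scale_disp": ("I", "J", "K"), "wrist_acc": ("J", "K", "L")}


def beat_morphometry(fids: dict[str, FiducialSet]) -> dict[str, float]:
    """Flatten intervals, pair amplitudes and single-wave amplitudes into one row."""
    row: dict[str, float] = {}
    for channel, prefix in (("scale_disp", "scale"), ("wrist_acc", "wrist")):
        fset = fids[channel]
        for key, val in intervals_amplitudes(fset, _PAIRS[channel]).items():
            row[f"{prefix}_{key}"] = val
        for label in _SINGLE[channel]:
            row[f"{prefix}_{label}_amp"] = fset.amplitude(label)
    return row


@dataclass(frozen=True)
class DecompositionResult:
    """Total / ascending-driven / descending-driven responses per channel."""

    time: np.ndarray
    total: BCGOutputs
    ascending: BCGOutputs
    descending: BCGOutputs
    force: ForceWaveform

    def channels(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            ch: {
                "total": self.total.channel(ch),
                "ascending": self.ascending.channel(ch),
                "descending": self.descending.channel(ch),
            }
            for ch in CHANNELS
        }


def run_decomposition(
    bp: AorticPressureSet, geom: AortaGeometry, body: BodyParameters
) -> DecompositionResult:
    """Decompose the steady-state BCG into its two gradient-driven components.

    Simulates the body model once per force component and once for the total,
    all in the same beat window, and verifies the superposition identity
    (ascending + descending = total) before returning.
    """
    total_beat = simulate_steady_beat(bp, geom, body)
    asc_force, desc_force = decompose_force(bp, geom)
    asc_beat = simulate_steady_beat(bp, geom, body, force_override=asc_force, onset=total_beat.onset)
    desc_beat = simulate_steady_beat(bp, geom, body, force_override=desc_force, onset=total_beat.onset)
    for ch in CHANNELS:
        tot = total_beat.outputs.channel(ch)
        recon = asc_beat.outputs.channel(ch) + desc_beat.outputs.channel(ch)
        scale = np.max(np.abs(tot))
        if scale > 0 and np.max(np.abs(recon - tot)) > 1e-10 * scale:
            raise AssertionError(f"superposition violated on channel {ch}")
    return DecompositionResult(
        time=total_beat.outputs.time,
        total=total_beat.outputs,
        ascending=asc_beat.outputs,
        descending=desc_beat.outputs,
        force=total_beat.force,
    )


@dataclass(frozen=True)
class SweepResult:
    """Morphometry versus perturbation fraction for one perturbation kind."""

    kind: str  # "pwv" or "ppa"
    fractions: tuple
    table: pd.DataFrame  # indexed by fraction; NaN rows where waves were lost
    missing: tuple  # fractions where wave detection failed

    @property
    def reference(self) -> pd.Series:
        return self.table.loc[0.0]


def run_sweep(
    gen_params: BPGeneratorParams,
    kind: str,
    geom: AortaGeometry | None = None,
    body: BodyParameters | None = None,
    fractions=DEFAULT_FRACTIONS,
) -> SweepResult:
    """Sweep a PWV or PPA perturbation over a fraction grid.

    For each fraction the pressure set is regenerated from perturbed generator
    parameters (delays scaled by ``1 - f`` for PWV; outlet pulse pressure by
    ``1 + f`` for PPA), the steady-state beat simulated, waves detected, and
    intervals/amplitudes tabulated.  Fractions where a required wave is lost
    are flagged and skipped, not fatal.
    """
    if kind not in ("pwv", "ppa"):
        raise ValueError("kind must be 'pwv' or 'ppa'")
    geom = geom or AortaGeometry()
    body = body or BodyParameters()
    perturb = perturb_pwv if kind == "pwv" else perturb_ppa
    fractions = tuple(sorted(fractions))
    rows, missing = {}, []
    for frac in fractions:
        perturbed = perturb(gen_params, float(frac))
        bp = generate_bp_set(perturbed)
        beat = simulate_steady_beat(bp, geom, body)
        try:
            rows[frac] = beat_morphometry(detect_beat_waves(beat))
        except (NoWavesError, MissingWaveError):
            missing.append(frac)
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "fraction"
    return SweepResult(kind=kind, fractions=fractions, table=table, missing=tuple(missing))


@dataclass(frozen=True)
class CohortResult:
    """Cohort morphometry summary plus the excluded-subject count."""

    morphometry: MorphometryTable
    n_excluded: int
    subject_seeds: tuple


def run_cohort(
    gen_params: BPGeneratorParams,
    n_subjects: int,
    seed: int,
    geom: AortaGeometry | None = None,
    body: BodyParameters | None = None,
) -> CohortResult:
    """Simulate a cohort of subjects with seeded inter-subject variability.

    Each subject draws its own generator seed from a root seed sequence, so the
    whole cohort is reproducible from ``seed``.  Subjects in which a required
    wave is undetectable are excluded and counted.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    geom = geom or AortaGeometry()
    body = body or BodyParameters()
    child_seeds = tuple(
        int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n_subjects)
    )
    rows, excluded = [], 0
    for s in child_seeds:
        subject = replace(gen_params, seed=s)
        bp = generate_bp_set(subject)
        beat = simulate_steady_beat(bp, geom, body)
        try:
            rows.append(beat_morphometry(detect_beat_waves(beat)))
        except (NoWavesError, MissingWaveError):
            excluded += 1
    if len(rows) < 2:
        raise NoWavesError("fewer than two subjects with detectable waves")
    return CohortResult(
        morphometry=summarize_cohort(rows), n_excluded=excluded, subject_seeds=child_seeds
    )
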