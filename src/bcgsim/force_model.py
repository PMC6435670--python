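"""Force ballistocardiogram from aortic pressure gradients.

The net head-to-foot force the circulating blood exerts on the body is modeled
as the area-weighted sum of two aortic pressure gradients:

    F(t) = A_D * [P1(t) - P2(t)] - A_A * [P0(t) - P1(t)]

with A_A and A_D the ascending- and descending-aortic cross-sectional areas.
Because the expression is linear, the force splits exactly into an ascending
component (driven by P0 - P1) and a descending component (driven by P1 - P2);
downstream responses to each component superpose to the total response.

Pressures enter in mmHg and are converted to Pa internally; forces are in N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aortic_input import AorticPressureSet

__all__ = [
    "MMHG_TO_PA",
    "AortaGeometry",
    "ForceWaveform",
    "compute_force_bcg",
    "decompose_force",
    "write_force_csv",
]

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class AortaGeometry:
    """Ascending / descending aortic cross-sectional areas in m^2.

    Defaults correspond to typical adult aortic diameters of about 2.5 cm
    (ascending) and 2.0 cm (descending) and are documented stand-ins; absolute
    BCG amplitudes scale proportionally with them.
    """

    area_ascending: float = 5.0e-4
    area_descending: float = 3.2e-4

    def __post_init__(self) -> None:
        for name, a in (
            ("area_ascending", self.area_ascending),
            ("area_descending", self.area_descending),
        ):
            if not (1e-5 < a < 2e-3):
                raise ValueError(f"{name}={a} m^2 outside the (1e-5, 2e-3) sanity band")


@dataclass(frozen=True)
class ForceWaveform:
    """Force BCG in newtons with its two gradient components.

    ``total == ascending_component + descending_component`` at every sample.
    """

    time: np.ndarray
    total: np.ndarray
    ascending_component: np.ndarray
    descending_component: np.ndarray

    def __post_init__(self) -> None:
        n = self.time.shape
        for arr in (self.total, self.ascending_component, self.descending_component):
            if arr.shape != n:
                raise ValueError("all force channels must share the time grid")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


def compute_force_bcg(bp: AorticPressureSet, geom: AortaGeometry) -> ForceWaveform:
    """Evaluate the two-gradient force model on a pressure set.

    The descending component is ``A_D * (P1 - P2)`` and the ascending component
    is ``-A_A * (P0 - P1)`` (both converted from mmHg to Pa); the total is their
    sum.  The output is on the input time grid.
    """
    p0, p1, p2 = (w.values for w in bp.waves())
    asc = -geom.area_ascending * (p0 - p1) * MMHG_TO_PA
    desc = geom.area_descending * (p1 - p2) * MMHG_TO_PA
    return ForceWaveform(
        time=bp.time,
        total=asc + desc,
        ascending_component=asc,
        descending_component=desc,
    )


def decompose_force(
    bp: AorticPressureSet, geom: AortaGeometry
) -> tuple[ForceWaveform, ForceWaveform]:
    """Split the force into its ascending-only and descending-only waveforms.

    Each returned waveform has its ``total`` equal to one component (the other
    component channel is zero); their sample-wise sum equals
    :func:`compute_force_bcg`'s total exactly.
    """
    full = compute_force_bcg(bp, geom)
    zeros = np.zeros_like(full.total)
    ascending = ForceWaveform(
        time=full.time,
        total=full.ascending_component,
        ascending_component=full.ascending_component,
        descending_component=zeros,
    )
    descending = ForceWaveform(
        time=full.time,
        total=full.descending_component,
        ascending_component=zeros,
        descending_component=full.descending_component,
    )
    return ascending, descending


def write_force_csv(force: ForceWaveform, path) -> None:
    pd.DataFrame(
        {
            "time_s": force.time,
            "f_total_n": force.total,
            "f_asc_n": force.ascending_component,
            "f_desc_n": force.descending_component,
        }
    ).to_csv(path, index=False, float_format="%.12e")
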