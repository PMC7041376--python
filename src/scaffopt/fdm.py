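"""FDM process planning: nozzle choice, flow rate and slice height for a
target strand diameter.

A strand thinner than the nozzle bore is obtained by under-extruding: with
``D_n`` the nozzle diameter, ``v_h`` the filament feed speed in the nozzle
and ``v_n`` the travel speed of the head, volume conservation of the melt,

    D_n^2 * v_n = D^2 * v_h,    v_n = (f/100) * v_h,

fixes the flow-rate percentage f = 100 * (D/D_n)^2.  Slicers take f as an
integer percentage; the value is truncated toward zero (76.5625 -> 76).  The
slice height is reduced along with the strand diameter so the deposited
strand stays nearly cylindrical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PrintPlan",
    "flow_rate",
    "select_nozzle",
    "build_print_plan",
    "DEFAULT_NOZZLES_UM",
]

#: Commercially available Ultimaker nozzle bores, um.
DEFAULT_NOZZLES_UM = (400.0, 800.0)

_FLOAT_GUARD = 1e-9  # absorb binary representation error before truncating


@dataclass(frozen=True)
class PrintPlan:
    """Process parameters to print strands of diameter ``D_um``."""

    D_um: float
    D_n_um: float
    flow_rate_percent: int
    v_h_mm_s: float = 40.0            # filament speed in the nozzle
    slice_height_um: float = 0.0
    extrusion_temp_C: float = 180.0
    bed_temp_C: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.flow_rate_percent <= 100:
            raise ValueError("flow rate must be in (0, 100] percent")
        if self.D_um > self.D_n_um:
            raise ValueError("strand cannot be thicker than the nozzle bore")
        if self.slice_height_um > self.D_n_um:
            raise ValueError("slice height cannot exceed the nozzle bore")

    @property
    def v_n_mm_s(self) -> float:
        """Extrusion-head travel speed, mm/s."""
        return self.flow_rate_percent / 100.0 * self.v_h_mm_s


def flow_rate(D_um: float, D_n_um: float) -> int:
    """Integer flow-rate percentage to print diameter ``D`` from nozzle ``D_n``.

    f = floor(100 * (D/D_n)^2); equals 100 exactly when D == D_n.  Raises if
    D exceeds the nozzle bore (under-extrusion can only thin a strand).
    """
    if D_um <= 0:
        raise ValueError("strand diameter must be positive")
    if D_um > D_n_um:
        raise ValueError(
            f"D={D_um} um exceeds nozzle bore D_n={D_n_um} um: cannot thicken"
        )
    return int(math.floor(100.0 * (D_um / D_n_um) ** 2 + _FLOAT_GUARD))


def select_nozzle(D_um: float, available_um=DEFAULT_NOZZLES_UM) -> float:
    """Smallest available nozzle bore that can print diameter ``D``.

    An exact match wins; otherwise the smallest bore >= D (a larger bore
    under-extrudes down to D, a smaller one cannot reach it).
    """
    if not available_um:
        raise ValueError("no nozzles available")
    feasible = [dn for dn in available_um if dn >= D_um]
    if not feasible:
        raise ValueError(
            f"no nozzle can print D={D_um} um (largest bore "
            f"{max(available_um)} um)"
        )
    return float(min(feasible))


def build_print_plan(
    D_um: float,
    available_um=DEFAULT_NOZZLES_UM,
    v_h_mm_s: float = 40.0,
    extrusion_temp_C: float = 180.0,
    bed_temp_C: float = 50.0,
) -> PrintPlan:
    """Full process plan for a target strand diameter.

    Slice height follows the strand diameter (a full-bore strand is printed
    at slice height D_n = D; an under-extruded strand at its own, reduced D).
    """
    if D_um <= 0:
        raise ValueError("strand diameter must be positive")
    D_n = select_nozzle(D_um, available_um)
    f = flow_rate(D_um, D_n)
    return PrintPlan(
        D_um=D_um,
        D_n_um=D_n,
        flow_rate_percent=f,
        v_h_mm_s=v_h_mm_s,
        slice_height_um=D_um,
        extrusion_temp_C=extrusion_temp_C,
        bed_temp_C=bed_temp_C,
    )


def plan_as_text(plan: PrintPlan) -> str:
    """Key-value text block (loadable as config by the geometry CLI)."""
    lines = [
        f"D_um = {plan.D_um:g}",
        f"D_n_um = {plan.D_n_um:g}",
        f"flow_rate_percent = {plan.flow_rate_percent}",
        f"v_h_mm_s = {plan.v_h_mm_s:g}",
        f"v_n_mm_s = {plan.v_n_mm_s:g}",
        f"slice_height_um = {plan.slice_height_um:g}",
        f"extrusion_temp_C = {plan.extrusion_temp_C:g}",
        f"bed_temp_C = {plan.bed_temp_C:g}",
    ]
    return "\n".join(lines) + "\n"
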