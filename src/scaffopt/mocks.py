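"""Mock objectives and toy domains for exercising the optimizer and solver
without the full evaluation chain."""

from __future__ import annotations

from typing import Callable

import numpy as np

from .geometry import DomainSpec, ScaffoldSpec, VoxelModel

__all__ = [
    "quadratic_bone_response",
    "monotone_response",
    "homogeneous_column",
]


def quadratic_bone_response(
    argmax_um: float = 650.0, peak_BO: float = 30.0, width_um: float = 100.0
) -> Callable[[float], float]:
    """Unimodal mock objective Omega(d_fil) = -BO% with a known argmax.

    BO%(d_fil) = peak - ((d_fil - argmax)/width)^2, so the minimum of Omega
    sits exactly at ``argmax_um``.
    """

    def omega(d_fil_um: float) -> float:
        return -(peak_BO - ((d_fil_um - argmax_um) / width_um) ** 2)

    return omega


def monotone_response(slope_per_um: float = 0.01) -> Callable[[float], float]:
    """Mock objective monotone in d_fil: positive slope drives the optimum to
    the lower bound, negative slope to the upper bound."""

    def omega(d_fil_um: float) -> float:
        return slope_per_um * d_fil_um

    return omega


def homogeneous_column(
    n_xy: int = 1, n_z: int = 40, voxel_mm: float = 0.025, phase: int = 0
) -> VoxelModel:
    """Single-phase voxel column for 1-D consolidation / oedometer benchmarks.

    The returned model carries a nominal spec/domain; its labels are uniform,
    so both assembled phases use the material bound to ``phase``.
    """
    labels = np.full((n_xy, n_xy, n_z), phase, dtype=np.int8)
    spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0)
    dom = DomainSpec(resolution_um=voxel_mm * 1e3, n_layers=2)
    return VoxelModel(labels=labels, voxel_mm=voxel_mm, spec=spec, domain=dom)
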