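"""Parametric FDM strand-lattice scaffold geometry on a voxel grid.

An FDM-printed scaffold is a stack of layers, each layer made of parallel
cylindrical strands of diameter ``D`` with center-to-center spacing ``d_fil``.
Consecutive layers are rotated by 90 degrees (layer 0 strands run along x,
layer 1 along y, ...) and interpenetrate vertically by ``overlap_fraction * D``,
so the vertical pitch between layer axes is ``(1 - overlap_fraction) * D``.

The computational domain is a rectangular sub-volume of the full cylindrical
scaffold: one ``d_fil x d_fil`` period in plane (strand axes lying on the
domain boundary planes, so mirror-symmetry boundary conditions reproduce the
periodic interior) and a configurable number of layers in height.  The domain
is voxelized on a regular grid; a voxel belongs to the scaffold phase if its
center lies inside any strand cylinder, otherwise it belongs to the
granulation-tissue phase filling the pores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCAFFOLD = 1
GRANULATION = 0

__all__ = [
    "ScaffoldSpec",
    "DomainSpec",
    "VoxelModel",
    "build_scaffold",
    "porosity",
    "export_geometry",
    "SCAFFOLD",
    "GRANULATION",
]


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric description of the strand lattice.

    Parameters
    ----------
    R_mm, h_mm
        Radius and height of the full cylindrical scaffold, mm.  Used for
        bookkeeping of the full-part volume; the mechanics is solved on a
        periodic sub-volume.
    D_um
        Strand diameter, micrometers.
    d_fil_um
        Center-to-center spacing of parallel strands within a layer,
        micrometers.  Must be >= ``D_um`` (strands at most in contact).
    overlap_fraction
        Vertical interpenetration of consecutive layers as a fraction of
        ``D``; the layer pitch is ``(1 - overlap_fraction) * D``.
    layer_angle_deg
        Angle between strand directions of consecutive layers.  Only the
        orthogonal (90 degree) lay-up is supported.
    """

    R_mm: float = 20.0
    h_mm: float = 5.0
    D_um: float = 400.0
    d_fil_um: float = 800.0
    overlap_fraction: float = 0.1
    layer_angle_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.R_mm <= 0 or self.h_mm <= 0:
            raise ValueError("R_mm and h_mm must be positive")
        if self.D_um <= 0:
            raise ValueError("strand diameter D_um must be positive")
        if self.d_fil_um < self.D_um:
            raise ValueError(
                f"d_fil_um={self.d_fil_um} < D_um={self.D_um}: strands cannot "
                "be closer than reciprocal contact"
            )
        if not 0.0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if self.layer_angle_deg != 90.0:
            raise ValueError("only the 90-degree orthogonal lay-up is supported")

    @property
    def layer_pitch_um(self) -> float:
        """Vertical distance between consecutive layer axes, micrometers."""
        return (1.0 - self.overlap_fraction) * self.D_um


@dataclass(frozen=True)
class DomainSpec:
    """Voxelized sub-volume on which the mechanics is solved.

    ``resolution_um`` is the voxel edge length; it must resolve a strand with
    at least 4 voxels across its diameter.  ``n_layers`` is the number of
    strand layers stacked in the build (z) direction; the domain height is the
    top tangent plane of the last layer.

    ``in_plane`` selects the lateral extent: ``"half"`` (default) is the
    minimal symmetric cell, half a ``d_fil`` period in x and y (strand axes
    on the x = 0 / y = 0 faces, pore center at the far corner) — the lattice
    is mirror-symmetric about both the strand axes and the inter-strand
    mid-planes, so with symmetry faces this cell reproduces the periodic
    interior exactly at a quarter of the cost of ``"full"``, one whole
    period, which exists for symmetry/rotation checks.
    """

    resolution_um: float = 100.0
    n_layers: int = 10
    in_plane: str = "half"

    def __post_init__(self) -> None:
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be positive")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers (one of each orientation)")
        if self.in_plane not in ("half", "full"):
            raise ValueError("in_plane must be 'half' or 'full'")

    def validate_against(self, spec: ScaffoldSpec) -> None:
        if self.resolution_um > spec.D_um / 4.0:
            raise ValueError(
                f"resolution {self.resolution_um} um too coarse: need at least "
                f"4 voxels across a strand of D={spec.D_um} um"
            )

    def height_um(self, spec: ScaffoldSpec) -> float:
        """Domain height: top of the last strand layer, micrometers."""
        return (self.n_layers - 1) * spec.layer_pitch_um + spec.D_um


@dataclass
class VoxelModel:
    """Labeled voxel domain: scaffold phase vs. pore-filling granulation phase.

    Attributes
    ----------
    labels
        ``(nx, ny, nz)`` int array, ``SCAFFOLD`` (1) or ``GRANULATION`` (0).
    voxel_mm
        Voxel edge length, mm.
    spec, domain
        The generating parameter sets.
    """

    labels: np.ndarray
    voxel_mm: float
    spec: ScaffoldSpec
    domain: DomainSpec
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _centers: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm**3

    @property
    def V_TOT_mm3(self) -> float:
        """Total domain volume (both phases), mm^3."""
        return self.labels.size * self.voxel_volume_mm3

    @property
    def scaffold_fraction(self) -> float:
        return float(np.count_nonzero(self.labels == SCAFFOLD)) / self.labels.size

    def axis_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis, mm."""
        if self._centers is None:
            h = self.voxel_mm
            cs = tuple(
                o + (np.arange(n) + 0.5) * h
                for n, o in zip(self.shape, self.origin_mm)
            )
            object.__setattr__(self, "_centers", cs)
        return self._centers  # type: ignore[return-value]


def _strand_mask(
    spec: ScaffoldSpec,
    n_layers: int,
    cx: np.ndarray,
    cy: np.ndarray,
    cz: np.ndarray,
    period_mm: float,
) -> np.ndarray:
    """Scaffold-phase mask for voxel centers (all lengths in mm)."""
    D = spec.D_um * 1e-3
    pitch = spec.layer_pitch_um * 1e-3
    r2 = (D / 2.0) ** 2

    mask = np.zeros((cx.size, cy.size, cz.size), dtype=bool)
    for k in range(n_layers):
        zk = k * pitch + D / 2.0
        dz2 = (cz - zk) ** 2  # (nz,)
        # strand axes lie on the period boundaries: perpendicular coordinate
        # folded into [0, period/2] measures distance to the nearest axis
        if k % 2 == 0:  # strands parallel to x, axes at y = 0 and y = period
            dperp = np.minimum(cy % period_mm, period_mm - cy % period_mm)
            in_cyl = dperp[None, :, None] ** 2 + dz2[None, None, :] <= r2
            mask |= np.broadcast_to(in_cyl, mask.shape)
        else:  # strands parallel to y, axes at x = 0 and x = period
            dperp = np.minimum(cx % period_mm, period_mm - cx % period_mm)
            in_cyl = dperp[:, None, None] ** 2 + dz2[None, None, :] <= r2
            mask |= np.broadcast_to(in_cyl, mask.shape)
    return mask


def build_scaffold(spec: ScaffoldSpec, domain: DomainSpec) -> VoxelModel:
    """Voxelize the strand lattice into a labeled scaffold/granulation domain.

    The in-plane extent is one ``d_fil`` period in x and y; the number of
    voxels per axis is the rounded ratio extent/resolution (the grid snaps the
    extent to a whole number of voxels, within half a voxel of nominal).

    Raises
    ------
    ValueError
        If the resolution is too coarse (fewer than 4 voxels per strand
        diameter) or the spec/domain invariants are violated.
    """
    domain.validate_against(spec)

    period_mm = spec.d_fil_um * 1e-3
    extent_mm = period_mm if domain.in_plane == "full" else period_mm / 2.0
    height_mm = domain.height_um(spec) * 1e-3
    h = domain.resolution_um * 1e-3

    nx = max(2, round(extent_mm / h))
    ny = nx
    # snap the voxel size so the in-plane extent is covered exactly (the
    # period sets the symmetry); the z count then rounds at the snapped size
    h = extent_mm / nx
    nz = max(2, round(height_mm / h))

    cx = (np.arange(nx) + 0.5) * h
    cy = (np.arange(ny) + 0.5) * h
    cz = (np.arange(nz) + 0.5) * h

    mask = _strand_mask(spec, domain.n_layers, cx, cy, cz, period_mm)
    labels = np.where(mask, SCAFFOLD, GRANULATION).astype(np.int8)

    frac = np.count_nonzero(mask) / mask.size
    if frac == 0.0 or frac == 1.0:
        raise ValueError(
            f"degenerate voxelization: scaffold fraction {frac}; check "
            "resolution and spacing"
        )
    return VoxelModel(labels=labels, voxel_mm=h, spec=spec, domain=domain)


def porosity(model: VoxelModel) -> float:
    """Granulation-phase (pore) volume fraction of the domain, in [0, 1]."""
    return 1.0 - model.scaffold_fraction


def export_geometry(model: VoxelModel, stl_path=None, vtk_path=None) -> None:
    """Export the scaffold phase as an STL surface and/or a VTK voxel field.

    The STL is a box-per-voxel surface of the scaffold phase (printable /
    viewable); the VTK file is legacy ASCII STRUCTURED_POINTS with the phase
    label as cell data, round-trippable bit-exactly via
    :func:`scaffopt.vtkio.read_structured_points`.
    """
    if stl_path is None and vtk_path is None:
        raise ValueError("nothing to export: give stl_path and/or vtk_path")
    if stl_path is not None:
        if model.scaffold_fraction == 0.0:
            raise ValueError("empty scaffold phase: nothing to export to STL")
        import trimesh

        occ = model.labels == SCAFFOLD
        grid = trimesh.voxel.VoxelGrid(occ)
        mesh = grid.as_boxes()
        mesh.apply_scale(model.voxel_mm)
        mesh.export(str(stl_path))
    if vtk_path is not None:
        from . import vtkio

        vtkio.write_structured_points(
            vtk_path,
            {"phase": model.labels},
            spacing=model.voxel_mm,
            origin=model.origin_mm,
        )
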