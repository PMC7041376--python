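"""Strand-lattice voxelization: phase partition, analytic volumes, symmetry."""

import numpy as np
import pytest

from scaffopt import vtkio
from scaffopt.geometry import (
    GRANULATION,
    SCAFFOLD,
    DomainSpec,
    ScaffoldSpec,
    VoxelModel,
    build_scaffold,
    export_geometry,
    porosity,
)


def brute_force_scaffold_fraction(spec, n_layers, extent_mm, height_mm, res_mm):
    """Independent fine-grid estimate of the scaffold volume fraction.

    Direct point-in-cylinder test on a dense grid of sample points; shares no
    code with the package voxelizer.
    """
    D = spec.D_um * 1e-3
    pitch = (1 - spec.overlap_fraction) * D
    period = spec.d_fil_um * 1e-3
    x = np.arange(res_mm / 2, extent_mm, res_mm)
    z = np.arange(res_mm / 2, height_mm, res_mm)
    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    inside = np.zeros(X.shape, dtype=bool)
    for k in range(n_layers):
        zk = k * pitch + D / 2
        perp = Y if k % 2 == 0 else X
        d = np.minimum(perp % period, period - perp % period)
        inside |= d**2 + (Z - zk) ** 2 <= (D / 2) ** 2
    return inside.mean()


class TestScaffoldSpec:
    def test_layer_pitch_from_overlap(self):
        # 10% vertical interpenetration of 400 um strands -> 360 um pitch
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0, overlap_fraction=0.1)
        assert spec.layer_pitch_um == pytest.approx(360.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(D_um=500.0, d_fil_um=400.0),     # spacing below contact
            dict(D_um=-400.0, d_fil_um=800.0),
            dict(D_um=400.0, d_fil_um=800.0, overlap_fraction=0.5),
            dict(R_mm=-1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScaffoldSpec(**kwargs)

    def test_too_coarse_resolution_rejected(self):
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0)
        with pytest.raises(ValueError, match="resolution"):
            build_scaffold(spec, DomainSpec(resolution_um=150.0, n_layers=4))


class TestBuildScaffold:
    def test_scaffold_fraction_decreases_with_spacing(self):
        dom = DomainSpec(resolution_um=50.0, n_layers=4)
        fracs = [
            build_scaffold(
                ScaffoldSpec(D_um=400.0, d_fil_um=d), dom
            ).scaffold_fraction
            for d in (500.0, 700.0, 900.0, 1100.0)
        ]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_volume_fraction_matches_fine_grid_oracle(self):
        # two-layer toy lattice vs. an independent 10 um brute-force estimate
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0)
        dom = DomainSpec(resolution_um=50.0, n_layers=2, in_plane="full")
        model = build_scaffold(spec, dom)
        height = dom.height_um(spec) * 1e-3
        ref = brute_force_scaffold_fraction(spec, 2, 0.8, height, 0.01)
        assert model.scaffold_fraction == pytest.approx(ref, rel=0.05)

    def test_phase_partition(self):
        model = build_scaffold(
            ScaffoldSpec(D_um=400.0, d_fil_um=800.0),
            DomainSpec(resolution_um=50.0, n_layers=4),
        )
        assert model.scaffold_fraction + porosity(model) == pytest.approx(1.0)
        assert set(np.unique(model.labels)) == {SCAFFOLD, GRANULATION}
        assert model.V_TOT_mm3 == pytest.approx(
            model.labels.size * model.voxel_mm**3
        )

    def test_half_and_full_period_agree(self):
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0)
        half = build_scaffold(spec, DomainSpec(50.0, 4, in_plane="half"))
        full = build_scaffold(spec, DomainSpec(50.0, 4, in_plane="full"))
        assert half.scaffold_fraction == pytest.approx(full.scaffold_fraction)

    def test_refinement_convergence(self):
        # volume fraction stabilizes under refinement once D/r >= 8
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=800.0)
        f1 = build_scaffold(spec, DomainSpec(50.0, 4)).scaffold_fraction
        f2 = build_scaffold(spec, DomainSpec(25.0, 4)).scaffold_fraction
        assert abs(f1 - f2) / f2 < 0.02

    def test_quarter_turn_plus_layer_shift_symmetry(self):
        # the orthogonal lay-up maps onto itself under a 90 degree in-plane
        # rotation composed with a one-layer vertical shift; exact only in
        # the stack interior (the finite top/bottom layers have no partner),
        # so compare a central window at least one strand away from the ends
        spec = ScaffoldSpec(D_um=400.0, d_fil_um=720.0)
        dom = DomainSpec(resolution_um=45.0, n_layers=6, in_plane="full")
        model = build_scaffold(spec, dom)
        h_um = model.voxel_mm * 1e3
        shift = round(spec.layer_pitch_um / h_um)
        assert shift * h_um == pytest.approx(spec.layer_pitch_um)
        rotated = np.rot90(model.labels, axes=(0, 1))
        height_um = dom.height_um(spec)
        centers = (np.arange(model.shape[2]) + 0.5) * h_um
        window = np.where(
            (centers >= 1.5 * spec.D_um)
            & (centers + spec.layer_pitch_um <= height_um - 1.5 * spec.D_um)
        )[0]
        assert window.size > 0
        np.testing.assert_array_equal(
            rotated[:, :, window + shift], model.labels[:, :, window]
        )


class TestPorosity:
    def test_uniform_phases(self):
        spec = ScaffoldSpec()
        dom = DomainSpec()
        all_gran = VoxelModel(
            labels=np.full((3, 3, 3), GRANULATION, dtype=np.int8),
            voxel_mm=0.1, spec=spec, domain=dom,
        )
        all_scaf = VoxelModel(
            labels=np.full((3, 3, 3), SCAFFOLD, dtype=np.int8),
            voxel_mm=0.1, spec=spec, domain=dom,
        )
        assert porosity(all_gran) == 1.0
        assert porosity(all_scaf) == 0.0


class TestExport:
    def test_vtk_roundtrip_is_bit_exact(self, tmp_path):
        model = build_scaffold(
            ScaffoldSpec(D_um=400.0, d_fil_um=800.0),
            DomainSpec(resolution_um=100.0, n_layers=2),
        )
        path = tmp_path / "phase.vtk"
        export_geometry(model, vtk_path=path)
        back = vtkio.read_structured_points(path)["phase"]
        np.testing.assert_array_equal(back, model.labels)

    def test_stl_is_watertight(self, tmp_path):
        import trimesh

        model = build_scaffold(
            ScaffoldSpec(D_um=400.0, d_fil_um=800.0),
            DomainSpec(resolution_um=100.0, n_layers=2),
        )
        path = tmp_path / "scaffold.stl"
        export_geometry(model, stl_path=path)
        mesh = trimesh.load(str(path))
        assert mesh.volume > 0

    def test_empty_scaffold_rejected(self, tmp_path):
        model = VoxelModel(
            labels=np.full((3, 3, 3), GRANULATION, dtype=np.int8),
            voxel_mm=0.1, spec=ScaffoldSpec(), domain=DomainSpec(),
        )
        with pytest.raises(ValueError, match="empty scaffold"):
            export_geometry(model, stl_path=tmp_path / "x.stl")

    def test_nothing_to_export_rejected(self):
        model = build_scaffold(
            ScaffoldSpec(D_um=400.0, d_fil_um=800.0),
            DomainSpec(resolution_um=100.0, n_layers=2),
        )
        with pytest.raises(ValueError):
            export_geometry(model)
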