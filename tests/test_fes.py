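"""HILLS I/O, FES reconstruction, region free energies and dG_r/nr."""

import io
import math

import numpy as np
import pytest

from conftest import brute_force_bias, grid_from_function, random_hills
from puckmet.fes import (
    FESGrid,
    GridAxis,
    HillsSeries,
    delta_g_rnr,
    partition_masks,
    read_fes,
    read_hills,
    reconstruct_fes,
    reconstruct_fes_averaged,
    region_free_energy,
    write_fes,
    write_hills,
)
from puckmet.ring import PartitionSpec

KT = 0.596


class TestHillsIO:
    def test_reads_plumed_style_header_and_rows(self):
        text = (
            "#! FIELDS time phi theta sigma_phi sigma_theta height biasf\n"
            "#! SET min_phi 0\n#! SET max_phi 2pi\n"
            "0.5 1.0 2.0 0.1 0.1 0.75 15\n"
            "1.0 1.1 2.1 0.1 0.1 0.74 15\n"
        )
        hills = read_hills(io.StringIO(text))
        assert len(hills) == 2
        assert hills.cv_names == ("phi", "theta")
        assert hills.periodic["phi"][1] == pytest.approx(2 * math.pi)
        assert hills.heights[1] == pytest.approx(0.74)

    def test_header_only_file_gives_empty_series(self):
        hills = read_hills(io.StringIO("#! FIELDS time phi theta sigma_phi sigma_theta height\n"))
        assert len(hills) == 0

    def test_missing_mandatory_columns_rejected(self):
        with pytest.raises(ValueError):
            read_hills(io.StringIO("#! FIELDS time phi theta height\n1 2 3 4\n"))
        with pytest.raises(ValueError):
            read_hills(io.StringIO("1 2 3 4\n"))

    def test_nonmonotonic_time_warns(self):
        text = (
            "#! FIELDS time phi theta sigma_phi sigma_theta height\n"
            "1.0 0 0 .1 .1 .5\n0.5 0 0 .1 .1 .5\n"
        )
        with pytest.warns(UserWarning):
            read_hills(io.StringIO(text))

    def test_write_read_roundtrip(self, rng, puckering_axes):
        hills = random_hills(rng, 50, puckering_axes)
        buf = io.StringIO()
        write_hills(hills, buf)
        buf.seek(0)
        back = read_hills(buf)
        np.testing.assert_allclose(back.centers, hills.centers, atol=1e-12)
        np.testing.assert_allclose(back.sigmas, hills.sigmas, atol=1e-12)
        np.testing.assert_allclose(back.heights, hills.heights, atol=1e-12)
        np.testing.assert_allclose(back.bias_factors, hills.bias_factors, atol=1e-12)
        assert back.cv_names == hills.cv_names


class TestReconstruction:
    def test_empty_series_gives_flat_zero_grid(self, puckering_axes):
        hills = HillsSeries(
            time=np.empty(0), centers=np.empty((0, 2)), sigmas=np.empty((0, 2)),
            heights=np.empty(0), bias_factors=np.empty(0),
            cv_names=("phi", "theta"),
        )
        fes = reconstruct_fes(hills, puckering_axes)
        assert np.all(fes.values == 0.0)

    def test_single_hill_closed_form(self, puckering_axes):
        # far-field minus hill-center value equals gamma/(gamma-1) * w
        gamma, w = 15.0, 1.0
        center = [puckering_axes[0].nodes[8], puckering_axes[1].nodes[11]]
        hills = HillsSeries(
            time=[0.0], centers=[center], sigmas=[[0.1, 0.1]],
            heights=[w], bias_factors=[gamma], cv_names=("phi", "theta"),
        )
        fes = reconstruct_fes(hills, puckering_axes, dialect="tempered")
        assert fes.values.max() == pytest.approx(gamma / (gamma - 1.0) * w, abs=1e-8)
        fes2 = reconstruct_fes(hills, puckering_axes, dialect="scaled")
        assert fes2.values.max() == pytest.approx(w, abs=1e-8)

    def test_matches_brute_force_oracle(self, rng, puckering_axes):
        hills = random_hills(rng, 50, puckering_axes)
        V = brute_force_bias(hills, puckering_axes)
        expected = -(15.0 / 14.0) * V
        expected -= expected.min()
        fes = reconstruct_fes(hills, puckering_axes)
        assert np.max(np.abs(fes.values - expected)) < 1e-10

    def test_periodic_seam_continuity(self, rng):
        # hill straddling phi = 0: refined grids agree across the seam
        hills = HillsSeries(
            time=[0.0], centers=[[0.05, 1.5]], sigmas=[[0.3, 0.3]],
            heights=[1.0], bias_factors=[15.0], cv_names=("phi", "theta"),
        )
        diffs = []
        for n in (90, 180, 360):
            axes = (
                GridAxis("phi", 0, 2 * math.pi, n, periodic=True),
                GridAxis("theta", 0, math.pi, 11),
            )
            fes = reconstruct_fes(hills, axes)
            diffs.append(np.max(np.abs(fes.values[0] - fes.values[-1])))
        # seam mismatch shrinks linearly with the node spacing
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[2] < diffs[0] / 3.0

    def test_bias_monotone_in_hill_count(self, rng, puckering_axes):
        from puckmet.fes import accumulate_bias

        hills = random_hills(rng, 30, puckering_axes)
        prev = np.zeros((puckering_axes[0].n_bins, puckering_axes[1].n_bins))
        for k in (10, 20, 30):
            sub = HillsSeries(
                hills.time[:k], hills.centers[:k], hills.sigmas[:k],
                hills.heights[:k], hills.bias_factors[:k], hills.cv_names,
            )
            V = accumulate_bias(sub, puckering_axes)
            assert np.all(V >= prev - 1e-12)
            prev = V

    def test_tempered_dialect_requires_gamma_above_one(self, puckering_axes):
        hills = HillsSeries(
            time=[0.0], centers=[[1.0, 1.0]], sigmas=[[0.1, 0.1]],
            heights=[1.0], bias_factors=[0.5], cv_names=("phi", "theta"),
        )
        with pytest.raises(ValueError):
            reconstruct_fes(hills, puckering_axes, dialect="tempered")

    def test_averaged_estimator_reduces_to_final_for_single_checkpoint(
        self, rng, puckering_axes
    ):
        hills = random_hills(rng, 40, puckering_axes)
        final = reconstruct_fes(hills, puckering_axes)
        avg = reconstruct_fes_averaged(hills, puckering_axes, n_checkpoints=1)
        np.testing.assert_allclose(avg.values, final.values, atol=1e-12)


class TestRegionFreeEnergy:
    def test_single_zero_node_unit_area(self):
        axes = (GridAxis("x", 0, 2, 3), GridAxis("y", 0, 2, 3))  # spacing 1 x 1
        fes = FESGrid(axes, np.zeros((3, 3)))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        assert region_free_energy(fes, mask, KT) == pytest.approx(0.0, abs=1e-14)

    def test_two_equal_nodes_give_minus_kt_ln2(self):
        axes = (GridAxis("x", 0, 2, 3), GridAxis("y", 0, 2, 3))
        fes = FESGrid(axes, np.zeros((3, 3)))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert region_free_energy(fes, mask, KT) == pytest.approx(-KT * math.log(2), abs=1e-14)

    def test_matches_direct_summation_oracle(self, rng):
        axes = (GridAxis("x", 0, 1, 10), GridAxis("y", 0, 1, 10))
        F = rng.uniform(0, 5, (10, 10))
        fes = FESGrid(axes, F - F.min())
        mask = rng.uniform(size=(10, 10)) > 0.4
        dA = axes[0].spacing * axes[1].spacing
        expected = -KT * math.log(sum(math.exp(-f / KT) * dA for f in fes.values[mask].ravel()))
        assert region_free_energy(fes, mask, KT) == pytest.approx(expected, abs=1e-12)

    def test_empty_mask_rejected(self):
        axes = (GridAxis("x", 0, 1, 4), GridAxis("y", 0, 1, 4))
        fes = FESGrid(axes, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            region_free_energy(fes, np.zeros((4, 4), dtype=bool), KT)


def two_state_grid(delta=2.0, n_theta=24):
    """North region uniformly 0, south uniformly `delta`, equal node counts."""
    axes = (
        GridAxis("phi", 0, 2 * math.pi, 24, periodic=True),
        GridAxis("theta", 0, math.pi, n_theta, periodic=False),
    )
    theta = axes[1].nodes
    assert not np.any(np.isclose(theta, math.pi / 2))  # even count: no node on the equator
    F = np.where(theta[None, :] > math.pi / 2, delta, 0.0) * np.ones((24, 1))
    return FESGrid(axes, F)


class TestDeltaGrnr:
    def test_two_state_closed_form_both_modes(self):
        fes = two_state_grid(2.0)
        assert delta_g_rnr(fes, mode="boltzmann", kT=KT) == pytest.approx(-2.0, abs=1e-12)
        assert delta_g_rnr(fes, mode="minimum", kT=KT) == pytest.approx(-2.0, abs=1e-12)

    def test_zero_for_mirror_symmetric_surface(self):
        axes = (
            GridAxis("phi", 0, 2 * math.pi, 24, periodic=True),
            GridAxis("theta", 0, math.pi, 24, periodic=False),
        )
        fes = grid_from_function(
            axes, lambda X, Y: np.cos(X) ** 2 * np.sin(Y) ** 2 * 3.0
        )  # symmetric under theta -> pi - theta
        assert delta_g_rnr(fes, kT=KT) == pytest.approx(0.0, abs=1e-10)

    def test_sign_flips_when_labels_swap(self, rng):
        axes = (
            GridAxis("phi", 0, 2 * math.pi, 16, periodic=True),
            GridAxis("theta", 0, math.pi, 16, periodic=False),
        )
        F = rng.uniform(0, 4, (16, 16))
        fes = FESGrid(axes, F - F.min())
        spec = PartitionSpec()
        dg = delta_g_rnr(fes, spec, KT)
        reactive, nonreactive = partition_masks(fes, spec)
        swapped = region_free_energy(fes, nonreactive, KT) - region_free_energy(fes, reactive, KT)
        assert swapped == pytest.approx(-dg, abs=1e-12)
        # mirroring the surface across the equator also flips the sign
        mirrored = FESGrid(fes.axes, fes.values[:, ::-1].copy())
        assert delta_g_rnr(mirrored, spec, KT) == pytest.approx(-dg, abs=1e-9)

    def test_modes_agree_within_area_entropy_bound(self):
        fes = two_state_grid(3.0)
        b = delta_g_rnr(fes, mode="boltzmann", kT=KT)
        m = delta_g_rnr(fes, mode="minimum", kT=KT)
        # equal-area two-state grid: entropy terms cancel exactly
        assert abs(b - m) <= KT * math.log(2) + 1e-9

    def test_empty_region_rejected(self):
        fes = two_state_grid(1.0)
        spec = PartitionSpec(theta_knots=np.array([0.0, 0.0]))  # nothing strictly north
        with pytest.raises(ValueError):
            delta_g_rnr(fes, spec, KT)


class TestFesIO:
    def test_write_read_roundtrip(self, rng, puckering_axes):
        hills = random_hills(rng, 20, puckering_axes)
        fes = reconstruct_fes(hills, puckering_axes)
        buf = io.StringIO()
        write_fes(fes, buf)
        buf.seek(0)
        back = read_fes(buf)
        np.testing.assert_allclose(back.values, fes.values, atol=1e-12)
        assert back.axes[0].periodic and not back.axes[1].periodic
        assert back.axes[0].n_bins == puckering_axes[0].n_bins
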