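"""Generator correctness: parameter validation, degenerate cases, and
recovery of simulation parameters by their binomial/geometric oracles."""

import numpy as np
import pytest

from drtkit import structure_geometry as sg
from drtkit import synthetic_data as sd

from conftest import rigid_motion


class TestReadSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"product_fraction": 1.2},
            {"p_tail": -0.1},
            {"sub_error_rate": 2.0},
            {"n_rate": -1e-9},
            {"mu_core": 0.5},
            {"n_reads": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.ReadSimParams(contaminant_reference="ACGT" * 100, **kwargs)

    def test_contaminant_required_when_mixture(self):
        with pytest.raises(ValueError, match="contaminant_reference"):
            sd.ReadSimParams(product_fraction=0.5, contaminant_reference=None)


class TestSimulateReads:
    def test_pure_product_degenerate(self):
        params = sd.ReadSimParams(
            n_reads=5, product_fraction=1.0, sub_error_rate=0.0, n_rate=0.0,
            p_tail=0.0, mu_core=20.0, contaminant_reference=None, seed=4,
        )
        rs = sd.simulate_product_read_set(params)
        assert len(rs.reads) == 5
        for read, truth in zip(rs.reads, rs.truth):
            assert set(read.seq) == {"A"}
            assert truth.label == "product"
            assert truth.core_len == len(read.seq)

    def test_pure_contaminant_has_no_long_a_runs(self):
        ref = "ACGT" * 50
        params = sd.ReadSimParams(
            n_reads=10, product_fraction=0.0, sub_error_rate=0.0, n_rate=0.0,
            contaminant_reference=ref, read_length_cap=50, seed=4,
        )
        rs = sd.simulate_product_read_set(params)
        assert len(rs.reads) == 10
        for read, truth in zip(rs.reads, rs.truth):
            assert truth.label == "contaminant"
            assert "AA" not in read.seq

    def test_product_fraction_recovered(self, study_readset):
        n = len(study_readset.reads)
        f = 0.8
        observed = sum(t.label == "product" for t in study_readset.truth) / n
        assert abs(observed - f) < 3 * np.sqrt(f * (1 - f) / n)

    def test_mean_core_and_tail_lengths_recovered(self, clean_readset):
        cores = [t.core_len for t in clean_readset.truth if t.label == "product"]
        # geometric(mean mu) has sd mu*sqrt(1-1/mu); cap at 150 is a <1% effect
        mu = 30.0
        se = mu * np.sqrt(1 - 1 / mu) / np.sqrt(len(cores))
        assert abs(np.mean(cores) - mu) < 3 * se + 0.2
        tails = [t.tail_len for t in clean_readset.truth
                 if t.label == "product" and t.tail_len > 0]
        mu_t = 8.0
        se_t = mu_t * np.sqrt(1 - 1 / mu_t) / np.sqrt(len(tails))
        assert abs(np.mean(tails) - mu_t) < 3 * se_t + 0.2

    def test_fixed_seed_reproducible(self, contaminant_ref):
        params = sd.ReadSimParams(
            n_reads=200, contaminant_reference=contaminant_ref, seed=11
        )
        a = sd.simulate_product_read_set(params)
        b = sd.simulate_product_read_set(params)
        assert [r.seq for r in a.reads] == [r.seq for r in b.reads]
        assert a.truth == b.truth

    def test_truth_matches_read_count_and_lengths(self, study_readset):
        assert len(study_readset.truth) == len(study_readset.reads)
        for read, truth in zip(study_readset.reads, study_readset.truth):
            assert truth.core_len <= len(read.seq)


class TestIdealHelix:
    def test_requires_three_residues(self):
        with pytest.raises(ValueError, match="n_res"):
            sd.HelixSimParams(n_res=2)

    def test_orientation_must_be_unit(self):
        with pytest.raises(ValueError, match="orientation"):
            sd.HelixSimParams(orientation=(0, 0, 2))

    def test_zero_radius_is_collinear_along_orientation(self):
        pts = sd.simulate_ideal_helix(
            sd.HelixSimParams(n_res=20, radius=0.0, orientation=(0, 0, 1))
        )
        frame = sg.fit_axis(pts)
        np.testing.assert_allclose(frame.axis, [0, 0, 1], atol=1e-9)
        assert frame.collinearity == pytest.approx(1.0)

    def test_axis_near_orientation_for_finite_radius(self):
        pts = sd.simulate_ideal_helix(sd.HelixSimParams(n_res=20))
        frame = sg.fit_axis(pts)
        # finite discrete helix: principal direction is within a few degrees
        # of the geometric axis (intrinsic spiral tilt, see methods note)
        angle = np.degrees(np.arccos(abs(frame.axis @ np.array([0, 0, 1.0]))))
        assert angle < 3.0

    def test_rotation_equivariance(self):
        """Fitting a rotated helix gives the rotated fitted axis (the
        known-rotation oracle), to machine precision."""
        pts = sd.simulate_ideal_helix(sd.HelixSimParams(n_res=20))
        base_axis = sg.fit_axis(pts).axis
        rot, trans = rigid_motion(seed=5)
        moved_axis = sg.fit_axis(pts @ rot.T + trans).axis
        np.testing.assert_allclose(moved_axis, rot @ base_axis, atol=1e-9)


class TestPlanarAssembly:
    def test_angle_count_must_match_units(self):
        with pytest.raises(ValueError, match="adjacent angles"):
            sd.AssemblySimParams(n_units=3, adjacent_angles=(90.0,))

    def test_angles_outside_open_interval_rejected(self):
        with pytest.raises(ValueError, match="0, 180"):
            sd.AssemblySimParams(n_units=2, adjacent_angles=(180.0,))

    def test_two_unit_orthogonal(self):
        model = sd.simulate_planar_assembly(
            sd.AssemblySimParams(n_units=2, adjacent_angles=(90.0,))
        )
        assert set(model.chains) == {"A", "B"}
        a = sg.fit_axis(model.chain_coords("A")).axis
        b = sg.fit_axis(model.chain_coords("B")).axis
        normal = sg.assembly_plane_normal(
            np.vstack([model.chain_coords("A"), model.chain_coords("B")])
        )
        angle = sg.projected_inter_unit_angle(
            sg.UnitFrame(np.zeros(3), a, 1.0),
            sg.UnitFrame(np.zeros(3), b, 1.0),
            normal,
        )
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_unit_axes_lie_in_common_plane(self):
        model = sd.simulate_planar_assembly(
            sd.AssemblySimParams(n_units=4, adjacent_angles=(60.0, 45.0, 30.0))
        )
        for cid in model.chains:
            axis = sg.fit_axis(model.chain_coords(cid)).axis
            assert abs(axis[2]) < 1e-9  # built in the xy plane


class TestNcrnaFamily:
    def test_zero_sub_rate_identical(self):
        fam = sd.simulate_ncrna_family("ACGTACGTAC", n_seqs=5, sub_rate=0.0)
        assert all(seq == "ACGTACGTAC" for _, seq in fam.records)

    def test_full_mask_blocks_all_mutation(self):
        ref = "ACGTACGTAC"
        fam = sd.simulate_ncrna_family(
            ref, n_seqs=5, sub_rate=1.0, conserved_mask=range(len(ref))
        )
        assert all(seq == ref for _, seq in fam.records)

    def test_invalid_sub_rate(self):
        with pytest.raises(ValueError):
            sd.simulate_ncrna_family("ACGT", n_seqs=1, sub_rate=1.5)

    def test_mask_position_outside_reference(self):
        with pytest.raises(ValueError, match="outside"):
            sd.simulate_ncrna_family("ACGT", 1, 0.1, conserved_mask=[10])

    def test_masked_columns_conserved_others_near_sub_rate(self):
        ref = sd.random_ncrna_reference(188, seed=3)
        mask = range(124, 128)
        fam = sd.simulate_ncrna_family(
            ref, n_seqs=100, sub_rate=0.3, conserved_mask=mask, seed=9
        )
        rows = [seq for rid, seq in fam.records if rid != "reference"]
        arr = np.array([list(s) for s in rows])
        ref_arr = np.array(list(ref))
        match = (arr == ref_arr).mean(axis=0)
        assert all(match[list(mask)] == 1.0)
        others = np.delete(match, list(mask))
        # mean identity over the unmasked columns: binomial oracle on
        # n_seqs * n_columns independent draws
        se_mean = np.sqrt(0.3 * 0.7 / (100 * others.size))
        assert abs(others.mean() - 0.7) < 3 * se_mean

    def test_column_map_identity_without_insertions(self):
        fam = sd.simulate_ncrna_family("ACGTAC", n_seqs=2, sub_rate=0.1)
        assert fam.column_map == list(range(6))

    def test_inserted_columns_are_reference_gaps(self):
        fam = sd.simulate_ncrna_family(
            "ACGTACGTAC", n_seqs=3, sub_rate=0.2, n_insert_columns=4, seed=5
        )
        ref_row = next(s for rid, s in fam.records if rid == "reference")
        gap_cols = [j for j, c in enumerate(ref_row) if c == "-"]
        assert gap_cols == [j for j, m in enumerate(fam.column_map) if m is None]
        assert len(gap_cols) == 4
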