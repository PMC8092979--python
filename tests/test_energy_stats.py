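"""Energy-change records, threshold filters, Pearson and the term matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allopath import (
    EnergyChangeRecord,
    GeneratorConfig,
    component_sum,
    energy_change,
    filter_by_change,
    generate_energy_trajectory,
    pearson,
    term_correlation_matrix,
)
from allopath.energy_stats import PRINTED_TOTAL_TOLERANCE, TERM_MATRIX_LABELS
from allopath.errors import ValidationError, ZeroVarianceError
from allopath.reference_tables import ALL_SITE_TABLES

from conftest import make_trajectory

ALL_ROWS = [
    (site, rid, row)
    for site, table in ALL_SITE_TABLES.items()
    for rid, row in table.items()
]


def records_from_table(table):
    return [
        EnergyChangeRecord.from_components(rid, *row[:5]) for rid, row in table.items()
    ]


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson([1, 5, 2], [1, 5, 2]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_triple(self):
        # cov = 3, var_a = 2, var_b = 42/9 -> r = 3 / sqrt(2 * 42/9)
        expected = 3.0 / np.sqrt(2.0 * 42.0 / 9.0)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)
        assert round(pearson([1, 2, 3], [1, 2, 4]), 3) == 0.982

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=12),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_bounds_and_affine_invariance(self, values, scale, shift):
        a = np.asarray(values)
        rng = np.random.default_rng(0)
        b = a + rng.standard_normal(a.size)
        if a.std() == 0 or b.std() == 0:
            return
        r = pearson(a, b)
        assert -1.0 <= r <= 1.0
        assert pearson(b, a) == pytest.approx(r, abs=1e-12)
        assert pearson(scale * a + shift, b) == pytest.approx(r, abs=1e-9)
        assert pearson(-a, b) == pytest.approx(-r, abs=1e-9)


class TestEnergyChange:
    def test_constant_trajectory_gives_zero_records(self):
        traj = make_trajectory({t: np.full((3, 20), v) for t, v in
                                zip(("bond", "angle", "dihedral", "electrostatic", "vdw"),
                                    (1.0, -2.0, 0.5, 3.0, -0.1))})
        for rec in energy_change(traj, window=5):
            assert rec.d_total == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_window_is_direct_subtraction(self):
        elec = np.array([[2.0, 0.0, 0.0, -3.134]])
        traj = make_trajectory({"electrostatic": elec,
                                **{t: np.zeros((1, 4)) for t in
                                   ("bond", "angle", "dihedral", "vdw")}})
        (rec,) = energy_change(traj, window=1)
        assert rec.d_electrostatic == pytest.approx(-5.134)
        assert rec.d_total == pytest.approx(-5.134)

    def test_window_out_of_range(self, small_energy):
        traj, _ = small_energy
        with pytest.raises(ValueError):
            energy_change(traj, window=0)
        with pytest.raises(ValueError):
            energy_change(traj, window=traj.n_snapshots)

    def test_planted_offsets_recovered_within_standard_error(self):
        offsets = {3: {"electrostatic": -6.0}, 17: {"bond": 9.0},
                   25: {"dihedral": 4.0}, 40: {"vdw": -5.0}}
        config = GeneratorConfig(
            n_residues=50, n_snapshots=2000, pathway_residues=(10,),
            sources=(20,), sinks=(30,), end_state_offsets=offsets, seed=101,
        )
        traj, truth = generate_energy_trajectory(config)
        w = 10
        records = {r.residue_id: r for r in energy_change(traj, window=w)}
        # The start/end difference of two w-frame means has standard
        # error sigma*sqrt(2/w); each recovery sits within 3 of those,
        # and the mean absolute error stays within 2*sigma/sqrt(w).
        se = config.noise_sigma * np.sqrt(2.0 / w)
        errors = []
        for rid, terms in truth.end_state_offsets.items():
            for term, offset in terms.items():
                err = records[rid].change(term) - offset
                errors.append(abs(err))
                assert abs(err) <= 3.0 * se
        assert np.mean(errors) <= 2.0 * config.noise_sigma / np.sqrt(w)

    def test_record_total_consistency_enforced(self):
        with pytest.raises(ValidationError):
            EnergyChangeRecord(1, 1.0, 1.0, 1.0, 1.0, 1.0, 99.0)


class TestComponentSum:
    @pytest.mark.parametrize("site,rid,row", ALL_ROWS,
                             ids=[f"{s}-{r}" for s, r, _ in ALL_ROWS])
    def test_reference_totals_reproduced(self, site, rid, row):
        assert component_sum(row[:5]) == pytest.approx(
            row[5], abs=PRINTED_TOTAL_TOLERANCE
        )

    def test_exact_rows_at_three_decimals(self):
        # These component rows sum to the printed total exactly at 3 dp.
        assert component_sum((4.522, 1.331, 0.735, 0.781, 1.889)) == pytest.approx(9.258)
        assert component_sum((0.413, 9.457, -0.467, -1.612, -1.047)) == pytest.approx(6.744)

    def test_zeros(self):
        assert component_sum((0, 0, 0, 0, 0)) == 0.0

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            component_sum((1.0, 2.0))


class TestFilterByChange:
    def test_lysine_site_electrostatic_filter(self):
        records = records_from_table(ALL_SITE_TABLES["lysine"])
        assert filter_by_change(records, "electrostatic", 5.0) == [338]

    def test_adp_site_has_no_large_total_change(self):
        records = records_from_table(ALL_SITE_TABLES["adp"])
        assert filter_by_change(records, "total", 8.0) == []

    def test_lysine_site_total_filter(self):
        records = records_from_table(ALL_SITE_TABLES["lysine"])
        assert filter_by_change(records, "total", 8.0) == [346]

    def test_signed_mode_drops_negative_changes(self):
        records = records_from_table(ALL_SITE_TABLES["lysine"])
        # 338's change is -5.134: caught by abs, missed by signed
        assert filter_by_change(records, "electrostatic", 5.0, mode="signed_gt") == []

    def test_empty_records(self):
        assert filter_by_change([], "total", 8.0) == []

    def test_unknown_term_rejected(self):
        records = records_from_table(ALL_SITE_TABLES["adp"])
        with pytest.raises(KeyError):
            filter_by_change(records, "entropy", 1.0)


class TestTermCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, small_energy):
        traj, _ = small_energy
        m = term_correlation_matrix(traj)
        assert m.labels == TERM_MATRIX_LABELS
        np.testing.assert_allclose(np.diag(m.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_nonbond_tracks_electrostatic_when_vdw_small(self, small_energy):
        traj, _ = small_energy  # generator default: vdw amplitude 5% of elec
        m = term_correlation_matrix(traj)
        assert m.get("nonbond", "electrostatic") > 0.99

    def test_planted_compensation_recovered_pooled(self):
        config = GeneratorConfig(
            n_residues=100, n_snapshots=2000, pathway_residues=(10, 20, 30),
            sources=(40, 50), sinks=(60, 70), compensation_rho=-0.5, seed=21,
        )
        traj, _ = generate_energy_trajectory(config)
        m = term_correlation_matrix(traj, mode="pooled2d")
        assert m.get("electrostatic", "dihedral") == pytest.approx(-0.5, abs=0.05)

    def test_pooled_matches_direct_pearson_on_flat_series(self, small_energy):
        traj, _ = small_energy
        m = term_correlation_matrix(traj)
        direct = pearson(
            traj.components["electrostatic"].ravel(),
            traj.components["dihedral"].ravel(),
        )
        assert m.get("electrostatic", "dihedral") == pytest.approx(direct, abs=1e-12)

    def test_system_sum_mode(self, small_energy):
        traj, _ = small_energy
        m = term_correlation_matrix(traj, mode="system_sum")
        assert m.get("electrostatic", "dihedral") < 0

    def test_zero_variance_term_flagged_not_zeroed(self):
        config = GeneratorConfig(
            n_residues=10, n_snapshots=50, pathway_residues=(3,), sources=(5,),
            sinks=(7,), term_scales={"bond": 0.0, "angle": 1.0, "dihedral": 1.0,
                                     "electrostatic": 1.0, "vdw": 0.05}, seed=2,
        )
        traj, _ = generate_energy_trajectory(config)
        m = term_correlation_matrix(traj)
        i = m.labels.index("bond")
        assert not m.defined[i, m.labels.index("electrostatic")]
        assert np.isnan(m.values[i, m.labels.index("electrostatic")])
        with pytest.raises(ZeroVarianceError):
            m.get("bond", "electrostatic")
        assert m.n_undefined > 0
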