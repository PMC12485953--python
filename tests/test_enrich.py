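"""IP-MS enrichment statistics: filtering, imputation, S0 statistic, permutation FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tailskit.enrich import (
    LFQTable,
    PermTestParams,
    PRESET_STRICT,
    filter_protein_groups,
    impute_gaussian_downshift,
    permutation_fdr,
    s0_statistic,
    volcano,
)
from tailskit.simulate import SimConfig, simulate_ipms

from oracles import student_t_two_sample

SAMPLES = ["bait_1", "bait_2", "bait_3", "control_1", "control_2", "control_3"]
GROUPS = {s: ("bait" if s.startswith("bait") else "control") for s in SAMPLES}


def _table(n=50, seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(25, 2, size=(n, 6))
    if missing:
        X[rng.random(X.shape) < missing] = np.nan
    ids = [f"P{i:04d}" for i in range(n)]
    return LFQTable(pd.DataFrame(X, index=ids, columns=SAMPLES), {}, dict(GROUPS))


class TestFilterProteinGroups:
    def test_flagged_rows_removed_order_preserved(self):
        t = _table(10)
        t.flags = {"P0001": {"reverse"}, "P0004": {"contaminant"},
                   "P0007": {"only_by_site"}}
        out = filter_protein_groups(t)
        assert len(out.intensities) == 7
        assert "P0001" not in out.intensities.index
        kept = [i for i in t.intensities.index if i not in t.flags]
        assert list(out.intensities.index) == kept

    def test_unflagged_rows_unchanged(self):
        t = _table(5)
        out = filter_protein_groups(t)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)


class TestImputeGaussianDownshift:
    def test_complete_table_is_identity(self):
        t = _table(20)
        out = impute_gaussian_downshift(t, PRESET_STRICT)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_seeded_determinism(self):
        t = _table(100, missing=0.2)
        p = PermTestParams(seed=5)
        a = impute_gaussian_downshift(t, p)
        b = impute_gaussian_downshift(t, p)
        pd.testing.assert_frame_equal(a.intensities, b.intensities)

    def test_imputed_center_matches_downshift(self):
        # sample with mean 25, sd 2 -> imputed values center near 25 - 1.8*2
        rng = np.random.default_rng(3)
        col = np.concatenate([rng.normal(25, 2, size=3000), np.full(1000, np.nan)])
        X = np.column_stack([col] + [rng.normal(25, 2, size=4000)] * 5)
        t = LFQTable(pd.DataFrame(X, columns=SAMPLES), {}, dict(GROUPS))
        out = impute_gaussian_downshift(t, PermTestParams(seed=2))
        obs = col[:3000]
        expect = obs.mean() - 1.8 * obs.std(ddof=1)
        imputed = out.intensities.iloc[3000:, 0]
        assert imputed.mean() == pytest.approx(expect, abs=0.1)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * obs.std(ddof=1), rel=0.1)

    def test_observed_cells_untouched(self):
        t = _table(100, missing=0.2)
        mask = t.intensities.isna()
        out = impute_gaussian_downshift(t, PermTestParams(seed=1))
        assert (out.intensities.to_numpy()[~mask.to_numpy()]
                == t.intensities.to_numpy()[~mask.to_numpy()]).all()


class TestS0Statistic:
    def test_equal_means_give_zero(self):
        assert s0_statistic([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=2.0) == 0.0

    def test_s0_zero_matches_textbook_t_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a = rng.normal(0, 1, size=rng.integers(2, 6)).tolist()
            b = rng.normal(0.5, 2, size=rng.integers(2, 6)).tolist()
            d = s0_statistic(a, b, s0=0.0)
            assert d == pytest.approx(student_t_two_sample(a, b), abs=1e-10)
            # and scipy agrees as a second, independent route
            assert d == pytest.approx(
                stats.ttest_ind(a, b, equal_var=True).statistic, abs=1e-10)

    def test_abs_d_strictly_decreasing_in_s0(self):
        a, b = [25.0, 26.0, 24.5], [20.0, 21.0, 20.5]
        ds = [abs(s0_statistic(a, b, s0)) for s0 in (0.0, 0.5, 1.22, 2.0, 5.0)]
        assert all(x > y for x, y in zip(ds, ds[1:]))

    def test_zero_variance_zero_s0_is_error(self):
        with pytest.raises(ValueError):
            s0_statistic([1.0, 1.0], [2.0, 2.0], s0=0.0)


def _planted(seed=0):
    cfg = SimConfig(seed=seed, ipms_missing_enabled=False)
    table, truth = simulate_ipms(cfg)
    return filter_protein_groups(table), truth


class TestPermutationFDR:
    def test_planted_signal_recovered_exactly(self):
        table, truth = _planted(seed=4)
        with pytest.warns(UserWarning, match="distinct relabelings"):
            cutoff, frame = permutation_fdr(table, PRESET_STRICT)
        sig = set(frame.index[frame["significant"]])
        assert sig == set(truth.ipms_enriched)

    def test_higher_fdr_target_gives_superset(self):
        table, _ = _planted(seed=8)
        with pytest.warns(UserWarning):
            _, strict = permutation_fdr(table, PermTestParams(fdr_target=0.05))
        with pytest.warns(UserWarning):
            _, loose = permutation_fdr(table, PermTestParams(fdr_target=0.1))
        assert set(strict.index[strict.significant]) <= \
            set(loose.index[loose.significant])

    def test_row_shuffle_invariance(self):
        table, _ = _planted(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.intensities))
        shuffled = LFQTable(table.intensities.iloc[perm], dict(table.flags),
                            dict(table.groups))
        with pytest.warns(UserWarning):
            c1, f1 = permutation_fdr(table, PRESET_STRICT)
        with pytest.warns(UserWarning):
            c2, f2 = permutation_fdr(shuffled, PRESET_STRICT)
        assert c1 == pytest.approx(c2)
        pd.testing.assert_frame_equal(f1.sort_index(), f2.sort_index())

    def test_missing_values_rejected(self):
        t = _table(20, missing=0.2)
        with pytest.raises(ValueError):
            permutation_fdr(t, PRESET_STRICT)


class TestVolcano:
    def test_planted_bait_side_and_row_conservation(self):
        table, truth = _planted(seed=9)
        with pytest.warns(UserWarning):
            rows = volcano(table, PRESET_STRICT)
        assert len(rows) == len(table.intensities)
        by_id = {r.protein_id: r for r in rows}
        for pid in truth.ipms_enriched:
            assert by_id[pid].side == "bait"
            assert by_id[pid].p_value < 0.01
        null_sides = [r.side for r in rows if r.protein_id not in truth.ipms_enriched]
        assert set(null_sides) == {"none"}

    def test_pvalue_is_classical_student_t(self):
        table, _ = _planted(seed=10)
        with pytest.warns(UserWarning):
            rows = volcano(table, PRESET_STRICT)
        X = table.intensities
        r0 = rows[0]
        p = stats.ttest_ind(X.iloc[0, :3], X.iloc[0, 3:], equal_var=True).pvalue
        assert r0.p_value == pytest.approx(p, abs=1e-12)
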