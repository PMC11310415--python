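"""Row filters, log2, validity filter, imputation, PCA, s0 test, FDR."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prodomain_evo import simulate as sim
from prodomain_evo.enrich import (
    EnrichConfig,
    IntensityTable,
    balanced_permutations,
    filter_rows,
    impute,
    log2_transform,
    pca,
    permutation_fdr,
    read_protein_groups,
    run_enrichment,
    s0_test,
    validity_filter,
    volcano_export,
)

GROUPS_4V4 = {
    **{f"target_{i}": "target" for i in range(1, 5)},
    **{f"control_{i}": "control" for i in range(1, 5)},
}
SAMPLES = list(GROUPS_4V4)


def make_table(values: np.ndarray, flags: dict[str, list[bool]] | None = None) -> IntensityTable:
    intensities = pd.DataFrame(values, columns=SAMPLES)
    intensities.index = pd.Index([f"P{i}" for i in range(len(intensities))], name="Protein IDs")
    flag_df = pd.DataFrame(False, index=intensities.index,
                           columns=["Potential contaminant", "Reverse", "Only identified by site"])
    for col, vals in (flags or {}).items():
        flag_df[col] = vals
    return IntensityTable(intensities=intensities, flags=flag_df, groups=dict(GROUPS_4V4))


class TestRowFilters:
    def test_no_flags_identity(self, rng):
        table = make_table(rng.uniform(1, 2, size=(10, 8)))
        kept, counts = filter_rows(table)
        assert len(kept.intensities) == 10
        assert counts["removed"] == 0

    def test_flagged_rows_removed_once(self, rng):
        flags = {
            "Potential contaminant": [True, False, True] + [False] * 7,
            "Reverse": [True, False, False, True] + [False] * 6,  # row 0 double-flagged
        }
        table = make_table(rng.uniform(1, 2, size=(10, 8)), flags)
        kept, counts = filter_rows(table)
        assert len(kept.intensities) == 7
        assert counts["removed"] == 3


class TestLog2:
    def test_elementwise_and_missing_preserved(self):
        df = pd.DataFrame({"a": [8.0, 1.0, np.nan]})
        out = log2_transform(df)
        assert out["a"].tolist()[:2] == [3.0, 0.0]
        assert np.isnan(out["a"].iloc[2])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(pd.DataFrame({"a": [4.0, -1.0]}))


class TestValidityFilter:
    def test_one_full_group_suffices(self):
        row_full_target = [20.0] * 4 + [np.nan] * 4
        row_three_three = [20.0, 20, 20, np.nan, 20, 20, 20, np.nan]
        row_all_valid = [20.0] * 8
        df = pd.DataFrame([row_full_target, row_three_three, row_all_valid], columns=SAMPLES)
        kept = validity_filter(df, GROUPS_4V4)
        assert kept.index.tolist() == [0, 2]

    def test_min_valid_override(self):
        row = [20.0, 20, 20, np.nan, np.nan, np.nan, np.nan, np.nan]
        df = pd.DataFrame([row], columns=SAMPLES)
        assert len(validity_filter(df, GROUPS_4V4)) == 0
        assert len(validity_filter(df, GROUPS_4V4, min_valid=3)) == 1


class TestImpute:
    def test_no_missing_is_identity(self, rng):
        df = pd.DataFrame(rng.normal(25, 2, size=(50, 8)), columns=SAMPLES)
        out = impute(df, seed=0)
        pd.testing.assert_frame_equal(df, out)

    def test_downshifted_mean_large_sample(self, rng):
        """Column mean 25, SD 2, downshift 1.8 -> imputed mean ~ 21.4."""
        observed = rng.normal(25, 2, size=10_000)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        df = pd.DataFrame({"target_1": col, "target_2": np.ones_like(col)})
        df["target_2"] = 0.5  # constant companion column, no missing
        out = impute(df, width=0.3, downshift=1.8, seed=42)
        imputed = out["target_1"].iloc[10_000:]
        mu, sd = observed.mean(), observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, abs=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_same_seed_identical(self, rng):
        df = pd.DataFrame(rng.normal(25, 2, size=(60, 8)), columns=SAMPLES)
        df.iloc[::7, 3] = np.nan
        a = impute(df, seed=9)
        b = impute(df, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_observed_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan, 20.0]})
        with pytest.raises(ValueError):
            impute(df, seed=0)


class TestPca:
    def test_group_shift_separates_on_pc1(self):
        base = np.full((100, 8), 25.0)
        base[:50, :4] += 3.0  # half the proteins shifted in the target samples
        noise = np.random.default_rng(0).normal(0, 0.01, size=base.shape)
        df = pd.DataFrame(base + noise, columns=SAMPLES)
        res = pca(df)
        pc1 = res.coordinates["PC1"]
        target = pc1[[s for s in SAMPLES if s.startswith("target")]]
        control = pc1[[s for s in SAMPLES if s.startswith("control")]]
        assert (target.max() < control.min()) or (control.max() < target.min())
        assert res.explained_variance_ratio[0] > 0.9

    def test_identical_samples_degenerate_but_defined(self):
        df = pd.DataFrame(np.full((30, 8), 25.0), columns=SAMPLES)
        res = pca(df)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_components_orthogonal(self, rng):
        df = pd.DataFrame(rng.normal(25, 2, size=(40, 8)), columns=SAMPLES)
        coords = pca(df).coordinates.to_numpy()
        gram = coords.T @ coords
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-6)


class TestS0Test:
    def test_equal_means_give_zero(self):
        X = np.tile([20.0, 21, 22, 23], (5, 2))
        df = pd.DataFrame(X, columns=SAMPLES)
        for s0 in (0.0, 1.0, 2.0):
            res = s0_test(df, GROUPS_4V4, s0, "target", "control")
            assert np.allclose(res["d"], 0.0)

    def test_s0_zero_matches_classical_t(self, rng):
        X = rng.normal(25, 2, size=(200, 8))
        df = pd.DataFrame(X, columns=SAMPLES)
        res = s0_test(df, GROUPS_4V4, 0.0, "target", "control")
        t_ref, p_ref = stats.ttest_ind(X[:, :4], X[:, 4:], axis=1)
        assert np.allclose(res["d"], t_ref, atol=1e-12)
        assert np.allclose(res["p_value"], p_ref, atol=1e-12)

    def test_worked_4v4_example(self):
        """Hand-checked pooled-variance t statistic on a single vector pair."""
        a = np.array([24.0, 25.0, 26.0, 27.0])
        b = np.array([22.0, 23.0, 24.0, 21.0])
        df = pd.DataFrame([np.concatenate([a, b])], columns=SAMPLES)
        res = s0_test(df, GROUPS_4V4, 0.0, "target", "control")
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * 0.5)
        assert res["d"].iloc[0] == pytest.approx(t_hand)

    def test_abs_d_strictly_decreases_in_s0(self, rng):
        X = rng.normal(25, 2, size=(50, 8))
        X[:, :4] += 1.0
        df = pd.DataFrame(X, columns=SAMPLES)
        d_prev = np.abs(s0_test(df, GROUPS_4V4, 0.0, "target", "control")["d"])
        for s0 in (0.5, 1.0, 2.0, 4.0):
            d_now = np.abs(s0_test(df, GROUPS_4V4, s0, "target", "control")["d"])
            nonzero = d_prev > 0
            assert (d_now[nonzero] < d_prev[nonzero]).all()
            d_prev = d_now

    def test_antisymmetric_under_group_swap(self, rng):
        X = rng.normal(25, 2, size=(50, 8))
        df = pd.DataFrame(X, columns=SAMPLES)
        fwd = s0_test(df, GROUPS_4V4, 2.0, "target", "control")
        rev = s0_test(df, GROUPS_4V4, 2.0, "control", "target")
        assert np.allclose(fwd["d"], -rev["d"])

    def test_zero_variance_with_s0_zero_flagged_infinite(self):
        X = np.tile([20.0] * 4 + [22.0] * 4, (1, 1))
        df = pd.DataFrame(X, columns=SAMPLES)
        res = s0_test(df, GROUPS_4V4, 0.0, "target", "control")
        assert np.isinf(res["d"].iloc[0])


class TestPermutations:
    def test_4v4_enumeration_count(self, rng):
        perms = balanced_permutations(4, 4, 1000, rng)
        assert len(perms) == 34  # 35 complement-distinct labelings minus identity
        seen = {tuple(idx1) for idx1, _ in perms}
        assert (0, 1, 2, 3) not in seen
        assert len(seen) == 34

    def test_subsampling_cap(self, rng):
        perms = balanced_permutations(6, 6, 50, rng)
        assert len(perms) == 50


class TestPermutationFdr:
    def _run(self, X, s0=2.0, fdr=0.01, seed=0):
        df = pd.DataFrame(X, columns=SAMPLES)
        return permutation_fdr(df, GROUPS_4V4, EnrichConfig(s0=s0, fdr=fdr, seed=seed),
                               "target", "control")

    def test_spiked_proteins_all_called_with_direction(self, rng):
        X = rng.normal(25, 0.5, size=(1000, 8))
        X[:50, :4] += 4.0
        res = self._run(X)
        called = res.table["significant"].to_numpy()
        assert called[:50].all()
        assert not called[50:].any()
        assert (res.table["direction"].iloc[:50] == "target").all()
        assert res.n_target_enriched == 50

    def test_null_makes_no_calls(self, rng):
        X = rng.normal(25, 0.5, size=(1000, 8))
        res = self._run(X)
        assert res.n_significant == 0
        assert res.threshold_d == np.inf

    def test_fdr_one_calls_everything_nonzero(self, rng):
        X = rng.normal(25, 0.5, size=(200, 8))
        res = self._run(X, fdr=1.0)
        nonzero = res.table["d"].abs() > 0
        assert res.table.loc[nonzero, "significant"].all()

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(25, 0.5, size=(300, 8))
        X[:10, :4] += 3.0
        a = self._run(X, seed=5)
        b = self._run(X, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.threshold_d == b.threshold_d


class TestVolcanoExport:
    def test_roundtrip_and_flag_consistency(self, rng, tmp_path):
        X = rng.normal(25, 0.5, size=(200, 8))
        X[:10, :4] += 4.0
        df = pd.DataFrame(X, columns=SAMPLES)
        df.index = pd.Index([f"P{i}" for i in range(200)], name="Protein IDs")
        res = permutation_fdr(df, GROUPS_4V4, EnrichConfig(seed=1), "target", "control")
        path = tmp_path / "volcano.tsv"
        out = volcano_export(res, path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        assert back["significant"].sum() == res.n_significant
        pd.testing.assert_frame_equal(
            back, out, check_dtype=False, check_exact=False, rtol=1e-12
        )
        # every significant protein is flagged in the export
        assert set(res.table.index[res.table.significant]) == set(back.index[back.significant])


class TestMaxQuantDialect:
    def test_read_protein_groups_zero_as_missing_and_flags(self):
        tsv = (
            "Protein IDs\tLFQ intensity target_1\tLFQ intensity control_1\t"
            "LFQ intensity target_2\tLFQ intensity control_2\tPotential contaminant\tReverse\n"
            "P1\t100\t0\t150\t90\t\t\n"
            "P2\t10\t20\t30\t40\t+\t\n"
        )
        groups = {"target_1": "t", "target_2": "t", "control_1": "c", "control_2": "c"}
        table = read_protein_groups(io.StringIO(tsv), groups)
        assert np.isnan(table.intensities.loc["P1", "control_1"])
        assert table.flags.loc["P2", "Potential contaminant"]
        assert list(table.intensities.columns) == list(groups)


class TestFullPipeline:
    def test_stage_counts_and_sensitivity(self):
        df, truth = sim.simulate_lfq(sim.LfqSimConfig(seed=3))
        table = read_protein_groups(io.StringIO(df.to_csv(sep="\t", index=False)),
                                    truth["groups"])
        res = run_enrichment(table, EnrichConfig(seed=3), "target", "control")
        assert res.counts["after_row_filter"] < res.counts["input_rows"]
        assert res.counts["after_validity_filter"] <= res.counts["after_row_filter"]
        called = set(res.table.index[res.table.significant & (res.table.direction == "target")])
        surviving_truth = set(truth["enriched_ids"]) & set(res.table.index)
        assert len(called & surviving_truth) / len(surviving_truth) >= 0.95
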