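from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import hsctrace as h
from hsctrace.stats import StatsError, ZeroVarianceError


def _t_pvalue_from_betainc(t, df):
    """P(|T| > t) via the regularized incomplete beta identity — a route
    independent of scipy.stats' t-distribution code."""
    return float(scipy.special.betainc(df / 2.0, 0.5, df / (df + t * t)))


class TestTTest:
    def test_paired_matches_hand_computation(self):
        x = [2.0, 2.0, 4.0, 4.0, 7.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        # diffs [1,0,1,0,2]: mean .8, var .7 -> t = .8 / sqrt(.7/5)
        res = h.t_test(x, y, paired=True)
        expected_t = 0.8 / np.sqrt(0.7 / 5.0)
        assert res["t"] == pytest.approx(expected_t, abs=1e-12)
        assert res["df"] == 4
        assert res["p"] == pytest.approx(_t_pvalue_from_betainc(expected_t, 4), abs=1e-12)

    def test_welch_matches_hand_computation(self):
        x = [1.0, 2.0, 3.0]
        y = [6.0, 8.0]
        # means 2 and 7; vars 1 and 2; se^2 = 1/3 + 1 = 4/3
        expected_t = -5.0 / np.sqrt(4.0 / 3.0)
        expected_df = (4.0 / 3.0) ** 2 / ((1.0 / 3.0) ** 2 / 2.0 + 1.0**2 / 1.0)
        res = h.t_test(x, y, paired=False)
        assert res["t"] == pytest.approx(expected_t, abs=1e-12)
        assert res["df"] == pytest.approx(expected_df, abs=1e-12)
        assert res["p"] == pytest.approx(
            _t_pvalue_from_betainc(abs(expected_t), expected_df), abs=1e-12
        )

    def test_zero_variance_raises_never_silently_zero(self):
        with pytest.raises(ZeroVarianceError):
            h.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)  # x == y
        with pytest.raises(ZeroVarianceError):
            h.t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0], paired=True)  # diffs all 1
        with pytest.raises(StatsError):
            h.t_test([1.0], [2.0], paired=True)


def _mwu_enumeration(x, y):
    """Exhaustive permutation oracle for untied samples."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)

    def u_stat(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    observed = u_stat(range(n1))
    us = np.array([u_stat(c) for c in combinations(range(len(pooled)), n1)])
    p = 2.0 * min((us >= observed).mean(), (us <= observed).mean())
    return observed, min(1.0, p)


class TestMannWhitney:
    def test_complete_separation(self):
        res = h.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res["U"] == 0.0

    def test_identical_multisets_give_half_n_squared(self):
        res = h.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["U"] == 9 / 2  # n^2 / 2 by symmetry, midranks for ties
        assert res["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_small_samples_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 8, size=2)
        pool = rng.permutation(np.arange(1.0, 20.0))
        x, y = pool[:nx], pool[nx:nx + ny]
        expected_u, expected_p = _mwu_enumeration(x, y)
        res = h.mann_whitney_u(x, y)
        assert res["method"] == "exact"
        assert res["U"] == expected_u
        assert res["p"] == pytest.approx(expected_p, abs=1e-12)

    def test_large_or_tied_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(1, 6, size=25).astype(float)
        res = h.mann_whitney_u(x, y)
        assert res["method"] == "asymptotic"
        assert 0.0 < res["p"] <= 1.0
        with pytest.raises(StatsError):
            h.mann_whitney_u([], [1.0])


class TestBonferroni:
    def test_examples(self):
        assert h.bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert h.bonferroni([0.5], m=5)[0] == 1.0  # capped

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20))
    def test_matches_formula_and_never_decreases(self, p):
        adj = h.bonferroni(p)
        np.testing.assert_allclose(adj, np.minimum(1.0, len(p) * np.asarray(p)))
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestSubtypeProportions:
    def test_hand_example_and_normalization(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["S1"] * 60,
                "lineage": ["T"] * 60,
                "subtype": ["CD4 T"] * 30 + ["CD8 T"] * 30,
            },
            index=[f"c{i}" for i in range(60)],
        )
        props = h.subtype_proportions(meta, denominator="lineage")
        assert props.loc[props["subtype"] == "CD4 T", "proportion"].iloc[0] == 0.5
        assert props.groupby(["sample_id", "lineage"])["proportion"].sum().eq(1.0).all()

    def test_matches_counting_oracle(self, cohort):
        meta = cohort.matrix.obs
        props = h.subtype_proportions(meta, denominator="all_cells")
        for row in props.sample(25, random_state=0).itertuples(index=False):
            sub = meta[meta["sample_id"] == row.sample_id]
            assert row.n_cells == int((sub["subtype"] == row.subtype).sum())
            assert row.proportion == pytest.approx(row.n_cells / len(sub))


class TestDifferentialAbundance:
    def _design(self):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(6)],
                "patient_id": [f"P{i}" for i in range(6)],
                "timepoint": ["D30"] * 6,
                "agvhd_grade": ["II-IV"] * 3 + ["0-I"] * 3,
            }
        )

    def test_identical_groups_give_zero_log2fc(self):
        props = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(6)],
                "lineage": "T",
                "subtype": "Treg",
                "n_cells": 10,
                "denominator": 100,
                "proportion": 0.1,
            }
        )
        res = h.differential_abundance(props, self._design(), ("agvhd_grade", "II-IV", "0-I"))
        assert res["log2fc"].iloc[0] == 0.0
        assert res["untested"].iloc[0]  # no variance: flagged, not p=0

    def test_adjustment_is_rowwise_bonferroni(self):
        rng = np.random.default_rng(6)
        rows = []
        for s in range(6):
            for sub in ("A", "B", "C"):
                rows.append(
                    {
                        "sample_id": f"S{s}", "lineage": "T", "subtype": sub,
                        "n_cells": 10, "denominator": 100,
                        "proportion": rng.uniform(0.05, 0.3),
                    }
                )
        res = h.differential_abundance(
            pd.DataFrame(rows), self._design(), ("agvhd_grade", "II-IV", "0-I")
        )
        np.testing.assert_allclose(
            res["p_adjusted"], np.minimum(1.0, len(res) * res["p_value"])
        )

    def test_planted_treg_depletion_recovered(self):
        cfg = h.SimConfig(
            timepoints=("Graft", "D30"),
            cells_per_sample=600,
            group_subtype_multiplier={"II-IV": {"Treg": 0.5}},
            seed=7,
        )
        sim = h.simulate_cohort(cfg)
        obs = sim.matrix.obs
        d30 = obs[obs["timepoint"] == "D30"]
        props = h.subtype_proportions(d30)
        res = h.differential_abundance(props, sim.design, ("agvhd_grade", "II-IV", "0-I"))
        treg = res[res["subtype"] == "Treg"].iloc[0]
        # halved weight renormalizes to log2(0.0526/0.1) ~ -0.93
        assert -1.5 < treg["log2fc"] < -0.4
        assert treg["p_value"] < 0.05


class TestCytokineScreen:
    def _fractions(self):
        return pd.DataFrame(
            {
                "donor": ["D1", "D2", "D3"] * 2,
                "condition": ["PBS"] * 3 + ["IL12"] * 3,
                "cell_class": "CD4 T",
                "fraction": [0.05, 0.06, 0.04, 0.10, 0.13, 0.09],
                "n_cells": 2000,
            }
        )

    def test_swapping_arms_negates_log2fc_exactly(self):
        fr = self._fractions()
        res = h.cytokine_screen(fr, baseline_label="PBS")
        swapped = fr.copy()
        swapped["condition"] = swapped["condition"].map({"PBS": "IL12", "IL12": "PBS"})
        res_swapped = h.cytokine_screen(swapped, baseline_label="PBS")
        assert res_swapped["log2fc"].iloc[0] == -res["log2fc"].iloc[0]
        assert res_swapped["p_value"].iloc[0] == pytest.approx(res["p_value"].iloc[0])

    def test_missing_baseline_donor_dropped_with_warning(self, caplog):
        fr = self._fractions()
        fr = fr[~((fr["donor"] == "D3") & (fr["condition"] == "PBS"))]
        with caplog.at_level("WARNING", logger="hsctrace"):
            res = h.cytokine_screen(fr)
        assert "without baseline" in caplog.text
        assert res["n_donors"].iloc[0] == 2

    def test_identical_arms_hit_zero_variance_path(self):
        fr = self._fractions()
        fr.loc[fr["condition"] == "IL12", "fraction"] = [0.05, 0.06, 0.04]
        res = h.cytokine_screen(fr)
        assert res["untested"].iloc[0]
        assert not res["significant"].iloc[0]

    def test_no_baseline_at_all_is_error(self):
        fr = self._fractions()
        with pytest.raises(StatsError, match="baseline"):
            h.cytokine_screen(fr[fr["condition"] != "PBS"])


class TestPseudobulk:
    def test_single_cell_group_equals_its_row(self, cohort):
        adata = cohort.matrix[:5]
        table = h.aggregate_pseudobulk(adata, group_keys=("sample_id",))
        dense = np.asarray(adata.X.todense()).sum(axis=0)
        np.testing.assert_array_equal(table.sum(axis=0).to_numpy(), dense)

    def test_conservation_and_loop_oracle(self):
        rng = np.random.default_rng(9)
        import anndata
        import scipy.sparse as sp

        counts = rng.integers(0, 5, size=(40, 7))
        groups = rng.choice(["a", "b", "c"], size=40)
        adata = anndata.AnnData(
            X=sp.csr_matrix(counts),
            obs=pd.DataFrame(
                {"sample_id": groups, "lineage": rng.choice(["T", "B"], size=40)},
                index=[f"c{i}" for i in range(40)],
            ),
        )
        table = h.aggregate_pseudobulk(adata, group_keys=("sample_id", "lineage"))
        np.testing.assert_array_equal(
            table.sum(axis=0).to_numpy(), counts.sum(axis=0)
        )  # per-gene conservation
        for key, frame in table.iterrows():
            sample, lineage = key.split("|")
            mask = (adata.obs["sample_id"] == sample) & (adata.obs["lineage"] == lineage)
            np.testing.assert_array_equal(frame.to_numpy(), counts[mask.to_numpy()].sum(axis=0))


class TestDeltaDeltaCt:
    def _table(self):
        rows = []
        for rep, (t, r) in enumerate(zip([20.1, 20.0, 19.9], [15.0, 15.1, 14.9])):
            rows.append(("S1", "aGvHD", "MDGA1", rep, t))
            rows.append(("S1", "aGvHD", "GAPDH", rep, r))
        # two reference-group samples with delta Ct 3.5 and 4.5 (mean 4.0)
        for rep in range(3):
            rows += [
                ("R1", "non-aGvHD", "MDGA1", rep, 19.5), ("R1", "non-aGvHD", "GAPDH", rep, 16.0),
                ("R2", "non-aGvHD", "MDGA1", rep, 19.0), ("R2", "non-aGvHD", "GAPDH", rep, 14.5),
            ]
        return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"])

    def test_triplicate_worked_example(self):
        res = h.delta_delta_ct(self._table()).set_index("sample_id")
        assert res.loc["S1", "delta_ct"] == pytest.approx(5.0, abs=1e-12)
        assert res.loc["S1", "delta_delta_ct"] == pytest.approx(1.0, abs=1e-12)
        assert res.loc["S1", "rq"] == pytest.approx(0.5, abs=1e-12)

    def test_reference_group_geometric_mean_is_one(self):
        res = h.delta_delta_ct(self._table())
        ref = res[res["group"] == "non-aGvHD"]
        assert np.exp(np.log(ref["rq"]).mean()) == pytest.approx(1.0, abs=1e-12)
        assert (res["rq"] > 0).all()

    def test_rq_inverts_sign_of_ddct(self):
        table = self._table()
        res = h.delta_delta_ct(table).set_index("sample_id")
        # sample at delta Ct 3.0 would have ddCt -1 -> RQ 2; emulate via R2
        assert res.loc["R2", "delta_ct"] == pytest.approx(4.5)
        assert res.loc["R2", "rq"] == pytest.approx(2.0 ** -(4.5 - 4.0))

    def test_sample_missing_reference_gene_dropped(self, caplog):
        table = self._table()
        table = table[~((table["sample_id"] == "S1") & (table["gene"] == "GAPDH"))]
        with caplog.at_level("WARNING", logger="hsctrace"):
            res = h.delta_delta_ct(table)
        assert "S1" not in set(res["sample_id"])
        assert "dropping 1 samples" in caplog.text


def test_percentage_helper():
    assert h.percentage(1, 3, ndigits=2) == 33.33
    with pytest.raises(StatsError):
        h.percentage(1, 0)
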