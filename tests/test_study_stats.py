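import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tmmeta.study_stats import (
    average_replicates,
    differential_stats,
    fit_variance_prior,
    map_and_deduplicate,
)

from conftest import make_matrix


class TestAverageReplicates:
    def test_mean_of_two_replicates(self):
        m = make_matrix(
            [[1.0, 3.0, 5.0, 7.0]],
            individuals=["I1", "I1", "I1", "I1"],
            conditions=["treated", "treated", "control", "control"],
            replicates=[1, 2, 1, 2],
        )
        out = average_replicates(m)
        assert out.values.loc["p0", "I1:treated"] == 2.0
        assert out.values.loc["p0", "I1:control"] == 6.0

    def test_no_replicates_is_identity_up_to_labels(self, two_group_matrix):
        m = make_matrix(
            two_group_matrix.values.to_numpy(),
            individuals=[f"I{j % 4}" for j in range(8)],
            conditions=["treated"] * 4 + ["control"] * 4,
        )
        out = average_replicates(m)
        assert out.values.shape == m.values.shape
        np.testing.assert_allclose(
            np.sort(out.values.to_numpy(), axis=1), np.sort(m.values.to_numpy(), axis=1)
        )

    def test_brute_force_group_means(self, rng):
        vals = rng.normal(size=(4, 18))
        inds = [f"I{k}" for k in range(3) for _ in range(6)]
        conds = (["treated"] * 3 + ["control"] * 3) * 3
        reps = [1, 2, 3] * 6
        m = make_matrix(vals, individuals=inds, conditions=conds, replicates=reps)
        out = average_replicates(m)
        for k in range(3):
            for cond, sl in (("treated", slice(0, 3)), ("control", slice(3, 6))):
                cols = [6 * k + j for j in range(6)][sl]
                np.testing.assert_allclose(
                    out.values[f"I{k}:{cond}"].to_numpy(), vals[:, cols].mean(axis=1)
                )

    def test_unpaired_individual_excluded(self, caplog):
        m = make_matrix(
            [[1.0, 2.0, 3.0]],
            individuals=["I1", "I1", "I2"],
            conditions=["treated", "control", "treated"],
        )
        with caplog.at_level("WARNING"):
            out = average_replicates(m)
        assert list(out.values.columns) == ["I1:treated", "I1:control"]
        assert any("I2" in rec.message for rec in caplog.records)


class TestDifferentialStats:
    def test_noiseless_logfc_and_zero_variance(self):
        m = make_matrix(
            [[2.0, 2.0, 1.0, 1.0]],
            individuals=["I1", "I2", "I3", "I4"],
            conditions=["treated", "treated", "control", "control"],
        )
        out = differential_stats(m, moderate=False)
        assert out.loc["p0", "logFC"] == 1.0
        assert out.loc["p0", "flag"] == "zero_variance" or out.loc["p0", "p_value"] <= 1.0

    def test_matches_textbook_pooled_t(self, two_group_matrix):
        out = differential_stats(two_group_matrix, moderate=False)
        vals = two_group_matrix.values.to_numpy()
        t_grp, c_grp = vals[:, :4], vals[:, 4:]
        for i, probe in enumerate(two_group_matrix.values.index):
            sp2 = (t_grp[i].var(ddof=1) * 3 + c_grp[i].var(ddof=1) * 3) / 6
            t_ref = (t_grp[i].mean() - c_grp[i].mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
            p_ref = 2 * sps.t.sf(abs(t_ref), df=6)
            assert out.iloc[i]["t_stat"] == pytest.approx(t_ref, rel=1e-12)
            assert out.iloc[i]["p_value"] == pytest.approx(p_ref, rel=1e-12)

    def test_null_pvalues_are_uniform(self):
        passes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = make_matrix(
                rng.normal(size=(500, 8)),
                individuals=[f"I{j}" for j in range(8)],
                conditions=["treated"] * 4 + ["control"] * 4,
            )
            p = differential_stats(m, moderate=False)["p_value"].to_numpy()
            ks = sps.kstest(p, "uniform").statistic
            if ks < 1.628 / np.sqrt(500):  # 1% critical value
                passes += 1
        assert passes >= 9

    def test_one_vs_one_yields_flagged_p_of_one(self):
        m = make_matrix(
            [[2.0, 1.0]], individuals=["I1", "I2"], conditions=["treated", "control"]
        )
        out = differential_stats(m, moderate=False)
        assert out.loc["p0", "p_value"] == 1.0
        assert out.loc["p0", "flag"] == "no_residual_df"
        assert not out.isna().any().any()

    def test_label_swap_negates_logfc_preserves_p(self, two_group_matrix):
        out = differential_stats(two_group_matrix, moderate=False)
        swapped = make_matrix(
            two_group_matrix.values.to_numpy(),
            individuals=[f"I{j}" for j in range(8)],
            conditions=["control"] * 4 + ["treated"] * 4,
        )
        out2 = differential_stats(swapped, moderate=False)
        np.testing.assert_allclose(out2["logFC"], -out["logFC"])
        np.testing.assert_allclose(out2["p_value"], out["p_value"])

    def test_moderation_shrinks_toward_common_variance(self, rng):
        # all probes share true variance 1 -> with many probes d0 is large and
        # moderated variances are much less dispersed than raw ones
        vals = rng.normal(0, 1, size=(2000, 6))
        m = make_matrix(
            vals, individuals=[f"I{j}" for j in range(6)],
            conditions=["treated"] * 3 + ["control"] * 3,
        )
        fit = fit_variance_prior(vals[:, :3].var(axis=1, ddof=1), d=2)
        assert fit.s0_sq == pytest.approx(1.0, rel=0.2)
        out_mod = differential_stats(m, moderate=True)
        out_raw = differential_stats(m, moderate=False)
        assert np.isfinite(out_mod["p_value"]).all()
        # moderated |t| is less heavy-tailed than unmoderated at n=3+3
        assert np.quantile(np.abs(out_mod["t_stat"]), 0.99) < np.quantile(
            np.abs(out_raw["t_stat"]), 0.99
        )

    def test_paired_mode_matches_one_sample_t(self, rng):
        vals = rng.normal(size=(30, 8))
        m = make_matrix(
            vals,
            individuals=[f"I{j % 4}" for j in range(8)],
            conditions=["treated"] * 4 + ["control"] * 4,
        )
        out = differential_stats(m, moderate=False, paired=True)
        diffs = vals[:, :4] - vals[:, 4:]
        t_ref = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / 2)
        np.testing.assert_allclose(out["t_stat"], t_ref, rtol=1e-10)


class TestMapAndDeduplicate:
    @staticmethod
    def _stats(rows):
        df = pd.DataFrame(rows, columns=["probe_id", "logFC", "p_value"]).set_index("probe_id")
        df["t_stat"] = 0.0
        df["mean_expression"] = 7.0
        df["flag"] = ""
        return df

    def test_highest_combined_change_wins(self):
        # scores: |1.0 * 1| = 1.0 vs |0.5 * 3| = 1.5 -> second kept
        stats = self._stats([("a", 1.0, 0.1), ("b", 0.5, 0.001)])
        pmap = pd.DataFrame({"probe_id": ["a", "b"], "gene_id": ["G1", "G1"]})
        kept, summary = map_and_deduplicate(stats, pmap, "s1", 3)
        assert len(kept) == 1
        assert kept.iloc[0]["probe_id"] == "b"
        assert kept.iloc[0]["logFC"] == 0.5  # selection never edits values

    def test_single_probe_gene_passes_through(self):
        stats = self._stats([("a", 0.3, 0.2)])
        pmap = pd.DataFrame({"probe_id": ["a"], "gene_id": ["G1"]})
        kept, _ = map_and_deduplicate(stats, pmap)
        assert kept.iloc[0][["logFC", "p_value"]].tolist() == [0.3, 0.2]

    def test_exact_tie_keeps_smallest_probe_id(self):
        stats = self._stats([("z9", 1.0, 0.01), ("a1", 1.0, 0.01)])
        pmap = pd.DataFrame({"probe_id": ["z9", "a1"], "gene_id": ["G1", "G1"]})
        kept, _ = map_and_deduplicate(stats, pmap)
        assert kept.iloc[0]["probe_id"] == "a1"

    def test_unmapped_probes_counted_not_silently_dropped(self):
        stats = self._stats([("a", 1.0, 0.01), ("orphan", 2.0, 0.01)])
        pmap = pd.DataFrame({"probe_id": ["a"], "gene_id": ["G1"]})
        kept, summary = map_and_deduplicate(stats, pmap)
        assert summary["n_unmapped"] == 1
        assert summary["n_genes"] == 1

    def test_kept_score_dominates_discarded(self, rng):
        n = 200
        stats = self._stats(
            [(f"p{i}", rng.normal(), float(rng.uniform(1e-6, 1))) for i in range(n)]
        )
        pmap = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(n)],
             "gene_id": [f"G{i % 40}" for i in range(n)]}
        )
        kept, _ = map_and_deduplicate(stats, pmap)
        scores = (stats["logFC"] * -np.log10(stats["p_value"])).abs()
        for _, row in kept.iterrows():
            gene_probes = pmap[pmap["gene_id"] == row["gene_id"]]["probe_id"]
            assert row["dedup_score"] >= scores[gene_probes].max() - 1e-12
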