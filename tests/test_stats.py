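"""Replicate t tests, BH-FDR and regulated-peptide classification."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from silacphos.errors import ConfigurationError, ValidationError
from silacphos.quant import compute_ratio, normalize_replicates, sum_by_peptide
from silacphos.simulate import SyntheticConfig, simulate_dataset
from silacphos.stats import (
    bh_fdr,
    classify,
    differential_analysis,
    filter_min_replicates,
    moderated_t,
    volcano_table,
)
from silacphos.stats import test_peptide as one_sample_test
from silacphos.stats import test_peptides as one_sample_test_table


def _long(values_by_peptide):
    rows = []
    for key, vals in values_by_peptide.items():
        for j, v in enumerate(vals):
            rows.append((key, f"R{j + 1}", v, True))
    return pd.DataFrame(rows, columns=[
        "peptide_key", "replicate_id", "normalized_log2_ratio", "is_phospho",
    ])


def bh_bruteforce(pvals):
    """Literal step-up definition: q_i = min_{j: p_j >= p_i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestReplicateFilter:
    def test_thresholds(self):
        data = _long({
            "AAsK": [0.1, 0.2],            # 2 replicates -> out at min 3
            "CCsK": [0.1, 0.2, 0.3],       # 3 -> in
            "DDsK": [0.1, 0.2, 0.3, 0.4],  # 4 -> in
        })
        kept, n_excluded = filter_min_replicates(data, min_replicates=3)
        assert set(kept["peptide_key"]) == {"CCsK", "DDsK"}
        assert n_excluded == 1

    def test_identity_when_all_complete(self):
        data = _long({"AAsK": [0.1] * 4, "CCsK": [0.2] * 4})
        kept, n_excluded = filter_min_replicates(data, min_replicates=3)
        assert n_excluded == 0
        assert len(kept) == len(data)

    def test_min_replicates_validation(self):
        with pytest.raises(ConfigurationError):
            filter_min_replicates(_long({"AAsK": [0.1] * 4}), min_replicates=1)

    def test_nan_ratios_do_not_count(self):
        data = _long({"AAsK": [0.1, 0.2, 0.3]})
        data.loc[2, "normalized_log2_ratio"] = np.nan
        kept, n_excluded = filter_min_replicates(data, min_replicates=3)
        assert kept.empty and n_excluded == 1


class TestTTest:
    def test_matches_direct_formula(self):
        vals = [1.0, 1.2, 0.8]
        mean, p = one_sample_test(vals)
        t = np.mean(vals) / (np.std(vals, ddof=1) / np.sqrt(3))
        expected = 2 * sps.t.sf(abs(t), 2)
        assert mean == pytest.approx(1.0)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_ttest_1samp(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.4, 0.3, 6)
        _, p = one_sample_test(vals)
        assert p == pytest.approx(sps.ttest_1samp(vals, 0.0).pvalue, rel=1e-12)

    def test_zero_variance_degenerate(self):
        mean, p = one_sample_test([0.0, 0.0, 0.0, 0.0])
        assert mean == 0.0 and p == 1.0
        mean, p = one_sample_test([0.5, 0.5, 0.5])
        assert mean == 0.5 and 0 < p < 1e-300

    def test_negation_symmetry(self):
        vals = [1.0, 1.2, 0.8, 0.5]
        m1, p1 = one_sample_test(vals)
        m2, p2 = one_sample_test([-v for v in vals])
        assert m2 == -m1 and p2 == p1

    def test_vectorized_agrees_with_scalar(self):
        data = _long({"AAsK": [1.0, 1.2, 0.8], "CCsK": [-0.2, 0.1, 0.05, 0.3]})
        res = one_sample_test_table(data).set_index("peptide_key")
        for key, vals in (("AAsK", [1.0, 1.2, 0.8]),
                          ("CCsK", [-0.2, 0.1, 0.05, 0.3])):
            m, p = one_sample_test(vals)
            assert res.loc[key, "mean_log2"] == pytest.approx(m)
            assert res.loc[key, "p_value"] == pytest.approx(p, rel=1e-12)


class TestModeratedT:
    def test_matches_limma_ebayes(self, tmp_path):
        """Empirical-Bayes moderation reproduces limma::eBayes p-values."""
        rng = np.random.default_rng(3)
        sds = np.exp(rng.normal(-1.2, 0.8, 40))
        mat = rng.normal(0, sds[:, None], (40, 4))
        mat[:4] += 1.0
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "p.tsv"
        pd.DataFrame(mat).to_csv(mat_path, sep="\t", index=False, header=False)
        script = (
            'suppressMessages(library(limma));'
            f'm <- as.matrix(read.table("{mat_path}", sep="\\t"));'
            'fit <- eBayes(lmFit(m, design=matrix(1, ncol(m), 1)));'
            f'write.table(data.frame(p=fit$p.value[,1]), "{out_path}", row.names=FALSE)'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"limma unavailable: {proc.stderr[:200]}")
        limma_p = pd.read_csv(out_path, sep=" ")["p"].to_numpy()
        long = pd.DataFrame({
            "peptide_key": np.repeat([f"P{i:03d}" for i in range(40)], 4),
            "replicate_id": np.tile([f"R{j}" for j in range(4)], 40),
            "normalized_log2_ratio": mat.ravel(),
        })
        res = moderated_t(long).sort_values("peptide_key")
        np.testing.assert_allclose(res["p_value"].to_numpy(), limma_p, rtol=1e-9)


class TestBH:
    def test_worked_example(self):
        q, passed = bh_fdr([0.01, 0.02, 0.03, 0.5], fdr=0.10)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert passed.tolist() == [True, True, True, False]

    def test_single_p(self):
        q, passed = bh_fdr([0.05], fdr=0.10)
        assert q[0] == pytest.approx(0.05) and passed[0]

    def test_all_ones_no_passes(self):
        q, passed = bh_fdr([1.0, 1.0, 1.0])
        assert not passed.any() and (q == 1.0).all()

    def test_validation(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    def test_equals_bruteforce_on_grid_subsets(self):
        """Step-up q-values match the definitional oracle exhaustively."""
        grid = [0.001, 0.01, 0.04, 0.11, 0.3, 1.0]
        for size in range(1, 5):
            for combo in itertools.combinations_with_replacement(grid, size):
                q, _ = bh_fdr(list(combo))
                np.testing.assert_allclose(q, bh_bruteforce(combo), rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_bruteforce_and_monotone(self, pvals):
        q, _ = bh_fdr(pvals)
        np.testing.assert_allclose(q, bh_bruteforce(pvals), rtol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-4, 1, 50)
        q1, _ = bh_fdr(p)
        perm = rng.permutation(50)
        q2, _ = bh_fdr(p[perm])
        np.testing.assert_allclose(q2, q1[perm])


class TestClassification:
    def test_direction_rules(self):
        res = pd.DataFrame({
            "peptide_key": ["A", "B", "C"],
            "n_replicates_quantified": 4,
            "mean_log2": [0.8, -0.8, 0.9],
            "p_value": [0.001, 0.001, 0.9],
        })
        out = classify(res, fdr=0.10).set_index("peptide_key")
        assert out.loc["A", "direction"] == "up"
        assert out.loc["B", "direction"] == "down"
        assert out.loc["C", "direction"] == "unchanged"

    def test_volcano_columns(self):
        res = classify(pd.DataFrame({
            "peptide_key": ["A"], "n_replicates_quantified": [4],
            "mean_log2": [0.5], "p_value": [0.01],
        }))
        v = volcano_table(res)
        assert v.loc[0, "neg_log10_p"] == pytest.approx(2.0)
        assert list(v.columns) == ["peptide_key", "mean_log2",
                                   "neg_log10_p", "direction"]

    def test_planted_effects_recovered_over_seeds(self):
        """At the design operating point the moderated test recovers >=80%
        of planted peptides with empirical FDR <= 0.15 (20 seeds)."""
        recalls, fdps = [], []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_proteins=60, n_phosphopeptides=300,
                n_nonphospho_peptides=100, seed=seed,
            )
            table, truth = simulate_dataset(cfg)
            norm, _ = normalize_replicates(compute_ratio(sum_by_peptide(table)))
            res = differential_analysis(norm, moderated=True)
            regulated = dict(zip(truth.peptides["peptide_key"],
                                 truth.peptides["regulated"]))
            called = res[res["direction"] != "unchanged"]
            tp = sum(regulated[k] for k in called["peptide_key"])
            n_true = sum(regulated[k] for k in res["peptide_key"])
            recalls.append(tp / n_true)
            fdps.append((len(called) - tp) / max(len(called), 1))
        assert np.mean(recalls) >= 0.80
        assert np.mean(fdps) <= 0.15
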