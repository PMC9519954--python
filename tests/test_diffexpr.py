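"""Differential-expression core: TMM, CPM/FPKM, dispersion, exact test, BH, QC."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gliastate as gs
from gliastate.diffexpr import _exact_pvalues


def frame(values, prefix="s"):
    values = np.asarray(values)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = frame(np.tile([[10], [20], [30], [40]], (1, 2)))
        norm = gs.tmm_factors(counts)
        np.testing.assert_allclose(norm.factors.to_numpy(), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(60, size=(3000, 1))
        counts = frame(np.hstack([base, 2 * base]))
        norm = gs.tmm_factors(counts)
        np.testing.assert_allclose(norm.factors.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_depth_scaling_invariance(self):
        # trimmed-mean log-ratios are depth-free; only the precision weights
        # feel absolute counts, so invariance is exact in M and tight overall
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, size=(2000, 4))
        f1 = gs.tmm_factors(frame(counts)).factors.to_numpy()
        scaled = counts.copy()
        scaled[:, 2] *= 3
        f2 = gs.tmm_factors(frame(scaled)).factors.to_numpy()
        np.testing.assert_allclose(f1, f2, rtol=5e-3)

    def test_outlier_gene_trimmed_out(self):
        # A=(10,10,10,10), B=(10,10,10,1000): the outlier is trimmed, the
        # remaining genes are identical, so effective libraries equalize.
        counts = frame([[10, 10], [10, 10], [10, 10], [10, 1000]])
        norm = gs.tmm_factors(counts)
        eff = norm.effective().to_numpy()
        assert eff[0] == pytest.approx(eff[1], rel=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.uniform(5, 300, size=(1500, 1)), size=(1500, 6))
        norm = gs.tmm_factors(frame(counts))
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = frame([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            gs.tmm_factors(counts)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_factors_match_edger_reference(self, tmp_path):
        rng = np.random.default_rng(42)
        mu = rng.uniform(5, 200, 500)
        libf = rng.uniform(0.7, 1.4, 6)
        counts = rng.poisson(rng.gamma(10.0, 0.1 * mu[:, None] * libf[None, :]))
        counts[:40, 3:] *= 4
        path = tmp_path / "counts.tsv"
        frame(counts).to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("{path}", header=TRUE, row.names=1))
            cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        ours = gs.tmm_factors(frame(counts)).factors.to_numpy()
        np.testing.assert_allclose(ours, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# CPM / FPKM
# ---------------------------------------------------------------------------


class TestExpressionSummaries:
    def test_cpm_toy_value(self):
        counts = frame([[100], [999900]])
        out = gs.cpm(counts)
        assert out.iloc[0, 0] == pytest.approx(100.0)

    def test_cpm_column_sums_identity(self):
        rng = np.random.default_rng(4)
        counts = frame(rng.poisson(40, size=(800, 3)))
        norm = gs.tmm_factors(counts)
        out = gs.cpm(counts, norm)
        expected = 1e6 / norm.factors.to_numpy()
        np.testing.assert_allclose(out.sum(axis=0).to_numpy(), expected, rtol=1e-12)

    def test_log_cpm_finite_at_zero(self):
        counts = frame([[0, 0], [10, 20]])
        out = gs.cpm(counts, log=True)
        assert np.all(np.isfinite(out.to_numpy()))

    def test_cpm_zero_preserving_and_nonnegative(self):
        counts = frame([[0, 5], [3, 0]])
        out = gs.cpm(counts)
        assert out.iloc[0, 0] == 0 and out.iloc[1, 1] == 0
        assert (out.to_numpy() >= 0).all()

    def test_fpkm_toy_value(self):
        # 10 reads, 2 kb transcript, 1e6 library -> FPKM 5
        counts = frame([[10], [999990]])
        lengths = pd.Series([2000.0, 1000.0], index=["g0", "g1"])
        out = gs.fpkm(counts, lengths)
        assert out.iloc[0, 0] == pytest.approx(5.0)

    def test_fpkm_depth_invariance_and_zeros(self):
        counts = frame([[10, 20], [90, 180], [0, 0]])
        lengths = pd.Series([500.0, 1500.0, 800.0], index=["g0", "g1", "g2"])
        out = gs.fpkm(counts, lengths)
        np.testing.assert_allclose(out.iloc[:, 0], out.iloc[:, 1], rtol=1e-12)
        assert (out.iloc[2] == 0).all()

    def test_fpkm_missing_length_rejected(self):
        counts = frame([[10], [20]])
        with pytest.raises(ValueError, match="missing gene lengths"):
            gs.fpkm(counts, pd.Series([100.0], index=["g0"]))


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


class TestCommonDispersion:
    def _simulate(self, phi, seed, n_genes=2000, reps=6):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 500, n_genes)
        libf = rng.uniform(0.85, 1.15, 2 * reps)
        mean = mu[:, None] * libf[None, :]
        if phi == 0:
            counts = rng.poisson(mean)
        else:
            counts = rng.poisson(rng.gamma(1 / phi, phi * mean))
        cond = pd.Series(["a"] * reps + ["b"] * reps, index=[f"s{j}" for j in range(2 * reps)])
        return gs.CountMatrix(frame(counts), cond)

    def test_poisson_data_gives_near_zero_phi(self):
        cm = self._simulate(0.0, seed=10)
        assert gs.estimate_common_dispersion(cm) <= 0.01

    def test_recovers_planted_dispersion(self):
        cm = self._simulate(0.2, seed=11)
        assert 0.15 <= gs.estimate_common_dispersion(cm) <= 0.25

    def test_unreplicated_design_rejected(self):
        counts = frame([[5, 7], [9, 11]])
        cond = pd.Series(["a", "b"], index=["s0", "s1"])
        with pytest.raises(ValueError, match="supply phi"):
            gs.estimate_common_dispersion(gs.CountMatrix(counts, cond))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def enumeration_oracle(s_ref, s_tgt, n_ref, n_tgt, phi, mu=10.0):
    """Independent brute-force conditional p-value via scipy pmf products."""
    s = s_ref + s_tgt
    a = np.arange(s + 1)
    if phi == 0:
        w = stats.binom.pmf(a, s, n_ref / (n_ref + n_tgt))
    else:
        r_ref, r_tgt = n_ref / phi, n_tgt / phi
        p_ref = (n_ref * mu) / (n_ref * mu + r_ref)
        p_tgt = (n_tgt * mu) / (n_tgt * mu + r_tgt)
        w = stats.nbinom.pmf(a, r_ref, 1 - p_ref) * stats.nbinom.pmf(s - a, r_tgt, 1 - p_tgt)
        w = w / w.sum()
    w_obs = w[s_ref]
    return min(1.0, w[w <= w_obs * (1 + 1e-9)].sum())


class TestExactTest:
    def test_symmetric_identical_sums_give_p_one(self):
        p = _exact_pvalues([25], [25], 3, 3, 0.1)
        assert p[0] == pytest.approx(1.0)

    def test_phi_zero_reduces_to_binomial(self):
        # totals 10 vs 0, equal libraries: p = 2 * (1/2)^10
        p = _exact_pvalues([10], [0], 2, 2, 0.0)
        assert p[0] == pytest.approx(2 * 0.5**10, abs=1e-15)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_for_small_totals(self, phi):
        pairs = [(a, s - a) for s in range(0, 31) for a in range(s + 1)]
        s_ref = np.array([p[0] for p in pairs])
        s_tgt = np.array([p[1] for p in pairs])
        ours = _exact_pvalues(s_ref, s_tgt, 3, 3, phi)
        expected = [enumeration_oracle(a, b, 3, 3, phi) for a, b in pairs]
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_unequal_group_sizes_match_enumeration(self):
        pairs = [(a, 20 - a) for a in range(21)]
        ours = _exact_pvalues([p[0] for p in pairs], [p[1] for p in pairs], 2, 5, 0.2)
        expected = [enumeration_oracle(a, b, 2, 5, 0.2) for a, b in pairs]
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_full_test_on_count_matrix(self, small_design):
        cm, truth = gs.generate_counts(small_design)
        table = gs.nb_exact_test(cm, norm=gs.tmm_factors(cm))
        assert list(table.columns) == ["logFC", "logCPM", "PValue", "FDR"]
        assert ((table["PValue"] >= 0) & (table["PValue"] <= 1)).all()
        # planted +2 panel should be overwhelmingly significant
        called = gs.call_degs(table, 0.01)
        planted = set(truth.index[truth["hi"].abs() > 0])
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9

    def test_more_than_two_groups_rejected(self):
        counts = frame(np.ones((5, 3), dtype=int))
        cond = pd.Series(["a", "b", "c"], index=counts.columns)
        with pytest.raises(ValueError, match="exactly 2"):
            gs.nb_exact_test(counts, cond, dispersion=0.1)

    def test_negative_dispersion_rejected(self, small_design):
        cm, _ = gs.generate_counts(small_design)
        with pytest.raises(ValueError, match="non-negative"):
            gs.nb_exact_test(cm, dispersion=-0.5)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_edger_smallp_on_equal_libraries(self, tmp_path):
        rng = np.random.default_rng(7)
        mu = rng.uniform(2, 150, 300)
        counts = rng.poisson(np.tile(mu[:, None], (1, 6)))
        counts[:30, 3:] = rng.poisson(np.tile(3 * mu[:30, None], (1, 3)))
        pad = counts.sum(axis=0).max() - counts.sum(axis=0)
        counts = np.vstack([counts, pad[None, :]])
        path = tmp_path / "counts.tsv"
        frame(counts).to_csv(path, sep="\t")
        script = tmp_path / "et.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.table("{path}", header=TRUE, row.names=1))
            d <- DGEList(counts=x, group=factor(rep(c("A","B"), each=3)))
            et <- exactTest(d, dispersion=0.1, rejection.region="smallp")
            cat(sprintf("%.15g", et$table$PValue), sep="\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        cond = pd.Series(["A"] * 3 + ["B"] * 3, index=[f"s{j}" for j in range(6)])
        ours = gs.nb_exact_test(frame(counts), cond, dispersion=0.1)["PValue"].to_numpy()
        np.testing.assert_allclose(ours, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# BH adjustment and DEG calls
# ---------------------------------------------------------------------------


def bh_brute_force(pvalues):
    """Literal step-up: FDR_i = min over j with p_(j) >= p_i of (m/j) p_(j)."""
    p = list(pvalues)
    m = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        candidates = [
            min(1.0, ranked[j] * m / (j + 1)) for j in range(m) if ranked[j] >= pi
        ]
        out.append(min(candidates))
    return np.array(out)


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        assert gs.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            gs.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_pvalues(self):
        np.testing.assert_allclose(gs.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(1, 200))
            np.testing.assert_allclose(gs.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_permutation_stability(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        direct = gs.bh_adjust(p)
        permuted = gs.bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(direct[perm], permuted, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            gs.bh_adjust([0.1, np.nan])
        with pytest.raises(ValueError):
            gs.bh_adjust([1.5])


class TestCallDegs:
    def test_empty_table(self):
        assert gs.call_degs(pd.DataFrame({"FDR": []})) == set()

    def test_strict_cutoff(self):
        table = pd.DataFrame({"FDR": [0.01, 0.009]}, index=["a", "b"])
        assert gs.call_degs(table, 0.01) == {"b"}

    def test_null_simulation_rarely_calls(self):
        design = gs.SyntheticDesign(
            n_genes=3000, conditions=[("a", 4), ("b", 4)],
            baseline_range=(2.0, 10.0), dispersion=0.2, seed=17,
        )
        cm, _ = gs.generate_counts(design)
        table = gs.nb_exact_test(cm, norm=gs.tmm_factors(cm))
        assert len(gs.call_degs(table, 0.01)) / len(table) <= 0.01


# ---------------------------------------------------------------------------
# Single-nuclei QC
# ---------------------------------------------------------------------------


class TestSnqcFilter:
    def _cells(self, values, genes):
        cols = [f"c{j}" for j in range(np.asarray(values).shape[1])]
        counts = pd.DataFrame(values, index=genes, columns=cols)
        return gs.CountMatrix(counts, pd.Series("x", index=cols))

    def test_fully_detected_matrix_unchanged(self):
        cm = self._cells(np.ones((4, 3), dtype=int), ["g1", "g2", "g3", "g4"])
        out = gs.snqc_filter(cm, min_cells_per_gene=2, min_genes_per_cell=2)
        assert out.counts.shape == (4, 3)

    def test_toy_hand_enumeration(self):
        # g3 detected in 1 cell -> dropped; cell c2 then has 1 gene -> dropped
        cm = self._cells([[1, 1, 1], [1, 1, 0], [1, 0, 0]], ["g1", "g2", "g3"])
        out = gs.snqc_filter(cm, min_cells_per_gene=2, min_genes_per_cell=2)
        assert list(out.genes) == ["g1", "g2"]
        assert list(out.samples) == ["c0", "c1"]

    def test_mitochondrial_genes_removed_first(self):
        cm = self._cells([[5, 5], [3, 3]], ["mt-Co1", "Gfap"])
        out = gs.snqc_filter(cm, min_cells_per_gene=1, min_genes_per_cell=1)
        assert list(out.genes) == ["Gfap"]

    def test_threshold_straddling_construction(self):
        # block A genes detected in 20 cells (pass min_cells 10); block B in
        # only 5 (dropped); the 10 cells carrying no block-A gene then fall
        # below min_genes 20 and are dropped
        n_a, n_b, n_cells = 30, 10, 30
        block_a = np.ones((n_a, n_cells), dtype=int)
        block_a[:, 20:] = 0
        block_b = np.zeros((n_b, n_cells), dtype=int)
        block_b[:, :5] = 1
        values = np.vstack([block_a, block_b])
        genes = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        cm = self._cells(values, genes)
        out = gs.snqc_filter(cm, min_cells_per_gene=10, min_genes_per_cell=20)
        assert out.counts.shape == (n_a, 20)
        assert set(out.genes) == {f"a{i}" for i in range(n_a)}

    def test_all_cells_filtered_raises(self):
        cm = self._cells([[1, 1]], ["g1"])
        with pytest.raises(ValueError, match="all cells"):
            gs.snqc_filter(cm, min_cells_per_gene=1, min_genes_per_cell=5)

    def test_filter_logs_before_and_after_counts(self, caplog):
        cm = self._cells([[1, 1, 1], [1, 1, 0], [1, 0, 0]], ["g1", "g2", "g3"])
        with caplog.at_level("INFO", logger="gliastate.diffexpr"):
            gs.snqc_filter(cm, min_cells_per_gene=2, min_genes_per_cell=2)
        joined = " ".join(rec.getMessage() for rec in caplog.records)
        assert "3" in joined and "2" in joined


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class TestEstimators:
    def test_nb_exact_test_estimator(self, small_design):
        cm, _ = gs.generate_counts(small_design)
        est = gs.NBExactTest(dispersion=0.05).fit(cm.counts.T, cm.conditions.to_numpy())
        assert est.dispersion_ == 0.05
        table = gs.nb_exact_test(cm, norm=gs.tmm_factors(cm), dispersion=0.05)
        np.testing.assert_allclose(
            est.deg_table_["PValue"].to_numpy(), table["PValue"].to_numpy()
        )
        assert est.degs_ == gs.call_degs(table, 0.01)

    def test_tmm_normalizer_round_trip(self):
        rng = np.random.default_rng(5)
        counts = frame(rng.poisson(60, size=(500, 4)))
        normalizer = gs.TMMNormalizer()
        out = normalizer.fit_transform(counts.T)
        expected = gs.cpm(counts, gs.tmm_factors(counts))
        np.testing.assert_allclose(out.T.to_numpy(), expected.to_numpy())

    def test_single_nuclei_qc_transformer(self):
        counts = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [1, 0, 0]],
            index=["g1", "g2", "g3"],
            columns=["c0", "c1", "c2"],
        )
        qc = gs.SingleNucleiQC(min_cells_per_gene=2, min_genes_per_cell=2)
        out = qc.fit_transform(counts.T)
        assert list(out.columns) == ["g1", "g2"]
        assert list(out.index) == ["c0", "c1"]
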