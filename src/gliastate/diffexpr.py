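"""Two-condition differential-expression core for RNA-seq count data.

Implements the classic exact-test route for negative-binomial counts:

* TMM (trimmed mean of M-values) between-sample normalization factors,
  with 30% two-sided trimming on M, 5% on A, and inverse-asymptotic-variance
  precision weights;
* CPM and FPKM expression summaries;
* common-dispersion estimation by maximizing the conditional negative-binomial
  log-likelihood on quantile-equalized pseudo-counts;
* a two-sided exact test conditional on per-gene totals, where the two-sided
  p-value sums the probabilities of all outcomes at most as probable as the
  observed one;
* Benjamini-Hochberg step-up FDR adjustment and strict FDR < cutoff DEG calls;
* the single-nuclei QC filter (mitochondrial genes out, then low-detection
  genes, then low-complexity cells).

Counts follow the NB parameterization ``var = mu + phi * mu**2`` with a single
dispersion ``phi`` shared across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import DEG_COLUMNS, CountMatrix

logger = logging.getLogger(__name__)

_POISSON_PHI = 1e-12  # below this, treat the NB as Poisson


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_sizes: pd.Series
    factors: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.factors.to_numpy() <= 0):
            raise ValueError("TMM factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors.to_numpy())))
        if abs(gm - 1.0) > 1e-8:
            raise ValueError(f"TMM factors have geometric mean {gm}, expected 1")

    def effective(self) -> pd.Series:
        """Effective library sizes (library size x factor)."""
        return self.library_sizes * self.factors


def _counts_array(counts) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(counts, CountMatrix):
        frame = counts.counts
    else:
        frame = counts
    return frame.to_numpy(dtype=float), frame.index, frame.columns


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample.

    Genes with a zero in either sample drop out (their log-ratio is not
    finite); the weighted trimmed mean of the remaining M values is the log2
    factor.  Weights are the inverse asymptotic (delta-method) variance of M.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2((obs / lib_obs) / (ref / lib_ref))
        abs_expr = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        asym_var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(log_ratio) & np.isfinite(abs_expr)
    log_ratio, abs_expr, asym_var = log_ratio[finite], abs_expr[finite], asym_var[finite]
    if log_ratio.size == 0 or np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = log_ratio.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_ratio)
    rank_a = rankdata(abs_expr)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(log_ratio[keep] / asym_var[keep]) / np.sum(1.0 / asym_var[keep])
    return float(2.0**f)


def tmm_factors(counts, reference_sample=None) -> NormFactors:
    """TMM normalization factors for every sample of a count matrix.

    The reference sample defaults to the one whose upper-quartile expression
    (counts scaled by library size) is closest to the mean upper quartile.
    Factors are rescaled so their geometric mean is 1.

    Raises
    ------
    ValueError
        If fewer than two samples are given or a sample has all-zero counts.
    """
    values, _, sample_ids = _counts_array(counts)
    if values.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    libs = values.sum(axis=0)
    if np.any(libs <= 0):
        bad = sample_ids[np.where(libs <= 0)[0][0]]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    if reference_sample is None:
        f75 = np.quantile(values / libs, 0.75, axis=0)
        if np.median(f75) < 1e-20:
            ref_idx = int(np.argmax(libs))
        else:
            ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(sample_ids.get_loc(reference_sample))
    raw = np.array(
        [
            _tmm_pair(values[:, k], values[:, ref_idx], libs[k], libs[ref_idx])
            for k in range(values.shape[1])
        ]
    )
    raw /= np.exp(np.mean(np.log(raw)))
    return NormFactors(
        library_sizes=pd.Series(libs, index=sample_ids),
        factors=pd.Series(raw, index=sample_ids),
    )


# ---------------------------------------------------------------------------
# Expression summaries
# ---------------------------------------------------------------------------


def cpm(counts, norm: NormFactors | None = None, log: bool = False, prior_count: float = 0.5):
    """Counts per million over effective library sizes.

    In the log2 variant the prior count is scaled by each sample's effective
    library size relative to the mean, so that a gene with zero counts maps to
    the same log-CPM in every sample.
    """
    values, gene_ids, sample_ids = _counts_array(counts)
    if norm is None:
        eff = values.sum(axis=0)
    else:
        eff = norm.effective().loc[sample_ids].to_numpy()
    if not log:
        out = values / eff[None, :] * 1e6
    else:
        scaled_prior = prior_count * eff / eff.mean()
        out = np.log2((values + scaled_prior[None, :]) / ((eff + 2 * scaled_prior)[None, :]) * 1e6)
    return pd.DataFrame(out, index=gene_ids, columns=sample_ids)


def fpkm(counts, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    Library size is the raw column sum (no TMM), matching direct calculation
    from a count table: ``count / (length_kb * lib_millions)``.

    Raises
    ------
    ValueError
        If any gene has no length or a non-positive length.
    """
    values, gene_ids, sample_ids = _counts_array(counts)
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing[:5])}")
    lens = lengths.loc[gene_ids].to_numpy()
    if np.any(lens <= 0):
        raise ValueError("gene lengths must be positive")
    libs = values.sum(axis=0)
    out = values / (lens[:, None] / 1e3) / (libs[None, :] / 1e6)
    return pd.DataFrame(out, index=gene_ids, columns=sample_ids)


# ---------------------------------------------------------------------------
# Quantile equalization of library sizes (pseudo-counts)
# ---------------------------------------------------------------------------


def _q2qnbinom(x, input_mean, output_mean, dispersion):
    """Quantile-to-quantile NB count mapping between two mean levels.

    Maps a count observed at ``input_mean`` to the equivalent quantile of an
    NB with ``output_mean`` (same dispersion), averaging normal and gamma
    tail approximations; the tail is chosen for numerical accuracy.
    """
    eps = 1e-14
    zero = (input_mean < eps) | (output_mean < eps)
    input_mean = np.where(zero, input_mean + 0.25, input_mean)
    output_mean = np.where(zero, output_mean + 0.25, output_mean)
    r_in = 1 + dispersion * input_mean
    r_out = 1 + dispersion * output_mean
    sd_in = np.sqrt(input_mean * r_in)
    sd_out = np.sqrt(output_mean * r_out)
    p = norm_dist.sf(x, loc=input_mean, scale=sd_in)
    q_norm_up = norm_dist.isf(p, loc=output_mean, scale=sd_out)
    p = gamma_dist.sf(x, a=input_mean / r_in, scale=r_in)
    q_gamma_up = gamma_dist.isf(p, a=output_mean / r_out, scale=r_out)
    p = norm_dist.cdf(x, loc=input_mean, scale=sd_in)
    q_norm_lo = norm_dist.ppf(p, loc=output_mean, scale=sd_out)
    p = gamma_dist.cdf(x, a=input_mean / r_in, scale=r_in)
    q_gamma_lo = gamma_dist.ppf(p, a=output_mean / r_out, scale=r_out)
    upper = (q_norm_up + q_gamma_up) / 2.0
    lower = (q_norm_lo + q_gamma_lo) / 2.0
    return np.maximum(np.where(x >= input_mean, upper, lower), 0.0)


def _pseudo_counts(values, libs, group_codes, dispersion, groupwise):
    """Equalize effective library sizes to their geometric mean.

    ``groupwise=True`` estimates per-gene mean proportions within each group
    (used for dispersion estimation, where groups may differ in expression);
    ``groupwise=False`` uses a single null proportion across all samples
    (used by the exact test, which conditions on the null).
    """
    common = float(np.exp(np.mean(np.log(libs))))
    pseudo = np.empty_like(values, dtype=float)
    if groupwise:
        for g in np.unique(group_codes):
            sel = group_codes == g
            lam = values[:, sel].sum(axis=1) / libs[sel].sum()
            in_mean = lam[:, None] * libs[None, sel]
            out_mean = np.broadcast_to((lam * common)[:, None], in_mean.shape)
            pseudo[:, sel] = _q2qnbinom(values[:, sel], in_mean, out_mean, dispersion)
    else:
        lam = values.sum(axis=1) / libs.sum()
        in_mean = lam[:, None] * libs[None, :]
        out_mean = np.broadcast_to((lam * common)[:, None], in_mean.shape)
        pseudo = _q2qnbinom(values, in_mean, out_mean, dispersion)
    return pseudo, common


# ---------------------------------------------------------------------------
# Common dispersion
# ---------------------------------------------------------------------------


def _conditional_log_lik(phi, pseudo, group_codes):
    """NB conditional log-likelihood of phi given per-group totals, summed over genes."""
    inv = 1.0 / phi
    total = 0.0
    n_genes = pseudo.shape[0]
    for g in np.unique(group_codes):
        sel = group_codes == g
        n = int(sel.sum())
        if n < 2:
            continue  # singleton groups carry no information on dispersion
        y = pseudo[:, sel]
        z = y.sum(axis=1)
        total += (
            np.sum(gammaln(y + inv))
            + n_genes * gammaln(n * inv)
            - np.sum(gammaln(z + n * inv))
            - n_genes * n * gammaln(inv)
        )
    return total


def estimate_common_dispersion(counts, conditions=None) -> float:
    """Single NB dispersion phi shared across genes, by conditional maximum likelihood.

    Library sizes are quantile-equalized to their geometric mean and the
    conditional log-likelihood given per-group pseudo-count totals is
    maximized over ``delta = phi / (1 + phi)``; the equalization/optimization
    pair is iterated twice.  The estimate is clipped to ``[0, 10]``.

    Raises
    ------
    ValueError
        If no condition has at least two replicates (supply phi explicitly).
    """
    if isinstance(counts, CountMatrix):
        values = counts.counts.to_numpy(dtype=float)
        cond = counts.conditions if conditions is None else pd.Series(conditions)
    else:
        values = np.asarray(counts, dtype=float)
        cond = pd.Series(conditions)
    labels, group_codes = np.unique(cond.to_numpy(), return_inverse=True)
    if max(np.bincount(group_codes)) < 2:
        raise ValueError(
            "no condition has >= 2 replicates; dispersion cannot be estimated "
            "-- supply phi explicitly"
        )
    libs = values.sum(axis=0)
    values = values[values.sum(axis=1) > 0]
    disp = 0.01
    for _ in range(2):
        pseudo, _ = _pseudo_counts(values, libs, group_codes, disp, groupwise=True)
        res = minimize_scalar(
            lambda d: -_conditional_log_lik(d / (1 - d), pseudo, group_codes),
            bounds=(1e-4, 100.0 / 101.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        disp = res.x / (1 - res.x)
    return float(np.clip(disp, 0.0, 10.0))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _exact_pvalues(s_ref, s_tgt, n_ref, n_tgt, phi):
    """Two-sided conditional exact p-values for per-gene group sums.

    The sum of ``n`` i.i.d. NB(mu, phi) counts is NB with size ``n / phi``;
    conditional on the total ``s``, the null distribution over the reference
    group's sum ``a`` has weights ``Gamma(a + r_ref) / Gamma(a + 1) *
    Gamma(s - a + r_tgt) / Gamma(s - a + 1)`` (the success probability
    cancels).  The two-sided p-value sums the probabilities of all outcomes
    whose probability is at most the observed one (relative tie tolerance
    1e-9), capped at 1.  ``phi = 0`` reduces to the conditional binomial.
    """
    s_ref = np.asarray(s_ref, dtype=np.int64)
    s_tgt = np.asarray(s_tgt, dtype=np.int64)
    totals = s_ref + s_tgt
    max_total = int(totals.max(initial=0))
    a = np.arange(max_total + 1, dtype=float)
    if phi > _POISSON_PHI:
        r_ref = n_ref / phi
        r_tgt = n_tgt / phi
        table_ref = gammaln(a + r_ref) - gammaln(a + 1)
        table_tgt = gammaln(a + r_tgt) - gammaln(a + 1)
    else:
        table_ref = -gammaln(a + 1) + a * np.log(n_ref / (n_ref + n_tgt))
        table_tgt = -gammaln(a + 1) + a * np.log(n_tgt / (n_ref + n_tgt))
    pvals = np.ones(s_ref.size)
    for i in range(s_ref.size):
        s = int(totals[i])
        if s == 0:
            continue
        log_w = table_ref[: s + 1] + table_tgt[s::-1]
        log_w = log_w - logsumexp(log_w)
        w = np.exp(log_w)
        w_obs = w[int(s_ref[i])]
        pvals[i] = min(1.0, float(w[w <= w_obs * (1 + 1e-9)].sum()))
    return pvals


def nb_exact_test(
    counts,
    conditions=None,
    norm: NormFactors | None = None,
    dispersion: float | None = None,
    reference: str | None = None,
    prior_count: float = 0.5,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Two-condition NB exact test; returns a DEG table (M, A, p, FDR).

    With ``compute_pvalues=False`` the exact test is skipped and PValue/FDR
    are filled with 1, for callers that only need the M-A values (e.g.
    significance-free state-change geometry).

    Library sizes (optionally TMM-adjusted via ``norm``) are quantile-equalized
    to a common size; per-gene group sums of the rounded pseudo-counts are then
    tested conditionally on their total.  ``M = log2`` fold-change of the
    non-reference (target) condition versus ``reference`` computed from
    normalized condition means with a prior count of ``prior_count`` per
    group; ``A`` is the average log2 CPM.  FDR is Benjamini-Hochberg.

    Raises
    ------
    ValueError
        If the design does not have exactly two condition labels, or
        ``dispersion`` is negative.
    """
    if isinstance(counts, CountMatrix):
        frame = counts.counts
        cond = counts.conditions if conditions is None else pd.Series(conditions)
    else:
        frame = counts
        cond = pd.Series(conditions)
    cond = cond.loc[frame.columns]
    labels = list(pd.unique(cond.to_numpy()))
    if len(labels) != 2:
        raise ValueError(f"exact test needs exactly 2 conditions, got {labels}")
    if reference is None:
        reference = labels[0]
    elif reference not in labels:
        raise ValueError(f"reference {reference!r} not among conditions {labels}")
    target = next(lab for lab in labels if lab != reference)
    if dispersion is None:
        dispersion = estimate_common_dispersion(frame.to_numpy(), cond)
        logger.info("estimated common dispersion phi=%.4g", dispersion)
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")

    values = frame.to_numpy(dtype=float)
    if norm is None:
        norm = NormFactors(
            library_sizes=pd.Series(values.sum(axis=0), index=frame.columns),
            factors=pd.Series(1.0, index=frame.columns),
        )
    eff = norm.effective().loc[frame.columns].to_numpy()
    is_ref = (cond == reference).to_numpy()
    n_ref = int(is_ref.sum())
    n_tgt = int((~is_ref).sum())

    pseudo, common_lib = _pseudo_counts(
        values, eff, np.zeros(values.shape[1], dtype=int), dispersion, groupwise=False
    )
    if compute_pvalues:
        sum_ref = np.rint(pseudo[:, is_ref].sum(axis=1)).astype(np.int64)
        sum_tgt = np.rint(pseudo[:, ~is_ref].sum(axis=1)).astype(np.int64)
        pvals = _exact_pvalues(sum_ref, sum_tgt, n_ref, n_tgt, dispersion)
    else:
        pvals = np.ones(values.shape[0])

    # M and A from equalized condition means with a prior count per group
    mean_ref = pseudo[:, is_ref].mean(axis=1)
    mean_tgt = pseudo[:, ~is_ref].mean(axis=1)
    m = np.log2((mean_tgt + prior_count) / (mean_ref + prior_count))
    cpm_ref = (mean_ref + prior_count) / common_lib * 1e6
    cpm_tgt = (mean_tgt + prior_count) / common_lib * 1e6
    a = 0.5 * (np.log2(cpm_ref) + np.log2(cpm_tgt))

    table = pd.DataFrame(
        {"logFC": m, "logCPM": a, "PValue": pvals, "FDR": bh_adjust(pvals)},
        index=frame.index,
    )
    table.attrs["reference"] = reference
    table.attrs["target"] = target
    table.attrs["dispersion"] = float(dispersion)
    return table[list(DEG_COLUMNS)]


# ---------------------------------------------------------------------------
# Multiple testing and DEG calls
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_degs(deg_table: pd.DataFrame, fdr_cutoff: float = 0.01) -> set:
    """Genes with FDR strictly below the cutoff."""
    if deg_table.empty:
        return set()
    if "FDR" not in deg_table.columns:
        raise ValueError("DEG table has no FDR column")
    called = set(deg_table.index[deg_table["FDR"] < fdr_cutoff])
    logger.info("called %d DEGs at FDR < %g (of %d genes)", len(called), fdr_cutoff, len(deg_table))
    return called


# ---------------------------------------------------------------------------
# Single-nuclei QC
# ---------------------------------------------------------------------------


def snqc_filter(
    matrix: CountMatrix,
    min_cells_per_gene: int = 200,
    min_genes_per_cell: int = 333,
    drop_mito: bool = True,
    mito_prefix: str = "mt-",
) -> CountMatrix:
    """Single-nuclei QC: drop mitochondrial genes, sparse genes, then shallow cells.

    Cells are the samples of ``matrix``.  In one pass and in this order:
    (1) genes whose symbol starts with ``mito_prefix`` (case-insensitive) are
    removed; (2) genes detected (count > 0) in fewer than
    ``min_cells_per_gene`` cells are removed; (3) cells with fewer than
    ``min_genes_per_cell`` detected genes (after gene filtering) are removed.

    Raises
    ------
    ValueError
        If every cell is filtered out.
    """
    frame = matrix.counts
    n_genes0, n_cells0 = frame.shape
    if drop_mito:
        is_mito = frame.index.astype(str).str.casefold().str.startswith(mito_prefix.casefold())
        frame = frame.loc[~is_mito]
        logger.info("snqc: removed %d mitochondrial genes", int(is_mito.sum()))
    detected_cells = (frame.to_numpy() > 0).sum(axis=1)
    frame = frame.loc[detected_cells >= min_cells_per_gene]
    detected_genes = (frame.to_numpy() > 0).sum(axis=0)
    frame = frame.loc[:, detected_genes >= min_genes_per_cell]
    logger.info(
        "snqc: %d genes x %d cells -> %d genes x %d cells",
        n_genes0, n_cells0, frame.shape[0], frame.shape[1],
    )
    if frame.shape[1] == 0:
        raise ValueError("all cells removed by QC filter")
    return CountMatrix(frame, matrix.conditions.loc[frame.columns])


# ---------------------------------------------------------------------------
# Estimator wrappers
# ---------------------------------------------------------------------------


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Transformer computing TMM factors and returning (log-)CPM.

    Follows the scikit-learn convention of samples as rows, so ``X`` is a
    samples x genes DataFrame or array (transposed relative to the
    genes x samples convention of the functional API).
    """

    def __init__(self, log: bool = False, prior_count: float = 0.5, reference_sample=None):
        self.log = log
        self.prior_count = prior_count
        self.reference_sample = reference_sample

    def fit(self, X, y=None):
        frame = pd.DataFrame(X).T
        self.norm_factors_ = tmm_factors(frame, reference_sample=self.reference_sample)
        return self

    def transform(self, X):
        frame = pd.DataFrame(X).T
        out = cpm(frame, self.norm_factors_, log=self.log, prior_count=self.prior_count)
        return out.T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


class NBExactTest(BaseEstimator):
    """Estimator form of the NB exact test.

    ``fit(X, y)`` takes a samples x genes matrix and a condition label per
    sample (exactly two labels) and exposes the DEG table and DEG calls as
    fitted attributes.
    """

    def __init__(
        self,
        fdr_cutoff: float = 0.01,
        dispersion: float | None = None,
        reference: str | None = None,
        use_tmm: bool = True,
    ):
        self.fdr_cutoff = fdr_cutoff
        self.dispersion = dispersion
        self.reference = reference
        self.use_tmm = use_tmm

    def fit(self, X, y):
        frame = pd.DataFrame(X).T
        cond = pd.Series(np.asarray(y), index=frame.columns)
        norm = tmm_factors(frame) if self.use_tmm else None
        self.norm_factors_ = norm
        self.deg_table_ = nb_exact_test(
            frame, cond, norm=norm, dispersion=self.dispersion, reference=self.reference
        )
        self.dispersion_ = self.deg_table_.attrs["dispersion"]
        self.degs_ = call_degs(self.deg_table_, self.fdr_cutoff)
        return self


class SingleNucleiQC(BaseEstimator, TransformerMixin):
    """Transformer form of the single-nuclei QC filter (cells as rows)."""

    def __init__(
        self,
        min_cells_per_gene: int = 200,
        min_genes_per_cell: int = 333,
        drop_mito: bool = True,
        mito_prefix: str = "mt-",
    ):
        self.min_cells_per_gene = min_cells_per_gene
        self.min_genes_per_cell = min_genes_per_cell
        self.drop_mito = drop_mito
        self.mito_prefix = mito_prefix

    def fit(self, X, y=None):
        frame = pd.DataFrame(X)
        cm = CountMatrix(frame.T, pd.Series("cell", index=frame.index))
        filtered = snqc_filter(
            cm,
            min_cells_per_gene=self.min_cells_per_gene,
            min_genes_per_cell=self.min_genes_per_cell,
            drop_mito=self.drop_mito,
            mito_prefix=self.mito_prefix,
        )
        self.kept_genes_ = filtered.genes
        self.kept_cells_ = filtered.samples
        return self

    def transform(self, X):
        frame = pd.DataFrame(X)
        return frame.loc[self.kept_cells_, self.kept_genes_]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
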