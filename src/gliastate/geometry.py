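"""Geometry of transcriptional state changes.

A state change is the vector of per-gene log2 fold-changes (M) for one
transition (reference condition -> target condition).  Two state changes --
for instance a neural progenitor graft before/after transplantation and host
astrocytes before/after injury -- are compared by the cosine of the angle
between them (restricted to a curated gene panel) and by Euclidean distances
in PCA space.  Additional summaries: median panel DEG, top-k most variable
DEGs across conditions, congruent/divergent per-gene classification, Pearson
correlation of DEG sets, and cluster-composition tables for single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA as _SKPCA

from .containers import GenePanel, StateChangeVector, validate_deg_table
from .diffexpr import fpkm


def state_change(
    deg_table: pd.DataFrame,
    reference: str | None = None,
    target: str | None = None,
    fdr_mask: float | None = None,
    source: str = "bulk",
) -> StateChangeVector:
    """Build a state-change vector (ordered per-gene M) from a DEG table.

    With ``fdr_mask`` set, only genes with FDR strictly below the mask are
    retained (consistent with DEG calling).  Genes are ordered by gene ID.
    """
    validate_deg_table(deg_table, require=("logFC",))
    table = deg_table
    if fdr_mask is not None:
        table = table[table["FDR"] < fdr_mask]
    values = table["logFC"].sort_index()
    return StateChangeVector(
        values=values,
        reference=reference or deg_table.attrs.get("reference", "reference"),
        target=target or deg_table.attrs.get("target", "target"),
        source=source,
    )


def state_change_fpkm(
    counts, gene_lengths, reference: str, target: str, prior: float = 1.0
) -> StateChangeVector:
    """State-change vector on the FPKM scale: log2 of mean-FPKM ratios.

    Alternative to the log-FC space when comparisons should be made on
    expression-level (FPKM) profiles; ``prior`` keeps the ratio finite at
    zero expression.
    """
    expr = fpkm(counts.counts, gene_lengths)
    cond = counts.conditions
    mean_ref = expr.loc[:, cond[cond == reference].index].mean(axis=1)
    mean_tgt = expr.loc[:, cond[cond == target].index].mean(axis=1)
    values = np.log2((mean_tgt + prior) / (mean_ref + prior)).sort_index()
    return StateChangeVector(values=values, reference=reference, target=target, source="fpkm")


def restrict_to_panel(vector: StateChangeVector, panel: GenePanel) -> StateChangeVector:
    """Subvector over the panel's genes, in panel order.

    Raises
    ------
    ValueError
        If the panel and the vector share no genes.
    """
    available = {str(g).casefold(): g for g in vector.genes}
    kept = [available[g] for g in panel.genes if g in available]
    if not kept:
        raise ValueError(f"panel {panel.name!r} shares no genes with the vector")
    return StateChangeVector(
        values=vector.values.loc[kept],
        reference=vector.reference,
        target=vector.target,
        source=vector.source,
    )


def median_panel_deg(vector: StateChangeVector, panel: GenePanel) -> float:
    """Median of the panel-restricted M values (violin-plot summary)."""
    return float(np.median(restrict_to_panel(vector, panel).to_numpy()))


def top_variable_degs(vectors, k: int = 2000) -> list:
    """The k genes with the largest variance of M across condition vectors.

    All vectors must cover the same gene set (intersect first otherwise).
    Variance is the population variance across vectors; ties break by gene
    ID; k is capped at the number of genes.

    Raises
    ------
    ValueError
        With fewer than two vectors or mismatched gene sets.
    """
    vectors = list(vectors)
    if len(vectors) < 2:
        raise ValueError("need at least two state-change vectors")
    genes = set(vectors[0].genes)
    for v in vectors[1:]:
        if set(v.genes) != genes:
            raise ValueError("vectors cover different gene sets; intersect first")
    frame = pd.concat([v.values.sort_index() for v in vectors], axis=1)
    var = frame.var(axis=1, ddof=0)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return [str(g) for g in order[: min(k, len(order))]]


def _align(v1: StateChangeVector, v2: StateChangeVector) -> tuple[np.ndarray, np.ndarray]:
    shared = v1.genes.intersection(v2.genes).sort_values()
    if len(shared) == 0:
        raise ValueError("vectors share no genes")
    return v1.values.loc[shared].to_numpy(), v2.values.loc[shared].to_numpy()


def cosine_similarity(v1: StateChangeVector, v2: StateChangeVector) -> float:
    """Cosine of the angle between two state-change vectors.

    Vectors are aligned on their shared genes (sorted by ID) first.  The raw
    signed value in [-1, 1] is returned: 1 = parallel state changes, 0 =
    orthogonal, -1 = opposite.

    Raises
    ------
    ValueError
        If either aligned vector has zero norm.
    """
    a, b = _align(v1, v2)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def pearson_correlation(v1: StateChangeVector, v2: StateChangeVector) -> float:
    """Sample Pearson correlation of the shared genes' M values.

    Raises
    ------
    ValueError
        With fewer than three shared genes or a zero-variance vector.
    """
    a, b = _align(v1, v2)
    if a.size < 3:
        raise ValueError("Pearson correlation needs at least 3 shared genes")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def congruence_classify(
    v_npc: StateChangeVector, v_host: StateChangeVector, min_abs_m: float = 1.0
) -> pd.Series:
    """Per-gene congruence labels over the shared genes.

    ``congruent-up`` if both M exceed ``min_abs_m``; ``congruent-down`` if
    both fall below ``-min_abs_m``; ``divergent`` if the signs differ and both
    magnitudes exceed the threshold; ``null`` otherwise.
    """
    shared = v_npc.genes.intersection(v_host.genes).sort_values()
    a = v_npc.values.loc[shared].to_numpy()
    b = v_host.values.loc[shared].to_numpy()
    labels = np.full(len(shared), "null", dtype=object)
    labels[(a > min_abs_m) & (b > min_abs_m)] = "congruent-up"
    labels[(a < -min_abs_m) & (b < -min_abs_m)] = "congruent-down"
    divergent = (np.sign(a) != np.sign(b)) & (np.abs(a) > min_abs_m) & (np.abs(b) > min_abs_m)
    labels[divergent] = "divergent"
    return pd.Series(labels, index=shared)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Column-centered SVD decomposition of a samples x features matrix."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # components x features
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a samples x features matrix via column-centered SVD.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the decomposition deterministic.

    Raises
    ------
    ValueError
        With fewer than two samples or non-finite features.
    """
    matrix = pd.DataFrame(matrix)
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("PCA input must be finite")
    n_components = min(n_components, min(values.shape[0] - 1, values.shape[1]))
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values)
    loadings = model.components_
    flip = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=matrix.columns),
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=pd.Series(model.mean_, index=matrix.columns),
    )


def pca_distance(result: PCAResult, sample_a, sample_b) -> float:
    """Euclidean distance between two samples in the retained PCA space.

    ``sample_b`` plays the role of the initial point of the displacement,
    though the distance itself is symmetric.

    Raises
    ------
    ValueError
        If either sample is not in the score table.
    """
    for s in (sample_a, sample_b):
        if s not in result.scores.index:
            raise ValueError(f"unknown sample {s!r}")
    diff = result.scores.loc[sample_a].to_numpy() - result.scores.loc[sample_b].to_numpy()
    return float(np.linalg.norm(diff))


class StatePCA(BaseEstimator):
    """Estimator form of the deterministic-sign PCA.

    ``fit(X)`` on a samples x features DataFrame exposes ``result_`` plus the
    usual fitted attributes; ``transform`` projects new data onto the
    components.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.result_ = pca(pd.DataFrame(X), n_components=self.n_components)
        self.components_ = self.result_.loadings.to_numpy()
        self.explained_variance_ratio_ = self.result_.explained_variance_ratio
        self.mean_ = self.result_.mean.to_numpy()
        return self

    def transform(self, X):
        values = pd.DataFrame(X).to_numpy(dtype=float)
        return (values - self.mean_[None, :]) @ self.components_.T

    def distance(self, sample_a, sample_b) -> float:
        return pca_distance(self.result_, sample_a, sample_b)


# ---------------------------------------------------------------------------
# Similarity report and cluster composition
# ---------------------------------------------------------------------------


@dataclass
class SimilarityReport:
    """Cosine/PCA comparison of two state changes on one gene universe."""

    panel: str
    n_genes: int
    cosine: float
    pca_dist: float | None = None
    genes: tuple = ()

    def to_dict(self) -> dict:
        return {
            "panel": self.panel,
            "n_genes": self.n_genes,
            "cosine_similarity": self.cosine,
            "pca_distance": self.pca_dist,
        }


def compare_state_changes(
    v1: StateChangeVector,
    v2: StateChangeVector,
    panel: GenePanel | None = None,
    n_components: int = 2,
) -> SimilarityReport:
    """Full comparison of two state changes, optionally panel-restricted.

    Reports the cosine similarity on the shared genes and the Euclidean
    distance between the two state vectors in a PCA space spanned by them.
    """
    if panel is not None:
        v1 = restrict_to_panel(v1, panel)
        v2 = restrict_to_panel(v2, panel)
        label = panel.name
    else:
        label = "all genes"
    shared = v1.genes.intersection(v2.genes).sort_values()
    cs = cosine_similarity(v1, v2)
    dist = None
    if len(shared) >= 2:
        mat = pd.DataFrame(
            [v1.values.loc[shared].to_numpy(), v2.values.loc[shared].to_numpy()],
            index=["state_1", "state_2"],
            columns=shared,
        )
        res = pca(mat, n_components=min(n_components, 1 if len(mat) == 2 else n_components))
        dist = pca_distance(res, "state_1", "state_2")
    return SimilarityReport(
        panel=label, n_genes=len(shared), cosine=cs, pca_dist=dist, genes=tuple(shared)
    )


@dataclass
class ClusterComposition:
    """Cell counts and within-cluster percentages per condition."""

    counts: pd.DataFrame  # clusters x conditions
    percentages: pd.DataFrame  # rows sum to 100


def cluster_composition(cluster_labels, condition_labels) -> ClusterComposition:
    """Tabulate, per cluster, how many cells come from each condition.

    Raises
    ------
    ValueError
        If the label vectors differ in length.
    """
    clusters = pd.Series(list(cluster_labels))
    conditions = pd.Series(list(condition_labels))
    if len(clusters) != len(conditions):
        raise ValueError("cluster and condition label vectors differ in length")
    counts = pd.crosstab(clusters, conditions)
    counts.index.name = "cluster"
    counts.columns.name = "condition"
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ClusterComposition(counts=counts, percentages=percentages)
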