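"""Gene-panel curation by multi-dataset vote thresholding.

A panel (e.g. healthy astrocyte, reactivity, EMT) is curated from several
per-dataset enriched-gene lists by keeping genes that appear in at least
``min_votes`` of the lists -- the rule used for astrocyte-state signatures
(5-of-8 for the healthy panel, 3-of-6 for reactivity).  Enriched genes are
defined from a DEG table by a strict log2 fold-change threshold (default
M > 2).  Panel distinctness is summarized as the unique-gene fraction per
panel plus pairwise (and triple) intersections.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .containers import GenePanel, normalize_symbol, validate_deg_table
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def derive_enriched_genes(
    deg_table: pd.DataFrame,
    lfc_threshold: float = 2.0,
    fdr_cutoff: float | None = None,
) -> list:
    """Genes enriched in a contrast: strictly ``M > lfc_threshold``.

    Returned order is stable: descending M, then gene symbol.  No FDR filter
    is applied unless ``fdr_cutoff`` is given (boundary genes with
    ``M == lfc_threshold`` are excluded by the strict inequality).

    Raises
    ------
    ValueError
        If the DEG table is empty.
    """
    validate_deg_table(deg_table, require=("logFC",))
    table = deg_table
    if fdr_cutoff is not None:
        table = table[table["FDR"] < fdr_cutoff]
    hits = table[table["logFC"] > lfc_threshold]
    hits = hits.sort_values("logFC", ascending=False, kind="mergesort")
    # stable tie-break on symbol within equal M
    ordered = sorted(hits.index, key=lambda g: (-hits.at[g, "logFC"], str(g)))
    return [str(g) for g in ordered]


def vote_panel(lists, min_votes: int, name: str = "panel") -> GenePanel:
    """Curate a panel: genes present in at least ``min_votes`` of the lists.

    Membership is set-based per list (duplicates within one list count once);
    symbols are whitespace-trimmed and case-normalized before matching.

    Raises
    ------
    ValueError
        If no lists are given or ``min_votes`` is outside ``[1, len(lists)]``.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("no gene lists given")
    if not 1 <= min_votes <= len(lists):
        raise ValueError(f"min_votes must lie in [1, {len(lists)}], got {min_votes}")
    votes: Counter = Counter()
    for gene_list in lists:
        votes.update({normalize_symbol(g) for g in gene_list})
    kept = sorted(g for g, v in votes.items() if v >= min_votes)
    logger.info(
        "panel %r: %d of %d candidate genes kept at >=%d of %d votes",
        name, len(kept), len(votes), min_votes, len(lists),
    )
    return GenePanel(
        name=name,
        genes=tuple(kept),
        votes={g: votes[g] for g in kept},
        n_sources=len(lists),
        min_votes=min_votes,
    )


@dataclass
class PanelOverlapReport:
    """Panel-distinctness summary: unique fractions and intersections."""

    unique_fraction: dict  # panel name -> percent of genes in no other panel
    pairwise: dict  # frozenset({name_a, name_b}) -> intersection size
    triple: int | None = None  # |P1 & P2 & P3| when exactly three panels
    sizes: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"panel": name, "size": self.sizes[name], "unique_percent": frac}
            for name, frac in self.unique_fraction.items()
        ]
        return pd.DataFrame(rows).set_index("panel")


def panel_uniqueness(panels) -> PanelOverlapReport:
    """Unique-gene fraction per panel plus pairwise/triple intersections.

    The unique fraction of panel P is ``100 * |P \\ union(others)| / |P|``.

    Raises
    ------
    ValueError
        With fewer than two panels, or if any panel is empty.
    """
    panels = list(panels)
    if len(panels) < 2:
        raise ValueError("need at least two panels")
    sets = {}
    for p in panels:
        if len(p) == 0:
            raise ValueError(f"panel {p.name!r} is empty")
        sets[p.name] = p.as_set()
    unique = {}
    for name, genes in sets.items():
        others = set().union(*(s for n, s in sets.items() if n != name))
        unique[name] = 100.0 * len(genes - others) / len(genes)
    pairwise = {
        frozenset({a, b}): len(sets[a] & sets[b]) for a, b in combinations(sets, 2)
    }
    triple = None
    if len(sets) == 3:
        triple = len(frozenset.intersection(*sets.values()))
    return PanelOverlapReport(
        unique_fraction=unique,
        pairwise=pairwise,
        triple=triple,
        sizes={n: len(s) for n, s in sets.items()},
    )


# ---------------------------------------------------------------------------
# Panel IO
# ---------------------------------------------------------------------------


def read_panel(path, name: str | None = None) -> GenePanel:
    """Read a panel from newline-delimited symbols or two-column TSV (symbol, votes).

    Symbols are trimmed and case-normalized; duplicates collapse to one entry
    with a warning.  Malformed lines are reported with their line numbers.
    """
    path = Path(path)
    genes: list = []
    votes: dict = {}
    seen = set()
    max_vote = 1
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            symbol = normalize_symbol(parts[0])
            if not symbol:
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            vote = 1
            if len(parts) == 2:
                try:
                    vote = int(parts[1])
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: malformed vote count {parts[1]!r}") from err
            elif len(parts) > 2:
                raise ValueError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(parts)}")
            if symbol in seen:
                logger.warning("%s:%d: duplicate symbol %r ignored", path, lineno, symbol)
                continue
            seen.add(symbol)
            genes.append(symbol)
            votes[symbol] = vote
            max_vote = max(max_vote, vote)
    return GenePanel(
        name=name or path.stem,
        genes=tuple(genes),
        votes=votes,
        n_sources=max_vote,
        min_votes=1,
    )


def write_panel(panel: GenePanel, path) -> None:
    """Write a panel as two-column TSV (symbol, votes)."""
    path = Path(path)
    with open(path, "w") as handle:
        for gene in panel.genes:
            handle.write(f"{gene}\t{panel.votes.get(gene, 1)}\n")


class PanelVoter(BaseEstimator):
    """Estimator form of vote-threshold curation.

    ``fit(lists)`` takes a sequence of gene lists and exposes the curated
    panel and vote table as fitted attributes.
    """

    def __init__(self, min_votes: int = 5, name: str = "panel"):
        self.min_votes = min_votes
        self.name = name

    def fit(self, X, y=None):
        self.panel_ = vote_panel(X, min_votes=self.min_votes, name=self.name)
        self.votes_ = dict(self.panel_.votes)
        return self

    def transform(self, X):
        """Restrict each input gene list to the curated panel."""
        members = self.panel_.as_set()
        return [[g for g in lst if normalize_symbol(g) in members] for lst in X]
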