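"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of panel-driven RNA-seq
experiments: negative-binomial counts (``var = mu + phi * mu**2``) with
condition-specific, panel-structured log2 fold-changes on top of a log-uniform
baseline, variable library sizes, and paired "lineages" whose panel-restricted
state-change vectors enclose a planted angle (target cosine similarity).  It
also produces per-dataset enriched-gene lists for vote-threshold curation and
radially symmetric lesion-like images for the intensity-profile module.

Every output ships with its ground truth (a per-gene, per-condition log2
fold-change table, the planted direction vectors, or the planted geometry),
so downstream estimators can be scored without external data.

Randomness is split into named sub-streams derived from one global seed via
``numpy.random.SeedSequence`` spawn keys, so adding e.g. an image does not
perturb the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

_STREAMS = {"baseline": 0, "counts": 1, "offpanel": 2, "directions": 3, "voting": 4, "image": 5}

_MAX_MEAN = 1e12  # reject designs whose NB means would overflow counts


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class PanelSpec:
    """A gene-index set with a log2 fold-change effect per condition.

    ``effects`` maps condition label to either a scalar (applied to every
    panel gene) or a per-gene array of length ``len(genes)``.
    """

    name: str
    genes: np.ndarray
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=int)
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} has duplicate gene indices")

    def effect_vector(self, condition: str) -> np.ndarray:
        eff = self.effects.get(condition, 0.0)
        return np.broadcast_to(np.asarray(eff, dtype=float), self.genes.shape).copy()


@dataclass
class SyntheticDesign:
    """Design of a synthetic count experiment.

    Parameters
    ----------
    n_genes
        Number of genes.
    conditions
        List of ``(label, n_replicates)`` pairs; replicate counts must be >= 2.
    panels
        Panel specifications (gene index sets with per-condition effects).
    baseline_log2_mean
        Per-gene baseline on the log2 count scale at a library of 1e6 reads.
        If None, drawn uniformly over ``baseline_range`` (log-uniform means,
        default spanning 2**0 to 2**12) from the design's baseline stream.
    dispersion
        NB dispersion phi, ``var = mu + phi * mu**2``; shared across genes.
        Default 0.05 (biological coefficient of variation ~0.22, typical for
        bulk tissue replicates).
    library_sizes
        Scalar or per-sample array of sequencing depths.  Default 1e6.
    seed
        Global seed; all sub-streams derive from it.
    """

    n_genes: int
    conditions: list
    panels: list = field(default_factory=list)
    baseline_log2_mean: np.ndarray | None = None
    baseline_range: tuple = (0.0, 12.0)
    dispersion: float = 0.05
    library_sizes: float | np.ndarray = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for label, n_rep in self.conditions:
            if n_rep < 2:
                raise ValueError(f"condition {label!r} has {n_rep} replicates; need >= 2")
        for panel in self.panels:
            if panel.genes.size and (panel.genes.min() < 0 or panel.genes.max() >= self.n_genes):
                raise ValueError(f"panel {panel.name!r} indexes genes outside [0, n_genes)")
        libs = np.broadcast_to(np.asarray(self.library_sizes, dtype=float), (self.n_samples,))
        if np.any(libs <= 0):
            raise ValueError("library sizes must be positive")
        self._libs = libs

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.conditions)

    @property
    def condition_labels(self) -> list:
        return [label for label, _ in self.conditions]

    def sample_conditions(self) -> pd.Series:
        labels, ids = [], []
        for label, n_rep in self.conditions:
            for r in range(n_rep):
                ids.append(f"{label}_{r + 1}")
                labels.append(label)
        return pd.Series(labels, index=ids)

    def baseline(self) -> np.ndarray:
        if self.baseline_log2_mean is not None:
            base = np.asarray(self.baseline_log2_mean, dtype=float)
            if base.shape != (self.n_genes,):
                raise ValueError("baseline_log2_mean must have length n_genes")
            return base
        lo, hi = self.baseline_range
        return _rng(self.seed, "baseline").uniform(lo, hi, self.n_genes)

    def gene_ids(self) -> pd.Index:
        width = len(str(self.n_genes - 1))
        return pd.Index([f"gene_{i:0{width}d}" for i in range(self.n_genes)])


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) via gamma-Poisson mixing; Poisson when phi ~ 0."""
    if phi < 1e-10:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def effect_matrix(design: SyntheticDesign, extra_effects: np.ndarray | None = None) -> pd.DataFrame:
    """Planted per-gene, per-condition log2 fold-changes (the truth table)."""
    labels = design.condition_labels
    eff = np.zeros((design.n_genes, len(labels)))
    for panel in design.panels:
        for j, label in enumerate(labels):
            eff[panel.genes, j] += panel.effect_vector(label)
    if extra_effects is not None:
        eff = eff + np.asarray(extra_effects, dtype=float)
    return pd.DataFrame(eff, index=design.gene_ids(), columns=labels)


def generate_counts(
    design: SyntheticDesign, extra_effects: np.ndarray | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix from the design; returns (counts, truth table).

    The NB mean of gene g in sample s of condition c is
    ``library_size_s / 1e6 * 2 ** (baseline_g + effect_gc)``.  The truth table
    holds the exact planted log2 fold-change per gene and condition; identical
    design and seed give bit-identical output.

    Raises
    ------
    ValueError
        If any mean is non-finite or would overflow representable counts.
    """
    truth = effect_matrix(design, extra_effects)
    base = design.baseline()
    cond = design.sample_conditions()
    label_to_col = {label: j for j, label in enumerate(truth.columns)}
    eff = truth.to_numpy()
    col_idx = np.array([label_to_col[c] for c in cond.to_numpy()])
    log2_mean = base[:, None] + eff[:, col_idx]
    mean = design._libs[None, :] / 1e6 * np.exp2(log2_mean)
    if not np.all(np.isfinite(mean)) or np.any(mean > _MAX_MEAN):
        raise ValueError("design rejected: NB means non-finite or beyond representable counts")
    counts = _sample_nb(_rng(design.seed, "counts"), mean, design.dispersion)
    frame = pd.DataFrame(counts, index=design.gene_ids(), columns=cond.index)
    return CountMatrix(frame, cond), truth


# ---------------------------------------------------------------------------
# Planted convergence (two lineages with a known angle)
# ---------------------------------------------------------------------------


@dataclass
class PlantedConvergence:
    """Orthonormal direction pair defining a planted angle between two
    panel-restricted state changes.

    Lineage 1 moves along ``u``; lineage 2 along ``cos(theta) u + sin(theta) w``,
    so the true cosine similarity of the planted panel vectors is
    ``cos(theta)`` exactly.
    """

    panel: str
    theta: float
    direction_u: np.ndarray
    direction_w: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= np.pi / 2:
            raise ValueError("theta must lie in [0, pi/2]")
        u = np.asarray(self.direction_u, dtype=float)
        w = np.asarray(self.direction_w, dtype=float)
        if abs(np.linalg.norm(u) - 1) > 1e-10 or abs(np.linalg.norm(w) - 1) > 1e-10:
            raise ValueError("direction vectors must be unit norm")
        if abs(float(u @ w)) > 1e-10:
            raise ValueError("direction vectors must be orthogonal")
        self.direction_u, self.direction_w = u, w

    @property
    def target_cs(self) -> float:
        return float(np.cos(self.theta))

    @classmethod
    def random(cls, panel: str, n_genes: int, theta: float, seed: int = 0) -> "PlantedConvergence":
        """Random orthonormal (u, w) pair over ``n_genes`` panel genes."""
        rng = _rng(seed, "directions")
        u = rng.standard_normal(n_genes)
        u /= np.linalg.norm(u)
        w = rng.standard_normal(n_genes)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        return cls(panel=panel, theta=theta, direction_u=u, direction_w=w)


def generate_state_pair(
    design: SyntheticDesign,
    convergence: PlantedConvergence,
    magnitudes: tuple = (60.0, 60.0),
    offpanel_sd: float = 0.1,
) -> tuple[CountMatrix, CountMatrix, dict]:
    """Two two-condition contrasts whose panel state changes enclose theta.

    ``design.conditions`` must name four conditions interpreted as
    (lineage-1 reference, lineage-1 target, lineage-2 reference, lineage-2
    target).  Panel genes in the target conditions move by ``m1 * u`` and
    ``m2 * (cos(theta) u + sin(theta) w)`` respectively; off-panel genes
    receive independent N(0, offpanel_sd**2) log2 fold-changes in the target
    conditions so panels dominate the geometry.

    Returns the two lineage count matrices and a truth dict with the planted
    panel vectors, their exact cosine, and the full effect table.
    """
    m1, m2 = magnitudes
    if m1 <= 0 or m2 <= 0:
        raise ValueError("magnitudes must be positive")
    panel = next((p for p in design.panels if p.name == convergence.panel), None)
    if panel is None:
        raise ValueError(f"panel {convergence.panel!r} not found in design")
    if panel.genes.size != convergence.direction_u.size:
        raise ValueError("direction vectors do not match panel size")
    if len(design.conditions) != 4:
        raise ValueError("state-pair design needs exactly 4 conditions (ref1, tgt1, ref2, tgt2)")
    labels = design.condition_labels
    ref1, tgt1, ref2, tgt2 = labels

    v1 = m1 * convergence.direction_u
    v2 = m2 * (
        np.cos(convergence.theta) * convergence.direction_u
        + np.sin(convergence.theta) * convergence.direction_w
    )
    extra = np.zeros((design.n_genes, 4))
    extra[panel.genes, 1] = v1
    extra[panel.genes, 3] = v2
    off = np.setdiff1d(np.arange(design.n_genes), panel.genes)
    rng = _rng(design.seed, "offpanel")
    extra[off, 1] = rng.normal(0.0, offpanel_sd, off.size)
    extra[off, 3] = rng.normal(0.0, offpanel_sd, off.size)

    cm, truth = generate_counts(design, extra_effects=extra)
    cond = cm.conditions
    lineage1 = cm.subset_samples(cond.index[cond.isin([ref1, tgt1])])
    lineage2 = cm.subset_samples(cond.index[cond.isin([ref2, tgt2])])
    norm1 = float(np.linalg.norm(v1))
    norm2 = float(np.linalg.norm(v2))
    truth_info = {
        "panel_genes": cm.genes[panel.genes],
        "v1": pd.Series(v1, index=cm.genes[panel.genes]),
        "v2": pd.Series(v2, index=cm.genes[panel.genes]),
        "true_cs": float(v1 @ v2 / (norm1 * norm2)),
        "effects": truth,
        "contrasts": ((ref1, tgt1), (ref2, tgt2)),
    }
    return lineage1, lineage2, truth_info


# ---------------------------------------------------------------------------
# Voting lists
# ---------------------------------------------------------------------------


def generate_voting_lists(
    true_panel,
    n_datasets: int,
    sensitivity,
    n_false_positives: int,
    background,
    seed: int = 0,
) -> list:
    """Per-dataset enriched-gene lists containing true panel genes with a
    given sensitivity plus random non-panel false positives.

    Each dataset list includes each true gene independently with probability
    ``sensitivity`` (scalar or per-dataset sequence) and
    ``n_false_positives`` genes drawn without replacement from ``background``
    (true-panel genes are excluded from the pool).  Deterministic under seed.

    Raises
    ------
    ValueError
        If sensitivity is outside [0, 1] or the false-positive pool is
        exhausted.
    """
    true_panel = list(true_panel)
    sens = np.broadcast_to(np.asarray(sensitivity, dtype=float), (n_datasets,))
    if np.any((sens < 0) | (sens > 1)):
        raise ValueError("sensitivity must lie in [0, 1]")
    pool = [g for g in background if g not in set(true_panel)]
    if n_false_positives > len(pool):
        raise ValueError(
            f"false-positive pool exhausted: need {n_false_positives}, have {len(pool)}"
        )
    rng = _rng(seed, "voting")
    lists = []
    for d in range(n_datasets):
        keep = rng.random(len(true_panel)) < sens[d]
        hits = [g for g, k in zip(true_panel, keep) if k]
        fps = list(rng.choice(pool, size=n_false_positives, replace=False)) if n_false_positives else []
        lists.append(hits + fps)
    return lists


# ---------------------------------------------------------------------------
# Lesion-like images
# ---------------------------------------------------------------------------


@dataclass
class LesionImageConfig:
    """Radially symmetric lesion phantom: core disk, border annulus, background.

    Intensities are arbitrary units; ``noise_sd`` adds i.i.d. Gaussian noise.
    """

    shape: tuple = (256, 256)
    center: tuple | None = None
    core_radius: float = 40.0
    border_width: float = 15.0
    core_intensity: float = 20.0
    border_intensity: float = 200.0
    background_intensity: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = ((self.shape[1] - 1) / 2.0, (self.shape[0] - 1) / 2.0)
        if not 0 < self.core_radius < min(self.shape) / 2:
            raise ValueError("core radius must lie in (0, min(image dims)/2)")
        for name in ("core_intensity", "border_intensity", "background_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_lesion_image(config: LesionImageConfig) -> tuple[np.ndarray, dict]:
    """Render the lesion phantom; returns (image, ground-truth geometry).

    The noiseless image is radially symmetric about the configured center:
    core intensity inside ``core_radius``, border intensity in the annulus
    ``[core_radius, core_radius + border_width)``, background elsewhere.
    """
    rows, cols = np.indices(config.shape)
    cx, cy = config.center
    r = np.hypot(cols - cx, rows - cy)
    image = np.full(config.shape, float(config.background_intensity))
    border_outer = config.core_radius + config.border_width
    image[r < border_outer] = config.border_intensity
    image[r < config.core_radius] = config.core_intensity
    if config.noise_sd > 0:
        image = image + _rng(config.seed, "image").normal(0.0, config.noise_sd, config.shape)
    truth = {
        "center": config.center,
        "core_radius": config.core_radius,
        "border_inner": config.core_radius,
        "border_outer": border_outer,
        "intensities": (
            config.core_intensity,
            config.border_intensity,
            config.background_intensity,
        ),
    }
    return image, truth
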