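"""Config-driven end-to-end run: QC -> normalize -> DE -> panels -> geometry.

A run compares two transcriptional transitions (contrast 1 and contrast 2),
optionally restricted to a curated gene panel, and writes DEG tables, a
similarity report, a congruence table and a manifest with checksums so that
identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .containers import CountMatrix
from .diffexpr import call_degs, nb_exact_test, snqc_filter, tmm_factors
from .geometry import compare_state_changes, congruence_classify, state_change
from .io import read_counts, write_deg_table
from .panels import read_panel, vote_panel

logger = logging.getLogger(__name__)


@dataclass
class ContrastConfig:
    counts: str
    conditions: str
    reference: str
    name: str = "contrast"


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run (YAML-serializable)."""

    output_dir: str
    contrast1: ContrastConfig
    contrast2: ContrastConfig
    panel: str | None = None
    gene_lists: list = field(default_factory=list)
    min_votes: int = 1
    fdr_cutoff: float = 0.01
    dispersion: float | None = None
    min_abs_m: float = 1.0
    single_cell_qc: bool = False
    min_cells_per_gene: int = 200
    min_genes_per_cell: int = 333
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        raw["contrast1"] = ContrastConfig(name="contrast1", **raw["contrast1"])
        raw["contrast2"] = ContrastConfig(name="contrast2", **raw["contrast2"])
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        for contrast in (self.contrast1, self.contrast2):
            for p in (contrast.counts, contrast.conditions):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input not found: {p}")
        if self.panel and not Path(self.panel).exists():
            raise FileNotFoundError(f"panel file not found: {self.panel}")
        for p in self.gene_lists:
            if not Path(p).exists():
                raise FileNotFoundError(f"gene list not found: {p}")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must lie in (0, 1]")


@dataclass
class RunManifest:
    """Provenance of one run: version, config hash, input checksums, outputs."""

    version: str
    config_hash: str
    started: str
    finished: str
    input_checksums: dict
    output_checksums: dict
    stage_counts: dict

    def write(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.__dict__, handle, indent=2, sort_keys=True)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _run_contrast(contrast: ContrastConfig, config: RunConfig, outdir: Path, counts_hook=None):
    cm = read_counts(contrast.counts, conditions=contrast.conditions)
    if config.single_cell_qc:
        cm = snqc_filter(
            cm,
            min_cells_per_gene=config.min_cells_per_gene,
            min_genes_per_cell=config.min_genes_per_cell,
        )
    norm = tmm_factors(cm)
    table = nb_exact_test(
        cm, norm=norm, dispersion=config.dispersion, reference=contrast.reference
    )
    out = outdir / f"{contrast.name}_degs.csv"
    write_deg_table(table, out)
    degs = call_degs(table, config.fdr_cutoff)
    return cm, table, out, degs


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write outputs plus a manifest.

    Stage order: (optional single-cell) QC -> TMM normalization -> NB exact
    test per contrast -> panel curation/loading -> state-change geometry
    (cosine similarity, PCA distance, congruence labels).  Any stage error
    aborts with the stage name; outputs already written are preserved.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    logger.info("pipeline seed=%d", config.seed)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [config.contrast1.counts, config.contrast1.conditions,
              config.contrast2.counts, config.contrast2.conditions]
    if config.panel:
        inputs.append(config.panel)
    inputs.extend(config.gene_lists)
    input_checksums = {str(p): _sha256(p) for p in inputs}
    stage_counts: dict = {}
    outputs: list = []

    stage = "de"
    try:
        tables = []
        for contrast in (config.contrast1, config.contrast2):
            _, table, out, degs = _run_contrast(contrast, config, outdir)
            tables.append(table)
            outputs.append(out)
            stage_counts[f"{contrast.name}_genes"] = int(len(table))
            stage_counts[f"{contrast.name}_degs"] = int(len(degs))

        stage = "panels"
        panel = None
        if config.gene_lists:
            lists = [
                [line.strip() for line in open(p) if line.strip()] for p in config.gene_lists
            ]
            panel = vote_panel(lists, min_votes=config.min_votes, name="voted_panel")
        elif config.panel:
            panel = read_panel(config.panel)
        if panel is not None:
            stage_counts["panel_genes"] = len(panel)

        stage = "geometry"
        v1 = state_change(tables[0])
        v2 = state_change(tables[1])
        report = compare_state_changes(v1, v2, panel=panel)
        labels = congruence_classify(v1, v2, min_abs_m=config.min_abs_m)
        report_path = outdir / "similarity_report.json"
        with open(report_path, "w") as handle:
            json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
        congruence_path = outdir / "congruence.csv"
        labels.rename("label").to_csv(congruence_path, index_label="gene")
        outputs.extend([report_path, congruence_path])
        stage_counts["geometry_shared_genes"] = int(report.n_genes)
        stage_counts["congruent"] = int((labels.str.startswith("congruent")).sum())
        stage_counts["divergent"] = int((labels == "divergent").sum())
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.__dict__.items() if k != "output_dir"},
                default=lambda o: o.__dict__,
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        input_checksums=input_checksums,
        output_checksums={p.name: _sha256(p) for p in outputs},
        stage_counts=stage_counts,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
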