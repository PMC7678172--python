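"""End-to-end orchestration: simulate (or load) -> filter -> associate.

One :func:`run_all` call executes the whole discovery procedure and
returns a machine-readable :class:`RunReport`; re-running with the same
config and seed reproduces every count and p-value (the timestamp is the
only non-deterministic field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path

from . import io as cio
from .filters import CascadeReport, run_cascade
from .models import GeneModel, Phenotype
from .simulate import DEFAULT_STAGES, SimulatedDataset, SimulationConfig, simulate_dataset
from .stats import AssociationResult, associate, cohort_summary

logger = logging.getLogger(__name__)


def _version() -> str:
    try:
        return metadata.version("coatscan")
    except metadata.PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class RunReport:
    """Self-describing record of one pipeline run."""

    config: dict
    cascade: CascadeReport
    associations: list[AssociationResult]
    cohort: dict
    version: str = field(default_factory=_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @property
    def final_keys(self):
        return self.cascade.final_keys

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "cascade": self.cascade.as_dict(),
            "associations": [
                {
                    "variant": cio.format_variant_column(a.variant),
                    "table": a.table.counts.tolist(),
                    "genotype_labels": list(a.table.col_labels),
                    "n_excluded": a.table.n_excluded,
                    "p_value": a.p_value,
                    "concordance_pct": a.concordance_pct,
                    "carrier_pct": a.carrier.pct,
                    "carrier_pct_rendered": a.carrier.rendered,
                }
                for a in self.associations
            ],
            "cohort": self.cohort,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n")
        return path


def run_all(
    config: SimulationConfig,
    stages=DEFAULT_STAGES,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Simulate a dataset, run the filtering cascade over its staged
    panels, and test each surviving candidate for association on the
    full cohort. Optionally writes the report JSON plus the simulated
    inputs (VCF, gene models, gene list, panels) under ``out_dir``."""
    dataset = simulate_dataset(config, stages=stages)
    report = analyse(dataset, stages=stages)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cio.write_vcf(dataset.vcf_records, out_dir / "calls.vcf", dataset.samples)
        cio.write_gene_models(dataset.gene_models, out_dir / "gene_models.tsv")
        cio.write_gene_list(dataset.gene_list, out_dir / "gene_list.txt")
        keys = [v.key for v, _ in dataset.vcf_records]
        for i, panel in enumerate(dataset.panels, start=1):
            cio.write_panel(panel, out_dir / f"panel_{i}.tsv", keys)
        report.write(out_dir / "report.json")
    return report


def analyse(dataset: SimulatedDataset, stages=DEFAULT_STAGES) -> RunReport:
    """The analysis half of :func:`run_all`, reusable on a pre-built
    dataset (simulated or assembled from files)."""
    cascade = run_cascade(
        dataset.vcf_records,
        dataset.gene_models,
        {s.upper() for s in dataset.gene_list},
        affected_id=dataset.truth.dam_id if dataset.truth else dataset.samples[0],
        carrier_id=dataset.truth.calf_id if dataset.truth else dataset.samples[1],
        panels=dataset.panels,
    )
    full_panel = dataset.panels[-1] if dataset.panels else []
    associations = [associate(full_panel, c.key) for c in cascade.final if full_panel]
    summary = cohort_summary(full_panel or dataset.cohort)
    report = RunReport(
        config=_config_dict(dataset.config),
        cascade=cascade,
        associations=associations,
        cohort={
            "n_total": summary.n_total,
            "n_pigmented": summary.n_pigmented,
            "n_white": summary.n_white,
            "white_pct": summary.white_pct,
            "per_location": summary.per_location,
        },
    )
    for stage in cascade.stages:
        logger.info("stage %-28s in=%5d out=%5d", stage.stage, stage.n_in, stage.n_out)
    return report


def _config_dict(config: SimulationConfig | None) -> dict:
    if config is None:
        return {}
    d = dataclasses.asdict(config)
    d["qual_range"] = list(d["qual_range"])
    return d


def validate_inputs(
    gene_models: list[GeneModel] | None = None,
    vcf_samples: list[str] | None = None,
    expected_samples: list[str] | None = None,
    panels: list | None = None,
) -> list[str]:
    """Structured pre-flight diagnostics; returns messages, raises nothing.

    Checks gene-model integrity (CDS length divisible by 3, segment
    spans matching sequence length), sample-id presence, and panel
    phenotype sanity. An empty list means no problems found.
    """
    diagnostics: list[str] = []
    # Accepts constructed GeneModel objects or raw TSV-style dicts
    # (symbol, segments "a-b;c-d", cds_seq) so content can be probed
    # before GeneModel's own constructor enforces the invariants.
    for model in gene_models or []:
        if isinstance(model, GeneModel):
            symbol, segments, cds_len = model.symbol, model.cds_segments, model.cds_length
        else:
            symbol = model.get("symbol", "?")
            try:
                segments = tuple(
                    (int(a), int(b))
                    for a, b in (part.split("-") for part in model["segments"].split(";"))
                )
            except (KeyError, ValueError):
                diagnostics.append(f"{symbol}: unparseable CDS segments")
                continue
            cds_len = len(model.get("cds_seq", ""))
        total = sum(end - start + 1 for start, end in segments)
        if total != cds_len:
            diagnostics.append(
                f"{symbol}: segment span {total} != CDS length {cds_len}"
            )
        if cds_len % 3 != 0:
            diagnostics.append(
                f"{symbol}: CDS length {cds_len} not divisible by 3"
            )
    if vcf_samples is not None and expected_samples is not None:
        for sid in expected_samples:
            if sid not in vcf_samples:
                diagnostics.append(f"sample {sid!r} not present in VCF samples")
    for i, panel in enumerate(panels or [], start=1):
        phenos = {a.phenotype for a in panel}
        if panel and phenos <= {Phenotype.PIGMENTED}:
            diagnostics.append(f"panel {i}: contains no affected (WHITE) animal")
    return diagnostics
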