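"""End-to-end run orchestration.

A run directory is produced in a fixed stage order — simulate (optional)
-> preprocess -> annotate -> filter -> metrics -> treemap — with every
stage writing its own outputs and a count ledger (reads in / out /
removed per reason), in the spirit of the raw-to-clean read accounting
of repertoire-sequencing studies. All stage parameters default to the
protocol values: 2-base / Q20 trimming window, 15-nt minimum merge
overlap, >200 bp / <6 mismatch V relatedness, 5% minor-collapse
fraction, mu = 1/8000, alpha = 0.001, 5-copy mutation floor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .align import Scoring
from .annotate import AnnotateConfig, annotate_sample
from .barcodes import BarcodeSet, design_barcodes
from .clonotype import ClonotypeTable
from .filters import DEFAULT_ALPHA, DEFAULT_MU, apply_artifact_filters
from .metrics import metrics_tidy, pairwise_sharing
from .preprocess import preprocess_run
from .reference import GermlineReference, generate_reference
from .simulate import SimulationParams, emit_run, simulate_repertoire
from .treemap import layout_treemap, write_svg

import numpy as np


@dataclass
class ReferenceSpec:
    n_v: int = 10
    n_d: int = 4
    n_j: int = 4


@dataclass
class PreprocessParams:
    window: int = 2
    q_threshold: int = 20
    min_overlap: int = 15
    min_length: int = 100


@dataclass
class FilterParams:
    cdr3_max_mismatch: int = 1
    minor_fraction: float = 0.05
    mu: float = DEFAULT_MU
    alpha: float = DEFAULT_ALPHA


@dataclass
class RunConfig:
    """Declarative configuration of a full run; YAML round-trips losslessly."""

    seed: int = 0
    n_samples: int = 2
    simulation: SimulationParams = field(default_factory=SimulationParams)
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    filters: FilterParams = field(default_factory=FilterParams)
    min_copies: int = 5
    barcode_length: int = 6
    barcode_min_distance: int = 3
    canvas: tuple[float, float] = (1000.0, 600.0)
    # optional external inputs; when unset the run starts by simulating
    fastq_fwd: str | None = None
    fastq_rev: str | None = None
    reference_fasta: str | None = None
    reference_sidecar: str | None = None
    barcodes: list[str] | None = None
    sample_ids: list[str] | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationParams(**d["simulation"])
        if "reference" in d:
            d["reference"] = ReferenceSpec(**d["reference"])
        if "preprocess" in d:
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "filters" in d:
            d["filters"] = FilterParams(**d["filters"])
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        return cls(**d)


@dataclass
class RunResult:
    out_dir: Path
    reference: GermlineReference
    barcodes: BarcodeSet
    sample_ids: list[str]
    tables_raw: dict[str, ClonotypeTable]
    tables_filtered: dict[str, ClonotypeTable]
    ledger: pd.DataFrame
    metrics: pd.DataFrame


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute all stages into ``out_dir``; see module docstring for order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger_rows: list[dict] = []

    # ---- stage 0: inputs (simulated or provided) ----
    if config.fastq_fwd is None:
        ref = generate_reference(
            config.reference.n_v, config.reference.n_d, config.reference.n_j,
            seed=config.seed,
        )
        barcodes = design_barcodes(
            config.n_samples, config.barcode_length,
            config.barcode_min_distance, seed=config.seed,
        )
        sample_ids = [f"S{i + 1}" for i in range(config.n_samples)]
        repertoires = {}
        for i, s in enumerate(sample_ids):
            rng = np.random.default_rng([config.seed, i])
            repertoires[s] = simulate_repertoire(
                config.simulation, ref, sample_id=s, rng=rng
            )
        files = emit_run(
            repertoires, barcodes, config.simulation, out,
            min_overlap=config.preprocess.min_overlap,
        )
        ref.write(out / "reference.fasta", out / "reference_cdr_marks.tsv")
        fwd, rev = files.fwd_fastq, files.rev_fastq
        for s in sample_ids:
            ledger_rows.append(
                {
                    "stage": "simulate", "sample_id": s,
                    "n_in": len(repertoires[s]),
                    "n_out": sum(c.abundance for c in repertoires[s]),
                    "detail": "clonotypes -> reads",
                }
            )
    else:
        if config.reference_fasta is None or config.barcodes is None:
            raise ValueError("external runs need reference_fasta and barcodes")
        ref = GermlineReference.read(config.reference_fasta, config.reference_sidecar)
        barcodes = BarcodeSet(
            list(config.barcodes), config.barcode_length, config.barcode_min_distance
        )
        sample_ids = config.sample_ids or [
            f"S{i + 1}" for i in range(len(barcodes))
        ]
        fwd, rev = Path(config.fastq_fwd), Path(config.fastq_rev)

    # ---- stage 1: preprocess ----
    merged, stats = preprocess_run(
        fwd, rev, barcodes, sample_ids,
        window=config.preprocess.window,
        threshold=config.preprocess.q_threshold,
        min_overlap=config.preprocess.min_overlap,
        min_length=config.preprocess.min_length,
    )
    pd.DataFrame(stats).T.fillna(0).astype(int).to_csv(
        out / "preprocess_stats.tsv", sep="\t"
    )
    for s, tally in stats.items():
        if s == "unassigned":
            ledger_rows.append(
                {"stage": "demultiplex", "sample_id": s,
                 "n_in": tally["assigned"], "n_out": 0, "detail": "no barcode match"}
            )
            continue
        ledger_rows.append(
            {"stage": "preprocess", "sample_id": s, "n_in": tally["assigned"],
             "n_out": tally["merged"],
             "detail": f"dropped_short={tally['dropped_short']} "
             f"mismatch={tally['MISMATCH']} no_overlap={tally['NO_OVERLAP']} "
             f"too_short={tally['TOO_SHORT']}"}
        )

    # ---- stage 2: annotate ----
    acfg = AnnotateConfig(scoring=Scoring(), min_copies=config.min_copies)
    tables_raw: dict[str, ClonotypeTable] = {}
    for s in sample_ids:
        records, log = annotate_sample(merged.get(s, []), ref, s, acfg)
        tables_raw[s] = ClonotypeTable(s, records)
        tables_raw[s].write_tsv(out / f"{s}.annotated.tsv")
        ledger_rows.append(
            {"stage": "annotate", "sample_id": s, "n_in": log["input"],
             "n_out": log["annotated"],
             "detail": f"unmapped={log['unmapped']} "
             f"failed_migration={log['failed_migration']}"}
        )

    # ---- stage 3: artifact filters ----
    tables_filtered, filter_ledger, report = apply_artifact_filters(
        tables_raw, ref,
        cdr3_max_mismatch=config.filters.cdr3_max_mismatch,
        minor_fraction=config.filters.minor_fraction,
        mu=config.filters.mu, alpha=config.filters.alpha,
    )
    report.to_csv(out / "contamination_report.tsv", sep="\t", index=False)
    filter_ledger.to_csv(out / "filter_ledger.tsv", sep="\t", index=False)
    for row in filter_ledger.itertuples(index=False):
        ledger_rows.append(
            {"stage": "filter", "sample_id": row.sample_id,
             "n_in": row.input_records, "n_out": row.output_records,
             "detail": f"related={row.removed_related} "
             f"singleton={row.removed_singleton} "
             f"contamination={row.removed_contamination}"}
        )
        tables_filtered[row.sample_id].write_tsv(
            out / f"{row.sample_id}.filtered.tsv"
        )

    # ---- stage 4: metrics ----
    frames = [
        metrics_tidy(t, ref) for t in tables_filtered.values() if len(t) > 0
    ]
    metrics_df = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    metrics_df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    sharing_rows = []
    nonempty = [s for s in sample_ids if len(tables_filtered[s]) > 0]
    for i, a in enumerate(nonempty):
        for b in nonempty[i + 1 :]:
            try:
                pab, pba = pairwise_sharing(tables_filtered[a], tables_filtered[b])
            except ValueError:
                continue
            sharing_rows.append(
                {"sample_a": a, "sample_b": b, "pA_to_B": pab, "pB_to_A": pba}
            )
    pd.DataFrame(sharing_rows).to_csv(out / "sharing.tsv", sep="\t", index=False)
    summary = {
        s: {
            "total_copies": tables_filtered[s].total_copies,
            "distinct_cdr3_nt": tables_filtered[s].distinct_cdr3_nt,
            "distinct_cdr3_aa": tables_filtered[s].distinct_cdr3_aa,
        }
        for s in sample_ids
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    # ---- stage 5: treemaps ----
    for s in nonempty:
        layout = layout_treemap(tables_filtered[s], config.canvas, seed=config.seed)
        write_svg(layout, out / f"{s}.treemap.svg")

    ledger = pd.DataFrame(ledger_rows)
    ledger.to_csv(out / "run_ledger.tsv", sep="\t", index=False)
    return RunResult(
        out, ref, barcodes, sample_ids, tables_raw, tables_filtered,
        ledger, metrics_df,
    )
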