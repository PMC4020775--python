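"""Pipeline orchestration: parse -> spacers -> composition -> rearrangement.

Produces one :class:`ArchitectureReport` mirroring the layout of a printed
mitogenome annotation table — one row per gene with its position, size,
signed spacer to the next gene, AT%, start and stop codons — plus a summary
block (totals, strand counts, overlaps, rearrangement events against a
reference order).  JSON output carries full precision; the human-readable
table applies one-decimal percent rounding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_io import MitogenomeRecord, parse_feature_table, parse_genbank, read_fasta
from .composition import extract_codons, region_composition
from .rearrangement import (
    GeneOrder,
    RearrangementReport,
    ancestral_pancrustacean_order,
    move_distance,
    order_from_record,
)
from .spacers import compute_spacers, summarize_spacers

__all__ = ["ArchitectureReport", "run_pipeline", "load_annotation"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ArchitectureReport:
    genome_id: str
    rows: pd.DataFrame  # gene, strand, start, end, size, igs_to_next, at_pct, start_codon, stop_codon
    summary: dict
    rearrangement: RearrangementReport | None
    warnings_log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "genome_id": self.genome_id,
            "rows": self.rows.where(pd.notna(self.rows), None).to_dict(orient="records"),
            "summary": self.summary,
            "rearrangement": None
            if self.rearrangement is None
            else {
                "event_count": self.rearrangement.event_count,
                "moved_genes": self.rearrangement.moved_genes,
            },
            "warnings": self.warnings_log,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        out = self.rows.copy()
        if "at_pct" in out:
            out["at_pct"] = out["at_pct"].map(
                lambda v: "" if pd.isna(v) else f"{v:.1f}"
            )
        return out.to_csv(sep="\t", index=False)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.tsv").write_text(self.to_tsv())
        (outdir / "report.json").write_text(self.to_json() + "\n")
        lines = []
        if self.rearrangement is not None:
            r = self.rearrangement
            lines.append(f"rearrangement events vs reference: {r.event_count}")
            for g, kind in sorted(r.moved_genes.items()):
                lines.append(f"  {g}: {kind}")
        (outdir / "rearrangement.txt").write_text("\n".join(lines) + "\n")
        (outdir / "log.txt").write_text("\n".join(self.warnings_log) + "\n")


def load_annotation(path, fmt: str | None = None) -> MitogenomeRecord:
    """Load a TSV feature table or GenBank record, guessing from the suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "tsv"
    return parse_genbank(path) if fmt == "genbank" else parse_feature_table(path)


def run_pipeline(
    annotation,
    fasta=None,
    reference: GeneOrder | None = None,
    thresholds: tuple[int, ...] = (160,),
    threshold_mode: str = "ge",
) -> ArchitectureReport:
    """Run all stages on one annotation.

    ``annotation`` is a path or an in-memory record; ``fasta`` optionally
    attaches a sequence, enabling the composition columns and sequence-based
    codon calls.  ``reference`` defaults to the ancestral pancrustacean
    order when the gene sets match, else the comparison is skipped.
    """
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        # --- parse ---------------------------------------------------------
        try:
            if isinstance(annotation, MitogenomeRecord):
                record = annotation
            else:
                record = load_annotation(annotation)
            if fasta is not None:
                record = record.with_sequence(
                    fasta if isinstance(fasta, str) and set(fasta) <= set("ACGTN")
                    else read_fasta(fasta)
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("parse", exc) from exc
        # --- spacers -------------------------------------------------------
        try:
            spacers = compute_spacers(record)
            summary = summarize_spacers(spacers, thresholds, threshold_mode)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("spacers", exc) from exc
        igs_next = {s.upstream: s.length for s in spacers}
        # --- composition (optional) ---------------------------------------
        at_by_gene: dict[str, float] = {}
        genome_at = None
        codons: dict[str, tuple[str, str, bool]] = {}
        if record.sequence is not None:
            try:
                for prof in region_composition(record, "genes"):
                    at_by_gene[prof.region_label] = prof.at_percent
                genome_at = region_composition(record, "genome")[0].at_percent
                codons = extract_codons(record)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("composition", exc) from exc
        # --- rearrangement -------------------------------------------------
        rearrangement = None
        try:
            order = order_from_record(record)
            ref = reference or ancestral_pancrustacean_order()
            if order.symbols() == ref.symbols():
                rearrangement = move_distance(order, ref)
            else:
                warnings.warn(
                    f"{record.genome_id}: gene set differs from reference; "
                    "rearrangement comparison skipped"
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("rearrangement", exc) from exc
        caught = [str(w.message) for w in wlog]

    rows = pd.DataFrame(
        [
            {
                "gene": f.name,
                "gene_class": f.gene_class,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "size": f.length,
                "igs_to_next": igs_next.get(f.name),
                "at_pct": at_by_gene.get(f.name),
                "start_codon": codons.get(f.name, (f.start_codon, None, None))[0],
                "stop_codon": codons.get(f.name, (None, f.stop_codon, None))[1],
            }
            for f in record.features
        ]
    )
    strand_counts = rows["strand"].value_counts().to_dict() if len(rows) else {}
    overlaps = [
        {"upstream": s.upstream, "downstream": s.downstream, "overlap_bp": -s.length}
        for s in spacers
        if s.is_overlap
    ]
    summary_block = {
        "genome_length": record.length,
        "gene_count": len(record.features),
        "strand_counts": strand_counts,
        "sum_gene_lengths": int(rows["size"].sum()) if len(rows) else 0,
        "igs_total_bp": summary.igs_total_bp,
        "igs_count": summary.igs_count,
        "igs_total_with_cr": summary.igs_total_with_cr,
        "overlaps": overlaps,
        "longest_igs": summary.longest,
        "n_at_least": summary.n_at_least,
        "genome_at_pct": genome_at,
    }
    if genome_at is None:
        summary_block.pop("genome_at_pct")
    return ArchitectureReport(
        genome_id=record.genome_id,
        rows=rows,
        summary=summary_block,
        rearrangement=rearrangement,
        warnings_log=caught,
    )
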