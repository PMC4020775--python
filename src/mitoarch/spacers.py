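"""Signed intergenic spacers (IGS) and overlaps on the circular genome.

Between each pair of circularly adjacent genes there is a signed gap:
positive = non-coding spacer, zero = abutting genes, negative = overlap.
The spacer immediately following the small ribosomal subunit gene (srRNA)
is the putative control region (AT-rich region) and is excluded from IGS
totals, the standard convention when comparing mitogenome spacer content
across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import MitogenomeRecord

__all__ = ["Spacer", "SpacerSummary", "compute_spacers", "summarize_spacers", "compare_genomes"]

CONTROL_REGION_UPSTREAM = "srRNA"


@dataclass(frozen=True)
class Spacer:
    """Signed gap between two circularly adjacent genes.

    ``length < 0`` means the genes overlap by ``-length`` bp; ``0`` means
    they abut.  ``is_control_region`` marks the spacer immediately
    following srRNA (the putative control region).
    """

    upstream: str
    downstream: str
    length: int
    wraps_origin: bool = False
    is_control_region: bool = False

    @property
    def is_igs(self) -> bool:
        """True for a positive, non-control-region spacer."""
        return self.length > 0 and not self.is_control_region

    @property
    def is_overlap(self) -> bool:
        return self.length < 0


@dataclass
class SpacerSummary:
    igs_total_bp: int
    igs_count: int
    igs_total_with_cr: int
    overlap_count: int
    overlap_bp: int
    longest: tuple[str, str, int] | None
    n_at_least: dict[int, int] = field(default_factory=dict)


def compute_spacers(record: MitogenomeRecord) -> list[Spacer]:
    """One signed spacer per adjacent feature pair, in feature order.

    On a circular record the pair (last feature, first feature) contributes
    the origin-wrapping spacer.  Only pairwise overlaps between consecutive
    features are supported; a feature overlapping two predecessors makes
    adjacency ambiguous and raises ``ValueError``.
    """
    feats = record.features
    if not feats:
        raise ValueError("record has no features")
    for i in range(2, len(feats)):
        if feats[i].start <= feats[i - 2].end:
            raise ValueError(
                f"feature {feats[i].name} overlaps non-adjacent {feats[i - 2].name}; "
                "only pairwise overlaps between consecutive genes are supported"
            )
    spacers: list[Spacer] = []
    for up, down in zip(feats, feats[1:]):
        spacers.append(
            Spacer(
                upstream=up.name,
                downstream=down.name,
                length=down.start - up.end - 1,
                is_control_region=up.name == CONTROL_REGION_UPSTREAM,
            )
        )
    if record.circular:
        up, down = feats[-1], feats[0]
        if len(feats) == 1:
            wrap_len = record.length - up.length
        else:
            wrap_len = (record.length - up.end) + (down.start - 1)
        spacers.append(
            Spacer(
                upstream=up.name,
                downstream=down.name,
                length=wrap_len,
                wraps_origin=True,
                is_control_region=up.name == CONTROL_REGION_UPSTREAM,
            )
        )
    else:
        warnings.warn(
            f"{record.genome_id}: non-circular record, no origin-wrapping spacer",
            stacklevel=2,
        )
    return spacers


def summarize_spacers(
    spacers: list[Spacer],
    thresholds: tuple[int, ...] = (160,),
    threshold_mode: str = "ge",
) -> SpacerSummary:
    """Totals and counts over a spacer list.

    A positive non-control-region spacer counts as an IGS regardless of
    length; zero-length spacers contain no nucleotides and never count.
    ``threshold_mode`` chooses whether ``n_at_least`` counts spacers
    ``>=`` (default) or strictly ``>`` each threshold.
    """
    if threshold_mode not in ("ge", "gt"):
        raise ValueError("threshold_mode must be 'ge' or 'gt'")
    igs = [s for s in spacers if s.is_igs]
    cr_bp = sum(s.length for s in spacers if s.is_control_region and s.length > 0)
    overlaps = [s for s in spacers if s.is_overlap]
    longest = max(igs, key=lambda s: s.length, default=None)
    return SpacerSummary(
        igs_total_bp=sum(s.length for s in igs),
        igs_count=len(igs),
        igs_total_with_cr=sum(s.length for s in igs) + cr_bp,
        overlap_count=len(overlaps),
        overlap_bp=sum(-s.length for s in overlaps),
        longest=(longest.upstream, longest.downstream, longest.length) if longest else None,
        n_at_least={
            t: sum(1 for s in igs if (s.length >= t if threshold_mode == "ge" else s.length > t))
            for t in thresholds
        },
    )


def compare_genomes(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """Per-genome IGS totals, one row per record.

    Columns: ``genome_id``, ``length``, ``igs_total_bp``, ``igs_count``.
    Records lacking an srRNA annotation get no control-region exclusion
    (warned), matching how an unannotated control region would be handled.
    """
    rows = []
    for rec in records:
        if not any(f.name == CONTROL_REGION_UPSTREAM for f in rec.features):
            warnings.warn(
                f"{rec.genome_id}: no srRNA feature; control-region exclusion skipped",
                stacklevel=2,
            )
        summary = summarize_spacers(compute_spacers(rec))
        rows.append(
            {
                "genome_id": rec.genome_id,
                "length": rec.length,
                "igs_total_bp": summary.igs_total_bp,
                "igs_count": summary.igs_count,
            }
        )
    return pd.DataFrame(rows, columns=["genome_id", "length", "igs_total_bp", "igs_count"])
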