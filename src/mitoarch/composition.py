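"""Nucleotide composition, codon usage and start/stop codon calls.

All per-gene statistics are computed on the coding strand: minority-strand
(N) genes are reverse-complemented before counting.  A+T content is
strand-symmetric, so AT fractions are unaffected by this choice, but
per-base counts and codon statistics are not.

Codon statistics use the invertebrate mitochondrial genetic code
(translation table 5: ATA=Met, TGA=Trp, AGA/AGG=Ser).  Protein-coding
genes whose length is not a multiple of three carry an incomplete stop
codon — a trailing T or TA completed to TAA by post-transcriptional
polyadenylation — whose bases contribute only their present codon
positions and are excluded from codon counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio.Data import CodonTable

from .annotation_io import MitogenomeRecord
from .spacers import compute_spacers
from .vocabulary import INVERTEBRATE_MITO_CODE

__all__ = [
    "CompositionProfile",
    "CodonUsageTable",
    "region_composition",
    "codon_position_composition",
    "codon_usage",
    "extract_codons",
    "round_percent",
]

COMMON_START_CODONS = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG", "TTG"})
COMPLETE_STOPS = frozenset({"TAA", "TAG"})


def round_percent(fraction: float, ndigits: int = 1) -> float:
    """Report a fraction as a percentage, round half up (0.80849 -> 80.8)."""
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts and A+T fraction of a labelled region set.

    ``at_fraction`` = (A+T)/(A+C+G+T); N bases are excluded from the
    denominator but counted in ``length``.
    """

    region_label: str
    base_counts: dict[str, int]
    length: int

    @property
    def at_fraction(self) -> float:
        c = self.base_counts
        denom = c["A"] + c["C"] + c["G"] + c["T"]
        return (c["A"] + c["T"]) / denom if denom else math.nan

    @property
    def at_percent(self) -> float:
        """AT content in percent, one decimal, round half up."""
        return round_percent(self.at_fraction)


def _profile(label: str, *seqs: str) -> CompositionProfile:
    counts = {b: 0 for b in "ACGTN"}
    total = 0
    for seq in seqs:
        for b in seq:
            counts[b] += 1
        total += len(seq)
    return CompositionProfile(region_label=label, base_counts=counts, length=total)


def region_composition(record: MitogenomeRecord, regions: str = "genome") -> list[CompositionProfile]:
    """Composition profiles for a named region selector.

    ``regions`` is one of ``genome`` (whole J strand), ``genes`` (each gene
    on its coding strand), ``pcg`` (all protein-coding genes pooled),
    ``igs`` (all positive non-control-region spacers pooled), ``igs-mean``
    (one profile per spacer, for a mean-of-spacers summary), ``rrna``
    (each ribosomal subunit gene), or a list of gene names.
    """
    if record.sequence is None:
        raise ValueError(f"{record.genome_id}: composition requires a sequence")
    if isinstance(regions, (list, tuple)):
        return [_profile(n, record.feature_sequence(n)) for n in regions]
    if regions == "genome":
        return [_profile("genome", record.sequence)]
    if regions == "genes":
        return [_profile(f.name, record.feature_sequence(f.name)) for f in record.features]
    if regions == "pcg":
        seqs = [record.feature_sequence(f.name) for f in record.features if f.gene_class == "PCG"]
        return [_profile("PCG", *seqs)]
    if regions == "rrna":
        return [
            _profile(f.name, record.feature_sequence(f.name))
            for f in record.features
            if f.gene_class == "rRNA"
        ]
    if regions in ("igs", "igs-mean"):
        seqs = []
        for sp in compute_spacers(record):
            if not sp.is_igs:
                continue
            up = record[sp.upstream]
            # circular coordinates of the spacer: the sp.length bases after up.end
            start = up.end % record.length + 1
            end = (up.end + sp.length - 1) % record.length + 1
            label = f"{sp.upstream}-{sp.downstream}"
            seqs.append((label, record.region_sequence(start, end)))
        if regions == "igs-mean":
            return [_profile(label, s) for label, s in seqs]
        return [_profile("IGS", *(s for _, s in seqs))]
    raise ValueError(f"unknown region selector {regions!r}")


def _coding_parts(record: MitogenomeRecord, warn: bool = True) -> dict[str, tuple[str, str]]:
    """Per PCG: (full codons, trailing incomplete tail) on the coding strand."""
    parts: dict[str, tuple[str, str]] = {}
    for f in record.features:
        if f.gene_class != "PCG":
            continue
        cds = record.feature_sequence(f.name)
        tail_len = len(cds) % 3
        body, tail = (cds[:-tail_len], cds[-tail_len:]) if tail_len else (cds, "")
        if tail and warn and not f.has_incomplete_stop and not "TAA".startswith(tail):
            warnings.warn(
                f"{f.name}: length {len(cds)} not a multiple of 3 and trailing "
                f"{tail!r} is not an incomplete stop; trailing bases dropped",
                stacklevel=3,
            )
        parts[f.name] = (body, tail)
    return parts


def codon_position_composition(record: MitogenomeRecord) -> list[CompositionProfile]:
    """Pooled composition at codon positions 1/2/3 across all PCGs.

    Trailing incomplete codons contribute only the positions they contain.
    """
    buckets: list[list[str]] = [[], [], []]
    for body, tail in _coding_parts(record).values():
        for pos in range(3):
            buckets[pos].append(body[pos::3])
        if "TAA".startswith(tail):  # valid incomplete stop: T or TA
            for pos, base in enumerate(tail):
                buckets[pos].append(base)
    return [_profile(f"codon_pos{p + 1}", *buckets[p]) for p in range(3)]


@dataclass
class CodonUsageTable:
    """Codon counts pooled over protein-coding genes.

    ``counts`` maps each observed codon to its count;
    ``incomplete_codons_dropped`` is the number of trailing partial codons
    (incomplete stops) excluded from the counts.
    """

    counts: dict[str, int] = field(default_factory=dict)
    code_id: int = INVERTEBRATE_MITO_CODE
    incomplete_codons_dropped: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def amino_acid(self, codon: str) -> str:
        table = CodonTable.unambiguous_dna_by_id[self.code_id]
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    def ranked(self) -> list[tuple[str, int, str]]:
        """(codon, count, amino acid), most frequent first, ties alphabetical."""
        order = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(codon, n, self.amino_acid(codon)) for codon, n in order]


def codon_usage(record: MitogenomeRecord) -> CodonUsageTable:
    """Count codons over all PCGs on their coding strands (table 5)."""
    table = CodonUsageTable()
    for body, tail in _coding_parts(record).values():
        for i in range(0, len(body), 3):
            codon = body[i : i + 3]
            table.counts[codon] = table.counts.get(codon, 0) + 1
        if tail:
            table.incomplete_codons_dropped += 1
    return table


def extract_codons(record: MitogenomeRecord) -> dict[str, tuple[str, str, bool]]:
    """Start/stop codon per PCG: ``{gene: (start, stop, complete)}``.

    The stop is the final triplet when the coding length is a multiple of
    three and that triplet is TAA or TAG; otherwise the trailing one or two
    bases are reported as an incomplete stop (a prefix of TAA/TAG completed
    by polyadenylation).  Unusual start codons are reported with a warning.
    """
    out: dict[str, tuple[str, str, bool]] = {}
    for f in record.features:
        if f.gene_class != "PCG":
            continue
        cds = record.feature_sequence(f.name)
        start = cds[:3]
        if start not in COMMON_START_CODONS:
            warnings.warn(
                f"{f.name}: unusual start codon {start!r} (possible annotation error)",
                stacklevel=2,
            )
        tail_len = len(cds) % 3
        if tail_len == 0:
            stop = cds[-3:]
            complete = stop in COMPLETE_STOPS
            if not complete:
                warnings.warn(
                    f"{f.name}: final triplet {stop!r} is not a stop codon", stacklevel=2
                )
        else:
            stop = cds[-tail_len:]
            complete = False
            if not "TAA".startswith(stop):
                warnings.warn(
                    f"{f.name}: trailing {stop!r} is not a prefix of TAA/TAG", stacklevel=2
                )
        out[f.name] = (start, stop, complete)
    return out
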