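"""Read, validate and write circular mitogenome annotations.

Coordinates are 1-based inclusive throughout, the convention of printed
mitogenome annotation tables; features that would span the circular origin
are rejected (none occur in curated ant mitogenome tables, and excluding
them keeps the interval arithmetic elementary).

Two on-disk annotation dialects are supported:

* a tab-separated feature table (the package's own format, round-trip safe),
  with either explicit ``start``/``end``/``strand`` columns or a single
  ``position`` column in which parentheses mark minority (N) strand genes,
  e.g. ``(21-89)``;
* GenBank flat files, via Biopython, with ``complement(..)`` encoding the
  N strand and feature names normalized through the synonym table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .vocabulary import GENE_CLASS, gene_class, load_synonym_table, normalize_gene_name

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "ValidationError",
    "parse_feature_table",
    "parse_genbank",
    "write_feature_table",
    "read_fasta",
]


class ValidationError(ValueError):
    """An annotation violates the record invariants."""


_VALID_STRANDS = frozenset({"J", "N"})
_CODON_RE = re.compile(r"^[ACGT]{1,3}$")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular mitogenome.

    Parameters
    ----------
    name : str
        Canonical gene symbol (see :mod:`mitoarch.vocabulary`).
    strand : str
        ``"J"`` (majority strand) or ``"N"`` (minority strand).
    start, end : int
        1-based inclusive positions on the J strand, ``end >= start``.
    start_codon, stop_codon : str, optional
        Annotated codons for protein-coding genes.  A stop codon of length
        1 or 2 marks an incomplete stop, completed to TAA by
        post-transcriptional polyadenylation.
    """

    name: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.name not in GENE_CLASS:
            raise ValidationError(f"unknown gene symbol: {self.name!r}")
        if self.strand not in _VALID_STRANDS:
            raise ValidationError(f"strand must be 'J' or 'N', got {self.strand!r}")
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"{self.name}: end < start ({self.end} < {self.start}); "
                "origin-spanning features are not supported"
            )
        for label, codon in (("start", self.start_codon), ("stop", self.stop_codon)):
            if codon is not None and not _CODON_RE.fullmatch(codon):
                raise ValidationError(f"{self.name}: invalid {label} codon {codon!r}")
        if self.start_codon is not None and len(self.start_codon) != 3:
            raise ValidationError(f"{self.name}: start codon must be a 3-mer")

    @property
    def gene_class(self) -> str:
        return gene_class(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def has_incomplete_stop(self) -> bool:
        return self.stop_codon is not None and len(self.stop_codon) < 3


@dataclass
class MitogenomeRecord:
    """A circular (or optionally linear) annotated mitogenome.

    ``features`` is kept sorted by ascending start; each of the 37
    vocabulary symbols may appear at most once.  ``sequence``, when present,
    is the J strand, length exactly ``length``.
    """

    genome_id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise ValidationError(f"genome length must be positive, got {self.length}")
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValidationError(f"duplicate gene symbol: {f.name}")
            seen.add(f.name)
            if f.end > self.length:
                raise ValidationError(
                    f"{f.name}: end {f.end} exceeds genome length {self.length}"
                )
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            if not re.fullmatch(r"[ACGTN]*", self.sequence):
                raise ValidationError("sequence may contain only A, C, G, T, N")

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_sequence(self, name: str) -> str:
        """Coding-strand sequence of a gene (reverse complement for N)."""
        if self.sequence is None:
            raise ValidationError(f"{self.genome_id}: record carries no sequence")
        f = self[name]
        seg = self.sequence[f.start - 1 : f.end]
        return reverse_complement(seg) if f.strand == "N" else seg

    def region_sequence(self, start: int, end: int) -> str:
        """J-strand sequence of a 1-based inclusive interval (may wrap)."""
        if self.sequence is None:
            raise ValidationError(f"{self.genome_id}: record carries no sequence")
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise ValidationError(f"region {start}-{end} outside 1-{self.length}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValidationError("wrapping region on a non-circular record")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def with_sequence(self, sequence: str) -> "MitogenomeRecord":
        return MitogenomeRecord(
            genome_id=self.genome_id,
            length=self.length,
            features=list(self.features),
            circular=self.circular,
            sequence=sequence.upper(),
        )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# TSV feature-table dialect
# ---------------------------------------------------------------------------

_POSITION_RE = re.compile(r"^(\()?\s*(\d+)\s*[-–]\s*(\d+)\s*(?(1)\))$")


def _parse_position(token: str) -> tuple[str, int, int]:
    """``(21-89)`` -> (N, 21, 89); ``852-1832`` -> (J, 852, 1832)."""
    m = _POSITION_RE.match(token.strip())
    if m is None:
        raise ValidationError(f"cannot parse position {token!r}")
    strand = "N" if m.group(1) else "J"
    return strand, int(m.group(2)), int(m.group(3))


def parse_feature_table(path, synonyms: dict[str, str] | None = None) -> MitogenomeRecord:
    """Parse the tab-separated feature-table dialect.

    Leading ``#key=value`` comment lines declare ``genome_id``, ``length``
    and ``circular``; then a header row and one row per gene.  Unknown gene
    symbols are skipped with a warning; duplicate symbols, inverted
    coordinates and coordinates beyond the declared length raise
    :class:`ValidationError`.
    """
    if synonyms is None:
        synonyms = load_synonym_table()
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip().lower() for c in line.split("\t")]
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ValidationError(f"{path}: no header row found")
    if "length" not in meta:
        raise ValidationError(f"{path}: missing '#length=' metadata line")

    col = {name: i for i, name in enumerate(header)}

    def cell(row: list[str], name: str) -> str:
        i = col.get(name)
        return row[i].strip() if i is not None and i < len(row) else ""

    features: list[GeneFeature] = []
    for row in rows:
        raw_name = cell(row, "gene") or cell(row, "name")
        symbol = normalize_gene_name(raw_name, synonyms)
        if symbol is None:
            warnings.warn(f"skipping unknown gene symbol {raw_name!r}", stacklevel=2)
            continue
        if "position" in col and cell(row, "position"):
            strand, start, end = _parse_position(cell(row, "position"))
            if cell(row, "strand"):
                strand = cell(row, "strand").upper()
        else:
            strand = cell(row, "strand").upper()
            start, end = int(cell(row, "start")), int(cell(row, "end"))
        features.append(
            GeneFeature(
                name=symbol,
                strand=strand,
                start=start,
                end=end,
                start_codon=cell(row, "start_codon") or None,
                stop_codon=cell(row, "stop_codon") or None,
            )
        )
    return MitogenomeRecord(
        genome_id=meta.get("genome_id", str(path)),
        length=int(meta["length"]),
        features=features,
        circular=meta.get("circular", "true").lower() != "false",
    )


def write_feature_table(record: MitogenomeRecord, path) -> None:
    """Write the TSV dialect; ``parse_feature_table`` round-trips it exactly."""
    lines = [
        "#mitoarch feature table",
        f"#genome_id={record.genome_id}",
        f"#length={record.length}",
        f"#circular={'true' if record.circular else 'false'}",
        "gene\tgene_class\tstrand\tstart\tend\tstart_codon\tstop_codon",
    ]
    for f in record.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.gene_class,
                    f.strand,
                    str(f.start),
                    str(f.end),
                    f.start_codon or "",
                    f.stop_codon or "",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GENBANK_TYPES = ("CDS", "tRNA", "rRNA", "gene")


def parse_genbank(
    path,
    synonyms: dict[str, str] | None = None,
    with_skipped: bool = False,
):
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    Typed features (CDS/tRNA/rRNA) take precedence over their paired bare
    ``gene`` features.  Names are normalized through the synonym table;
    unmappable names are skipped with a warning (returned as a list when
    ``with_skipped`` is true).  Multi-interval ``join(..)`` locations are
    rejected.
    """
    if synonyms is None:
        synonyms = load_synonym_table()
    gb = SeqIO.read(path, "genbank")
    by_name: dict[str, tuple[int, GeneFeature]] = {}
    skipped: list[str] = []
    priority = {t: i for i, t in enumerate(_GENBANK_TYPES)}
    for feat in gb.features:
        if feat.type not in priority:
            continue
        if len(feat.location.parts) > 1:
            raise ValidationError(
                f"multi-interval (join) feature at {feat.location} is not supported"
            )
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        symbol = normalize_gene_name(raw, synonyms) if raw else None
        if symbol is None:
            skipped.append(raw or f"<unnamed {feat.type}>")
            warnings.warn(
                f"skipping unmappable {feat.type} feature {raw!r}", stacklevel=2
            )
            continue
        gf = GeneFeature(
            name=symbol,
            strand="N" if feat.location.strand == -1 else "J",
            start=int(feat.location.start) + 1,  # Biopython is 0-based half-open
            end=int(feat.location.end),
        )
        rank = priority[feat.type]
        if symbol not in by_name or rank < by_name[symbol][0]:
            by_name[symbol] = (rank, gf)
    record = MitogenomeRecord(
        genome_id=gb.id or gb.name,
        length=len(gb.seq),
        features=[gf for _, gf in by_name.values()],
        circular=gb.annotations.get("topology", "circular") == "circular",
        sequence=str(gb.seq).upper() if len(gb.seq) else None,
    )
    return (record, skipped) if with_skipped else record


def read_fasta(path) -> str:
    """Read the first sequence of a FASTA file as an uppercase string."""
    rec = next(SeqIO.parse(path, "fasta"))
    return str(rec.seq).upper()


def attach_codon_annotations(record: MitogenomeRecord) -> MitogenomeRecord:
    """Fill ``start_codon``/``stop_codon`` on PCG features from the sequence."""
    from .composition import extract_codons  # local import: avoid cycle

    codons = extract_codons(record)
    feats = []
    for f in record.features:
        if f.name in codons:
            start, stop, _complete = codons[f.name]
            feats.append(replace(f, start_codon=start, stop_codon=stop))
        else:
            feats.append(f)
    return MitogenomeRecord(
        genome_id=record.genome_id,
        length=record.length,
        features=feats,
        circular=record.circular,
        sequence=record.sequence,
    )
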