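"""Synthetic annotated mitogenomes with known ground truth.

The generator lays the genes of a circular order onto a J-strand sequence,
junction by junction: positive spacers become AT-biased non-coding runs,
negative spacers (allowed only between tRNA genes, mirroring real ant
mitogenomes where overlaps occur only between tRNAs) slide the downstream
gene into the upstream one, and the origin-wrapping junction after the
last gene is the AT-rich control region.  Protein-coding genes are built
codon-wise — a start codon from {ATG, ATA, ATT}, an i.i.d. AT-weighted
body with per-codon-position weights, and a TAA/TAG stop or a
policy-chosen incomplete stop (trailing T or TA) — so every analysis
statistic has an exactly known or tightly bounded expectation.

Composition is modelled i.i.d. per base from region-specific AT weights;
real mitogenomes have codon-level selection, strand-asymmetric skews and
repeats that this deliberately does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotation_io import GeneFeature, MitogenomeRecord, reverse_complement
from .rearrangement import GeneOrder, ancestral_pancrustacean_order
from .vocabulary import gene_class

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_mitogenome", "mutate_order", "atta_like_spec"]

#: Default gene lengths (bp), realistic for an ant mitogenome.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 981, "COI": 1533, "COII": 684, "ATP8": 184, "ATP6": 666,
    "COIII": 792, "ND3": 354, "ND5": 1665, "ND4": 1347, "ND4L": 276,
    "ND6": 561, "Cytb": 1119, "ND1": 948,
    "lrRNA": 1426, "srRNA": 795,
}
DEFAULT_TRNA_LENGTH = 70

#: Default AT probabilities per region class.
DEFAULT_AT_WEIGHTS: dict[str, float] = {
    "pcg_pos1": 0.763,
    "pcg_pos2": 0.736,
    "pcg_pos3": 0.864,
    "trna": 0.85,
    "rrna": 0.84,
    "igs": 0.861,
    "control": 0.90,
}

START_CODONS = ("ATA", "ATG", "ATT")
COMPLETE_STOPS = ("TAA", "TAG")


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic mitogenome.

    ``spacer_lengths`` gives the signed gap after each gene of
    ``gene_order`` except the last; the junction after the last gene wraps
    the origin and is the control region of ``control_region_length`` bp.
    When ``spacer_lengths`` is None, lengths are drawn per junction from
    ``spacer_sampler`` (default: geometric-ish mix of short gaps).
    ``stop_codon_policy`` is the fraction of PCGs given an incomplete stop
    when ``incomplete_stop_genes`` is not set explicitly.
    """

    gene_order: GeneOrder = field(default_factory=ancestral_pancrustacean_order)
    gene_lengths: Mapping[str, int] | None = None
    spacer_lengths: Sequence[int] | None = None
    spacer_sampler: Callable[[np.random.Generator], int] | None = None
    control_region_length: int = 300
    at_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AT_WEIGHTS))
    incomplete_stop_genes: tuple[str, ...] | None = None
    stop_codon_policy: float = 0.0
    seed: int = 0
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        for key, w in self.at_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"AT weight {key}={w} outside [0, 1]")
        self.at_weights = {**DEFAULT_AT_WEIGHTS, **dict(self.at_weights)}
        if not 0.0 <= self.stop_codon_policy <= 1.0:
            raise ValueError("stop_codon_policy must be a fraction in [0, 1]")
        if self.control_region_length < 0:
            raise ValueError("control_region_length must be non-negative")

    def resolved_gene_lengths(self) -> dict[str, int]:
        out = {}
        for name, _ in self.gene_order.genes:
            if self.gene_lengths and name in self.gene_lengths:
                out[name] = self.gene_lengths[name]
            elif name in DEFAULT_GENE_LENGTHS:
                out[name] = DEFAULT_GENE_LENGTHS[name]
            else:
                out[name] = DEFAULT_TRNA_LENGTH
        return out


@dataclass
class SyntheticTruth:
    """Ground truth realized by the generator."""

    record: MitogenomeRecord
    gene_order: GeneOrder
    spacer_lengths: dict[tuple[str, str], int]  # includes the control-region junction
    control_region_length: int
    codon_counts: dict[str, int]
    incomplete_stop_genes: tuple[str, ...]
    at_weights: dict[str, float]
    region_at_counts: dict[str, tuple[int, int]]  # class -> (A+T bases, total bases)
    applied_moves: tuple = ()


def _default_sampler(rng: np.random.Generator) -> int:
    # short spacers with an occasional long one; never negative
    return int(rng.geometric(0.02)) - 1 if rng.random() < 0.8 else 0


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    if n == 0:
        return ""
    p = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return "".join(rng.choice(np.array(list("ATCG")), size=n, p=p))


def _pcg_sequence(
    rng: np.random.Generator, length: int, incomplete: bool, weights: Mapping[str, float]
) -> tuple[str, str]:
    """Coding-strand CDS of ``length`` bp; returns (sequence, stop)."""
    if incomplete:
        tail = {1: "T", 2: "TA", 0: None}[length % 3]
        if tail is None:
            raise ValueError(
                f"PCG length {length} is a multiple of 3; an incomplete stop needs "
                "length = 3k+1 (stop T) or 3k+2 (stop TA)"
            )
        stop = tail
    else:
        if length % 3:
            raise ValueError(f"PCG length {length} not a multiple of 3 for a complete stop")
        stop = str(rng.choice(COMPLETE_STOPS))
    body_len = length - 3 - len(stop)
    if body_len < 0 or body_len % 3:
        raise ValueError(f"infeasible PCG length {length}")
    ncod = body_len // 3
    cols = [
        _random_bases(rng, ncod, weights["pcg_pos1"]),
        _random_bases(rng, ncod, weights["pcg_pos2"]),
        _random_bases(rng, ncod, weights["pcg_pos3"]),
    ]
    body = "".join(a + b + c for a, b, c in zip(*cols)) if ncod else ""
    start = str(rng.choice(START_CODONS))
    return start + body + stop, stop


def generate_mitogenome(spec: SyntheticSpec) -> tuple[MitogenomeRecord, SyntheticTruth]:
    """Realize a spec into an annotated, sequenced circular record.

    Deterministic given ``spec.seed``: identical specs produce
    byte-identical sequences and feature tables.
    """
    rng = np.random.default_rng(spec.seed)
    order = spec.gene_order.genes
    n = len(order)
    lengths = spec.resolved_gene_lengths()

    if spec.spacer_lengths is not None:
        if len(spec.spacer_lengths) != n - 1:
            raise ValueError(
                f"spacer_lengths must have {n - 1} entries (one per junction "
                f"between consecutive genes), got {len(spec.spacer_lengths)}"
            )
        spacers = [int(s) for s in spec.spacer_lengths]
    else:
        sampler = spec.spacer_sampler or _default_sampler
        spacers = [int(sampler(rng)) for _ in range(n - 1)]

    # which PCGs get incomplete stops
    pcgs = [g for g, _ in order if gene_class(g) == "PCG"]
    if spec.incomplete_stop_genes is not None:
        incomplete = set(spec.incomplete_stop_genes)
    else:
        incomplete = {g for g in pcgs if rng.random() < spec.stop_codon_policy}
    # a PCG length that is not a multiple of 3 implies an incomplete stop
    incomplete |= {g for g in pcgs if lengths[g] % 3}

    # feasibility: overlaps only between tRNAs, never deeper than a neighbor
    for i, s in enumerate(spacers):
        up, down = order[i][0], order[i + 1][0]
        if s < 0:
            if gene_class(up) != "tRNA" or gene_class(down) != "tRNA":
                raise ValueError(
                    f"negative spacer at {up}-{down}: overlaps are only generated "
                    "between tRNA genes"
                )
            if -s >= min(lengths[up], lengths[down]):
                raise ValueError(
                    f"overlap {-s} bp at {up}-{down} exceeds a neighboring gene"
                )

    genome_length = sum(lengths[g] for g, _ in order) + sum(spacers) + spec.control_region_length
    seq: list[str | None] = [None] * genome_length
    at_counts: dict[str, list[int]] = {k: [0, 0] for k in DEFAULT_AT_WEIGHTS}

    def tally(cls: str, bases: str) -> None:
        at_counts[cls][0] += sum(1 for b in bases if b in "AT")
        at_counts[cls][1] += len(bases)

    def write(start: int, bases: str) -> None:  # 1-based start
        for k, b in enumerate(bases):
            seq[start - 1 + k] = b

    features: list[GeneFeature] = []
    codon_counts: dict[str, int] = {}
    truth_spacers: dict[tuple[str, str], int] = {}
    pos = 1  # start of the next gene
    prev_end = 0
    for i, (name, strand) in enumerate(order):
        glen = lengths[name]
        start = pos
        end = start + glen - 1
        cls = gene_class(name)
        if cls == "PCG":
            cds, stop = _pcg_sequence(rng, glen, name in incomplete, spec.at_weights)
            body = cds[3 : len(cds) - len(stop)]
            for p in range(3):
                tally(f"pcg_pos{p + 1}", body[p::3])
            for j in range(0, len(cds) - len(cds) % 3, 3):
                codon = cds[j : j + 3]
                codon_counts[codon] = codon_counts.get(codon, 0) + 1
            write(start, cds if strand == "J" else reverse_complement(cds))
            features.append(
                GeneFeature(name=name, strand=strand, start=start, end=end,
                            start_codon=cds[:3], stop_codon=stop)
            )
        else:
            weight = spec.at_weights["trna" if cls == "tRNA" else "rrna"]
            fresh_from = max(start, prev_end + 1)  # overlap prefix is already written
            bases = _random_bases(rng, end - fresh_from + 1, weight)
            tally("trna" if cls == "tRNA" else "rrna", bases)
            write(fresh_from, bases)
            features.append(GeneFeature(name=name, strand=strand, start=start, end=end))
        prev_end = end
        if i < n - 1:
            gap = spacers[i]
            truth_spacers[(name, order[i + 1][0])] = gap
            if gap > 0:
                igs = _random_bases(rng, gap, spec.at_weights["igs"])
                tally("igs", igs)
                write(end + 1, igs)
            pos = end + gap + 1
    # control region: from the last gene's end to the origin
    cr = _random_bases(rng, spec.control_region_length, spec.at_weights["control"])
    tally("control", cr)
    write(prev_end + 1, cr)
    truth_spacers[(order[-1][0], order[0][0])] = spec.control_region_length

    assert all(b is not None for b in seq), "generator left unwritten positions"
    record = MitogenomeRecord(
        genome_id=spec.genome_id,
        length=genome_length,
        features=features,
        circular=True,
        sequence="".join(seq),  # type: ignore[arg-type]
    )
    truth = SyntheticTruth(
        record=record,
        gene_order=spec.gene_order,
        spacer_lengths=truth_spacers,
        control_region_length=spec.control_region_length,
        codon_counts=codon_counts,
        incomplete_stop_genes=tuple(sorted(incomplete)),
        at_weights=dict(spec.at_weights),
        region_at_counts={k: (v[0], v[1]) for k, v in at_counts.items()},
    )
    return record, truth


def mutate_order(
    order: GeneOrder, moves: Sequence[tuple[str, int | str, bool]]
) -> GeneOrder:
    """Apply single-gene moves to a circular order.

    Each move is ``(gene, new_position, flip)``: the gene is removed and
    reinserted either immediately after the gene named by ``new_position``
    (string form) or at integer index ``new_position`` of the list after
    removal; ``flip`` inverts its strand.  Moves apply sequentially; moving
    the same gene twice in one call is an error.
    """
    moved = [m[0] for m in moves]
    if len(set(moved)) != len(moved):
        dupes = sorted({g for g in moved if moved.count(g) > 1})
        raise ValueError(f"gene(s) moved twice in one call: {dupes}")
    genes = list(order.genes)
    for name, target, flip in moves:
        idx = next((i for i, (g, _) in enumerate(genes) if g == name), None)
        if idx is None:
            raise ValueError(f"gene {name!r} not in order")
        gene, strand = genes.pop(idx)
        if flip:
            strand = "N" if strand == "J" else "J"
        if isinstance(target, str):
            after = next((i for i, (g, _) in enumerate(genes) if g == target), None)
            if after is None:
                raise ValueError(f"anchor gene {target!r} not in order")
            genes.insert(after + 1, (gene, strand))
        else:
            genes.insert(target % (len(genes) + 1), (gene, strand))
    return GeneOrder(tuple(genes))


def atta_like_spec(seed: int = 0) -> SyntheticSpec:
    """Spec reproducing the published *A. laevigata* architecture.

    Gene order, gene lengths and signed junction lengths are taken from the
    bundled KC346251 annotation (37 genes, 30 positive spacers, three
    tRNA-tRNA overlaps, 74 bp post-srRNA control-region remainder, 18,729
    bp total), with ATP8 ending in the incomplete stop T.
    """
    from .datasets import atta_laevigata
    from .rearrangement import order_from_record
    from .spacers import compute_spacers

    rec = atta_laevigata()
    order = order_from_record(rec)
    by_junction = {(s.upstream, s.downstream): s.length for s in compute_spacers(rec)}
    genes = order.genes
    spacer_lengths = [by_junction[(genes[i][0], genes[i + 1][0])] for i in range(len(genes) - 1)]
    cr = by_junction[(genes[-1][0], genes[0][0])]
    return SyntheticSpec(
        gene_order=order,
        gene_lengths={f.name: f.length for f in rec.features},
        spacer_lengths=spacer_lengths,
        control_region_length=cr,
        incomplete_stop_genes=("ATP8",),
        seed=seed,
        genome_id=f"synthetic_atta_like_seed{seed}",
    )
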