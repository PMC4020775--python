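"""Gene-order comparison against a reference arrangement.

The distance model is the minimal number of single-gene moves (a
translocation, optionally with an inversion, i.e. a strand flip) turning
one circular signed gene order into another.  Every tRNA rearrangement
discussed for ant mitogenomes is of this form, including a three-gene
local permutation like I-Q-M -> M-I-Q, which is one move of trnM.

The distance equals n minus the size of the largest common circular
subsequence of (symbol, strand) pairs; because gene symbols are unique,
that subsequence can be found by maximizing an ordinary LCS over all
rotations of the query against a fixed linearization of the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

from .annotation_io import MitogenomeRecord
from .spacers import compute_spacers
from .vocabulary import gene_class

__all__ = [
    "GeneOrder",
    "RearrangementReport",
    "ancestral_pancrustacean_order",
    "order_from_record",
    "move_distance",
]

SignedGene = tuple[str, str]  # (symbol, strand)


@dataclass(frozen=True)
class GeneOrder:
    """A circular, signed gene arrangement.

    Two orders are equal when one is a rotation of the other; reflections
    are distinct (reading direction is fixed by the majority strand).
    """

    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        symbols = [g for g, _ in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("gene symbols must be unique in a GeneOrder")
        for _, strand in self.genes:
            if strand not in ("J", "N"):
                raise ValueError(f"strand must be 'J' or 'N', got {strand!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def symbols(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def strand_of(self, symbol: str) -> str:
        for g, s in self.genes:
            if g == symbol:
                return s
        raise KeyError(symbol)

    def rotated(self, offset: int) -> "GeneOrder":
        n = len(self.genes)
        offset %= n
        return GeneOrder(self.genes[offset:] + self.genes[:offset])

    def start_at(self, symbol: str) -> "GeneOrder":
        for i, (g, _) in enumerate(self.genes):
            if g == symbol:
                return self.rotated(i)
        raise KeyError(symbol)

    def canonical(self) -> tuple[SignedGene, ...]:
        """Lexicographically smallest rotation (rotation-invariant key)."""
        n = len(self.genes)
        return min((self.genes[i:] + self.genes[:i]) for i in range(n))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


@dataclass
class RearrangementReport:
    """Minimal single-gene-move edit between two circular orders."""

    event_count: int
    moved_genes: dict[str, str]  # symbol -> "translocation" | "translocation+inversion"
    alignment: tuple[SignedGene, ...]  # retained common circular subsequence


#: The hypothesized ancestral pancrustacean arrangement of the 37
#: mitochondrial genes, linearized at the gene following the control
#: region.  N-strand genes carry strand "N".
_ANCESTRAL: tuple[SignedGene, ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("ND2", "J"), ("trnW", "J"),
    ("trnC", "N"), ("trnY", "N"), ("COI", "J"), ("trnL2", "J"), ("COII", "J"),
    ("trnK", "J"), ("trnD", "J"), ("ATP8", "J"), ("ATP6", "J"), ("COIII", "J"),
    ("trnG", "J"), ("ND3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("ND5", "N"), ("trnH", "N"),
    ("ND4", "N"), ("ND4L", "N"), ("trnT", "J"), ("trnP", "N"), ("ND6", "J"),
    ("Cytb", "J"), ("trnS2", "J"), ("ND1", "N"), ("trnL1", "N"), ("lrRNA", "N"),
    ("trnV", "N"), ("srRNA", "N"),
)


def ancestral_pancrustacean_order() -> GeneOrder:
    """The ancestral pancrustacean gene order (37 genes), the standard
    reference arrangement for arthropod mitogenome comparisons."""
    return GeneOrder(_ANCESTRAL)


def order_from_record(record: MitogenomeRecord) -> GeneOrder:
    """Circular gene order of a record, linearized after the control region.

    Genes are listed clockwise by ascending start (overlapping genes by
    start) beginning at the gene downstream of the control-region spacer
    (the one following srRNA); without an srRNA annotation the rotation is
    left at the first annotated feature.
    """
    genes = tuple((f.name, f.strand) for f in record.features)
    order = GeneOrder(genes)
    if record.circular and any(f.name == "srRNA" for f in record.features):
        cr = next(s for s in compute_spacers(record) if s.is_control_region)
        order = order.start_at(cr.downstream)
    return order


def _lcs_keep(a: tuple[SignedGene, ...], b: tuple[SignedGene, ...]) -> list[SignedGene]:
    """One longest common subsequence of two signed gene sequences."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            row[j] = 1 + nxt[j + 1] if a[i] == b[j] else max(nxt[j], row[j + 1])
    keep: list[SignedGene] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            keep.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def _circularly_equal(a: list[SignedGene], b: list[SignedGene]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    doubled = b + b
    return any(doubled[i : i + len(a)] == a for i in range(len(b)))


_ENUMERATION_LIMIT = 200_000


def move_distance(query: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Minimal single-gene moves from ``reference`` to ``query``.

    ``event_count`` is n minus the largest common circular subsequence of
    (symbol, strand) pairs.  Among the minimal moved sets, ties are broken
    by preferring the set moving fewest non-tRNA genes (tRNA translocations
    are by far the commonest mitogenome rearrangement, so a solution that
    moves a tRNA is preferred over one moving an rRNA or PCG), then the
    lexicographically smallest set of symbols.  A moved gene whose strand
    differs between the two orders is annotated ``translocation+inversion``.
    """
    if query.symbols() != reference.symbols():
        diff = sorted(query.symbols() ^ reference.symbols())
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    n = len(query)
    ref = reference.genes
    best = 0
    best_keep: list[SignedGene] = []
    for offset in range(n):
        rot = query.rotated(offset).genes
        keep = _lcs_keep(rot, ref)
        if len(keep) > best:
            best = len(keep)
            best_keep = keep
    d = n - best
    moved = _select_moved_set(query, reference, d, fallback_keep=best_keep)
    annotations = {
        g: (
            "translocation+inversion"
            if query.strand_of(g) != reference.strand_of(g)
            else "translocation"
        )
        for g in moved
    }
    alignment = tuple(g for g in ref if g[0] not in moved)
    return RearrangementReport(event_count=d, moved_genes=annotations, alignment=alignment)


def _select_moved_set(
    query: GeneOrder, reference: GeneOrder, d: int, fallback_keep: list[SignedGene]
) -> set[str]:
    if d == 0:
        return set()
    symbols = sorted(query.symbols())
    if comb(len(symbols), d) <= _ENUMERATION_LIMIT:
        q, r = query.genes, reference.genes
        candidates = []
        for combo in combinations(symbols, d):
            removed = set(combo)
            qk = [g for g in q if g[0] not in removed]
            rk = [g for g in r if g[0] not in removed]
            if _circularly_equal(qk, rk):
                candidates.append(combo)
        if candidates:
            n_non_trna = lambda c: sum(1 for g in c if gene_class(g) != "tRNA")
            return set(min(candidates, key=lambda c: (n_non_trna(c), c)))
    kept = {g for g, _ in fallback_keep}
    return {g for g in query.symbols() if g not in kept}
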