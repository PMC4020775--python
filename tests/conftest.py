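"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import pytest

from mitoarch import GeneFeature, MitogenomeRecord, atta_laevigata
from mitoarch.rearrangement import GeneOrder


@pytest.fixture(scope="session")
def atta() -> MitogenomeRecord:
    """The bundled A. laevigata annotation (no sequence)."""
    return atta_laevigata()


def make_record(genes, length, genome_id="test", sequence=None, circular=True):
    """Build a record from (name, strand, start, end) tuples."""
    feats = [GeneFeature(name=n, strand=s, start=a, end=b) for n, s, a, b in genes]
    return MitogenomeRecord(
        genome_id=genome_id, length=length, features=feats,
        circular=circular, sequence=sequence,
    )


def coverage_runs(record) -> tuple[Counter, Counter]:
    """Independent per-position oracle for spacers and overlaps.

    Marks how many features cover every position of the circle and returns
    the multisets of maximal uncovered-run lengths (positive spacers) and
    maximal >=2-covered-run lengths (overlap magnitudes).
    """
    cov = [0] * record.length
    for f in record.features:
        for p in range(f.start - 1, f.end):
            cov[p] += 1

    def run_lengths(predicate):
        flags = [predicate(c) for c in cov]
        if all(flags):
            return Counter([record.length])
        # rotate so the circle starts on a False position, then scan runs
        start = flags.index(False)
        rotated = flags[start:] + flags[:start]
        runs, current = [], 0
        for f in rotated:
            if f:
                current += 1
            elif current:
                runs.append(current)
                current = 0
        if current:
            runs.append(current)
        return Counter(runs)

    return run_lengths(lambda c: c == 0), run_lengths(lambda c: c >= 2)


# ---------------------------------------------------------------------------
# brute-force single-gene-move distance (BFS over the full order space)
# ---------------------------------------------------------------------------


def bfs_move_neighbors(genes: tuple) -> set[tuple]:
    """All orders one move away: remove a gene, reinsert anywhere, optional flip."""
    out = set()
    n = len(genes)
    for i in range(n):
        gene, strand = genes[i]
        rest = genes[:i] + genes[i + 1 :]
        for flip in (strand, "N" if strand == "J" else "J"):
            for j in range(len(rest) + 1):
                out.add(
                    GeneOrder(rest[:j] + ((gene, flip),) + rest[j:]).canonical()
                )
    return out


def bfs_distances_from(reference: GeneOrder, max_depth: int | None = None) -> dict:
    """BFS distance from the reference to every reachable canonical order."""
    start = reference.canonical()
    dist = {start: 0}
    frontier = [start]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        depth += 1
        nxt = []
        for state in frontier:
            for nb in bfs_move_neighbors(state):
                if nb not in dist:
                    dist[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return dist
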