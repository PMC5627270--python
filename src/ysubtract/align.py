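"""Seeded ungapped local nucleotide alignment.

The transcript-vs-genome comparisons in the filter cascade (female-genome
subtraction, repeat screening) need BLAT-like local hits with a simple
match-minus-mismatch score. Because paralog divergence in this setting is
dominated by point substitutions, an ungapped seeded aligner is sufficient
and keeps every score exactly on the matches − mismatches scale the filter
thresholds are defined on.

Algorithm: exact k-mer seeds define (target, strand, diagonal) triples; on
each seeded diagonal the best-scoring ungapped segment is found by a
maximum-subarray scan (+1 match, −1 mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import revcomp


@dataclass(frozen=True)
class LocalHit:
    """Best ungapped local alignment of a query against one target."""

    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    score: int
    matches: int
    mismatches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0

    def query_coverage(self, query_len: int) -> float:
        return self.length / query_len


class SeedIndex:
    """Exact k-mer position index over a set of target sequences."""

    def __init__(self, targets: dict[str, str], k: int = 16):
        self.k = k
        self.targets = targets
        index: dict[str, list[tuple[str, int]]] = {}
        for tid in sorted(targets):
            seq = targets[tid]
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((tid, i))
        self._index = index

    def seed_diagonals(self, query: str) -> set[tuple[str, int]]:
        """(target_id, diagonal) pairs sharing at least one exact k-mer."""
        k = self.k
        diags: set[tuple[str, int]] = set()
        for qpos in range(len(query) - k + 1):
            for tid, tpos in self._index.get(query[qpos : qpos + k], ()):
                diags.add((tid, tpos - qpos))
        return diags


def _best_segment_on_diagonal(
    query: str, target: str, diag: int
) -> tuple[int, int, int, int, int] | None:
    """Maximum-scoring ungapped segment (+1/−1) on one diagonal.

    Returns (score, q_start, q_end, matches, mismatches) or None.
    """
    # overlap of query[q] vs target[q + diag]
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(target) - diag)
    if q_hi <= q_lo:
        return None
    best = None  # (score, qs, qe, matches, mismatches)
    run_score = 0
    run_start = q_lo
    run_mm = 0
    for q in range(q_lo, q_hi):
        step = 1 if query[q] == target[q + diag] else -1
        if run_score <= 0:
            run_score, run_start, run_mm = 0, q, 0
        run_score += step
        if step < 0:
            run_mm += 1
        if run_score > 0 and (best is None or run_score > best[0]):
            length = q + 1 - run_start
            best = (run_score, run_start, q + 1, length - run_mm, run_mm)
    return best


def best_local_hit(
    query: str, index: SeedIndex, min_score: int = 1
) -> LocalHit | None:
    """Best ungapped local hit of the query (either strand) in the index.

    Ties broken by longer alignment, then lexicographic target id, then
    leftmost target position, then forward strand first.
    """
    best: LocalHit | None = None
    best_key = None
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        for tid, diag in sorted(index.seed_diagonals(q)):
            seg = _best_segment_on_diagonal(q, index.targets[tid], diag)
            if seg is None:
                continue
            score, qs, qe, matches, mm = seg
            if score < min_score:
                continue
            ts, te = qs + diag, qe + diag
            if strand == "-":
                qs, qe = len(query) - qe, len(query) - qs
            hit = LocalHit(tid, qs, qe, ts, te, strand, score, matches, mm)
            key = (-hit.score, -hit.length, hit.target_id, hit.t_start, hit.strand != "+")
            if best is None or key < best_key:
                best, best_key = hit, key
    return best


def all_local_hits(
    query: str, index: SeedIndex, min_score: int
) -> list[LocalHit]:
    """All distinct seeded diagonal hits with score ≥ min_score (either strand)."""
    hits: list[LocalHit] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        for tid, diag in sorted(index.seed_diagonals(q)):
            seg = _best_segment_on_diagonal(q, index.targets[tid], diag)
            if seg is None or seg[0] < min_score:
                continue
            score, qs, qe, matches, mm = seg
            ts, te = qs + diag, qe + diag
            if strand == "-":
                qs, qe = len(query) - qe, len(query) - qs
            hits.append(LocalHit(tid, qs, qe, ts, te, strand, score, matches, mm))
    return hits
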