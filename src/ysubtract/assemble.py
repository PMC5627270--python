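"""Greedy de Bruijn transcript assembly and overlap-based merging.

The assembler builds contigs as maximal non-branching paths over solid
k-mers (canonical count ≥ min_count, which drops singleton sequencing-error
k-mers). Both orientations of every solid k-mer enter the graph so the
walk is strand-symmetric; mirror-image unitigs are collapsed afterwards
and each contig is reported on the strand carrying its longest ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .seqio import Read, longest_orf, revcomp


@dataclass
class TranscriptRecord:
    """A candidate transcript with its per-stage filter audit trail."""

    id: str
    sequence: str
    audit: dict[str, tuple[bool, float | str | None]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def record_stage(self, stage: str, passed: bool, metric=None) -> None:
        self.audit[stage] = (passed, metric)


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def count_canonical_kmers(seqs: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            km = canonical(km)
            counts[km] = counts.get(km, 0) + 1
    return counts


@dataclass
class _Unitig:
    seq: str
    kmers: list[str]
    start: str  # first (k-1)-mer node
    end: str  # last (k-1)-mer node
    mean_count: float = 0.0


def _graph(kmers: set[str]) -> tuple[dict[str, list[str]], dict[str, int]]:
    out_edges: dict[str, list[str]] = {}
    in_deg: dict[str, int] = {}
    for km in kmers:
        u, v = km[:-1], km[1:]
        out_edges.setdefault(u, []).append(v)
        in_deg[v] = in_deg.get(v, 0) + 1
        in_deg.setdefault(u, in_deg.get(u, 0))
        out_edges.setdefault(v, [])
    for node in out_edges:
        out_edges[node].sort()
    return out_edges, in_deg


def _build_unitigs(kmers: set[str], counts: dict[str, int] | None = None) -> list[_Unitig]:
    """Maximal non-branching paths (and isolated cycles) over a k-mer set."""
    out_edges, in_deg = _graph(kmers)

    def is_junction(node: str) -> bool:
        return len(out_edges[node]) != 1 or in_deg.get(node, 0) != 1

    def finish(path: list[str], used_kms: list[str]) -> _Unitig:
        seq = path[0] + "".join(p[-1] for p in path[1:])
        mean = 0.0
        if counts is not None and used_kms:
            mean = sum(counts.get(canonical(km), 0) for km in used_kms) / len(used_kms)
        return _Unitig(seq, used_kms, path[0], path[-1], mean)

    used: set[str] = set()
    unitigs: list[_Unitig] = []
    for start in sorted(out_edges):
        if not is_junction(start):
            continue
        for nxt in out_edges[start]:
            edge = start + nxt[-1]
            if edge in used:
                continue
            used.add(edge)
            path, kms = [start, nxt], [edge]
            node = nxt
            while not is_junction(node):
                node2 = out_edges[node][0]
                edge = node + node2[-1]
                if edge in used:
                    break
                used.add(edge)
                path.append(node2)
                kms.append(edge)
                node = node2
            unitigs.append(finish(path, kms))
    # isolated cycles: every node has in=out=1
    for km in sorted(kmers):
        if km in used:
            continue
        used.add(km)
        path, kms = [km[:-1], km[1:]], [km]
        node = km[1:]
        while True:
            node2 = out_edges[node][0]
            edge = node + node2[-1]
            if edge in used:
                break
            used.add(edge)
            path.append(node2)
            kms.append(edge)
            node = node2
        unitigs.append(finish(path, kms))
    return unitigs


def _unitigs_from_kmers(kmers: set[str], k: int) -> list[str]:
    return [u.seq for u in _build_unitigs(kmers)]


def _clean_graph(
    solid: set[str], k: int, counts: dict[str, int], rounds: int = 3
) -> set[str]:
    """Pop bubbles and clip low-coverage tips from the k-mer graph.

    Sequencing errors shared by two reads survive the solidity threshold
    and create short parallel paths (bubbles) or dead-end stubs (tips)
    next to a much better-covered true path; both would break a
    transcript into fragments. A bubble is a unitig sharing both junction
    nodes with a better-covered sibling; a tip is a dead-end unitig
    shorter than 2k whose coverage is far below its junction siblings.
    Clean data has neither, so the cleanup is a no-op there.
    """
    for _ in range(rounds):
        unitigs = _build_unitigs(solid, counts)
        out_edges, in_deg = _graph(solid)
        drop: set[str] = set()

        # fork-edge plucking: at a branch, an edge supported far worse than
        # its strongest sibling is an error variant; removing it reduces
        # interleaved (overlapping) bubbles to tips. The reverse-complement
        # mirror handles in-forks by symmetry.
        for node, succs in out_edges.items():
            if len(succs) < 2:
                continue
            edge_counts = {s: counts.get(canonical(node + s[-1]), 0) for s in succs}
            cmax = max(edge_counts.values())
            for s, c in edge_counts.items():
                if c < 0.2 * cmax:
                    drop.add(canonical(node + s[-1]))

        by_span: dict[tuple[str, str], list[_Unitig]] = {}
        for u in unitigs:
            by_span.setdefault((u.start, u.end), []).append(u)
        for group in by_span.values():
            if len(group) > 1:
                group.sort(key=lambda u: (-u.mean_count, u.seq))
                for u in group[1:]:
                    drop.update(canonical(km) for km in u.kmers)

        incident: dict[str, list[_Unitig]] = {}
        for u in unitigs:
            incident.setdefault(u.start, []).append(u)
            incident.setdefault(u.end, []).append(u)
        for u in unitigs:
            if len(u.seq) >= 2 * k:
                continue
            dead_start = in_deg.get(u.start, 0) == 0 and len(out_edges[u.start]) <= 1
            dead_end = len(out_edges[u.end]) == 0 and in_deg.get(u.end, 0) <= 1
            if dead_start == dead_end:  # attached both sides, or fully isolated
                continue
            junction = u.end if dead_start else u.start
            siblings = [v for v in incident[junction] if v.seq != u.seq]
            if siblings and u.mean_count < 0.3 * max(v.mean_count for v in siblings):
                drop.update(canonical(km) for km in u.kmers)

        if not drop:
            break
        solid = {km for km in solid if canonical(km) not in drop}
    return solid


def orient_by_orf(seq: str) -> str:
    """Canonical reporting strand: the one with the longest ORF (ties: lexicographic)."""
    rc = revcomp(seq)
    orf_f = longest_orf(seq, both_strands=False)
    orf_r = longest_orf(rc, both_strands=False)
    len_f = orf_f.aa_len if orf_f else -1
    len_r = orf_r.aa_len if orf_r else -1
    if len_f != len_r:
        return seq if len_f > len_r else rc
    return min(seq, rc)


def assemble_transcripts(
    reads: Iterable[Read | str],
    k: int = 25,
    min_count: int = 2,
    min_len: int = 100,
) -> list[TranscriptRecord]:
    """Assemble contigs from reads via a greedy de Bruijn traversal.

    ``k`` must be odd and in [15, 31] (odd k avoids palindromic k-mers,
    which would make the canonical count ambiguous).
    """
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError(f"k must be odd and in [15, 31], got {k}")
    seqs = [r.seq if isinstance(r, Read) else r for r in reads]
    counts = count_canonical_kmers(seqs, k)
    solid: set[str] = set()
    for km, c in counts.items():
        if c >= min_count:
            solid.add(km)
            solid.add(revcomp(km))
    solid = _clean_graph(solid, k, counts)
    raw = _unitigs_from_kmers(solid, k)
    # collapse mirror-image unitigs, keep longest first for stable ids
    seen: set[str] = set()
    contigs: list[str] = []
    for seq in sorted(raw, key=lambda s: (-len(s), s)):
        if len(seq) < min_len:
            continue
        can = canonical(seq)
        if can in seen:
            continue
        seen.add(can)
        contigs.append(orient_by_orf(seq))
    records = []
    for i, seq in enumerate(contigs):
        rec = TranscriptRecord(f"contig_{i + 1:05d}", seq, provenance=[f"contig_{i + 1:05d}"])
        rec.record_stage("step2_assembly", True, len(seq))
        records.append(rec)
    return records


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int | None:
    """Longest suffix(a)/prefix(b) overlap ≥ min_overlap at ≥ min_identity."""
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for ell in range(min(len(a), len(b)), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a_arr[-ell:] != b_arr[:ell]))
        if mm <= (1.0 - min_identity) * ell:
            return ell
    return None


def merge_transcripts(
    records: list[TranscriptRecord],
    min_overlap: int = 30,
    min_identity: float = 0.95,
    proteome: dict[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Greedy agglomeration of overlapping fragments (either strand).

    Pairs whose suffix/prefix overlap is ≥ ``min_overlap`` bp at
    ≥ ``min_identity`` are joined, longest overlap first, until no pair
    qualifies; exact duplicates and exact substrings collapse first. When
    a proteome is supplied, fragments hitting the same protein in
    compatible order are additionally joined with an N-gap (scaffolding by
    translational mapping, simplified).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be ≥ 1")
    # orient deterministically, drop exact duplicates / contained copies
    work: list[TranscriptRecord] = []
    for rec in sorted(records, key=lambda r: (-r.length, r.id)):
        seq = orient_by_orf(rec.sequence)
        rc = revcomp(seq)
        container = next((w for w in work if seq in w.sequence or rc in w.sequence), None)
        if container is not None:
            container.provenance = sorted(set(container.provenance) | set(rec.provenance))
            continue
        work.append(TranscriptRecord(rec.id, seq, dict(rec.audit), list(rec.provenance)))

    def try_merge_once() -> bool:
        best = None  # (overlap, i, j, merged_seq)
        for i in range(len(work)):
            for j in range(len(work)):
                if i == j:
                    continue
                a, b = work[i].sequence, work[j].sequence
                for b_seq in (b, revcomp(b)):
                    ell = _best_overlap(a, b_seq, min_overlap, min_identity)
                    if ell is not None and (best is None or ell > best[0]):
                        best = (ell, i, j, a + b_seq[ell:])
        if best is None:
            return False
        ell, i, j, merged_seq = best
        keep, drop = work[i], work[j]
        merged = TranscriptRecord(
            keep.id,
            orient_by_orf(merged_seq),
            dict(keep.audit),
            sorted(set(keep.provenance) | set(drop.provenance)),
        )
        merged.record_stage("step5_merge", True, ell)
        for idx in sorted((i, j), reverse=True):
            del work[idx]
        work.append(merged)
        return True

    while try_merge_once():
        pass

    if proteome:
        _stm_join(work, proteome)
    work.sort(key=lambda r: (-r.length, r.id))
    return work


def _stm_join(work: list[TranscriptRecord], proteome: dict[str, str]) -> None:
    """Join fragments whose peptides hit the same protein in compatible order."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    from .seqio import orf_peptide, longest_orf

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    assignments: dict[str, list[tuple[int, int]]] = {}
    for idx, rec in enumerate(work):
        orf = longest_orf(rec.sequence)
        if orf is None or orf.aa_len < 20:
            continue
        pep = orf_peptide(rec.sequence, orf)
        best = None
        for pid in sorted(proteome):
            aln = aligner.align(proteome[pid], pep)
            if len(aln) == 0:
                continue
            score = aln.score
            if best is None or score > best[0]:
                start = int(aln[0].aligned[0][0][0])
                best = (score, pid, start)
        if best is not None and best[0] >= 50:
            assignments.setdefault(best[1], []).append((best[2], idx))
    to_remove: set[int] = set()
    for pid, frags in assignments.items():
        if len(frags) < 2:
            continue
        frags.sort()
        joined = ("N" * 10).join(work[idx].sequence for _, idx in frags)
        prov = sorted(set().union(*(work[idx].provenance for _, idx in frags)))
        rec = TranscriptRecord(work[frags[0][1]].id, joined, {}, prov)
        rec.record_stage("step5_merge", True, f"stm:{pid}")
        to_remove.update(idx for _, idx in frags)
        work.append(rec)
    for idx in sorted(to_remove, reverse=True):
        del work[idx]
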