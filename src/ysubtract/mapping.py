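"""End-to-end read mapping and male/female coverage profiles.

The mapper aligns whole reads against target sequences allowing up to a
fixed number of substitutions (no indels, no splicing): the simulator
plants intron-free transcripts and substitution-only divergence, so this
contract carries exactly the information the downstream filters consume
(mismatch counts, covered positions, per-library totals).

Candidate placements come from a pigeonhole seed index: a read with at
most m mismatches must contain at least one of m+1 non-overlapping exact
segments, so each segment is looked up exactly and the full placement is
verified by Hamming distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import Read, revcomp


@dataclass(frozen=True)
class MappingResult:
    """A read's best end-to-end placement on a target."""

    read_id: str
    target_id: str
    start: int  # 0-based half-open span on the target
    end: int
    strand: str
    mismatches: int


class TargetIndex:
    """Pigeonhole segment index over targets for Hamming-bounded mapping."""

    def __init__(self, targets: dict[str, str]):
        if not targets:
            raise ValueError("targets must be non-empty")
        self.targets = {tid: seq.upper() for tid, seq in targets.items()}
        self._seg_indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _segment_index(self, seg_len: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._seg_indexes.get(seg_len)
        if idx is None:
            idx = {}
            for tid in sorted(self.targets):
                seq = self.targets[tid]
                for i in range(len(seq) - seg_len + 1):
                    idx.setdefault(seq[i : i + seg_len], []).append((tid, i))
            self._seg_indexes[seg_len] = idx
        return idx

    def map_read(self, seq: str, max_mismatches: int) -> tuple[str, int, int, str, int] | None:
        """Best end-to-end placement of ``seq`` or None.

        Best = fewest mismatches; ties broken by lowest target id, then
        leftmost position, then forward strand.
        """
        n = len(seq)
        seg_len = max(1, n // (max_mismatches + 1))
        idx = self._segment_index(seg_len)
        best = None
        best_key = None
        for strand in ("+", "-"):
            s = seq if strand == "+" else revcomp(seq)
            seen: set[tuple[str, int]] = set()
            for j in range(max_mismatches + 1):
                off = j * seg_len
                if off + seg_len > n:
                    break
                for tid, tpos in idx.get(s[off : off + seg_len], ()):
                    start = tpos - off
                    if start < 0 or (tid, start) in seen:
                        continue
                    seen.add((tid, start))
                    target = self.targets[tid]
                    if start + n > len(target):
                        continue
                    mm = _hamming_le(s, target, start, max_mismatches)
                    if mm is None:
                        continue
                    key = (mm, tid, start, strand != "+")
                    if best_key is None or key < best_key:
                        best, best_key = (tid, start, start + n, strand, mm), key
        return best


def _hamming_le(read: str, target: str, start: int, limit: int) -> int | None:
    window = target[start : start + len(read)]
    if read == window:
        return 0
    mm = 0
    for a, b in zip(read, window):
        if a != b:
            mm += 1
            if mm > limit:
                return None
    return mm


def map_reads(
    reads: Iterable[Read],
    targets: dict[str, str] | TargetIndex,
    max_mismatches: int = 2,
) -> list[MappingResult]:
    """Map each read end-to-end against the targets (≤ max_mismatches subs)."""
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets)
    out: list[MappingResult] = []
    for r in reads:
        hit = index.map_read(r.seq, max_mismatches)
        if hit is not None:
            tid, start, end, strand, mm = hit
            out.append(MappingResult(r.id, tid, start, end, strand, mm))
    return out


def unmapped_reads(
    reads: Sequence[Read],
    targets: dict[str, str] | TargetIndex,
    max_mismatches: int = 2,
) -> list[Read]:
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets)
    return [r for r in reads if index.map_read(r.seq, max_mismatches) is None]


@dataclass
class CoverageProfile:
    """Per-target male/female depth and breadth statistics."""

    target_id: str
    length: int
    depth_male: float
    depth_female: float
    breadth_male: float
    breadth_female: float
    normalized_ratio: float | None  # log2 of library-size-normalized M/F depth
    male_only: bool


def _per_target_stats(
    mappings: Iterable[MappingResult], lengths: dict[str, int]
) -> tuple[dict[str, float], dict[str, float], float]:
    """aligned-bases depth, breadth and library total for one sex."""
    masks = {tid: np.zeros(n, dtype=bool) for tid, n in lengths.items()}
    bases = {tid: 0 for tid in lengths}
    total = 0.0
    for m in mappings:
        if m.target_id not in lengths:
            raise KeyError(f"mapping refers to unknown target {m.target_id!r}")
        aligned = m.end - m.start
        bases[m.target_id] += aligned
        total += aligned
        masks[m.target_id][m.start : m.end] = True
    depth = {tid: bases[tid] / lengths[tid] for tid in lengths}
    breadth = {tid: float(masks[tid].mean()) for tid in lengths}
    return depth, breadth, total


def compute_coverage(
    mappings_male: Iterable[MappingResult],
    mappings_female: Iterable[MappingResult],
    targets: dict[str, str],
    total_male_bases: float | None = None,
    total_female_bases: float | None = None,
) -> dict[str, CoverageProfile]:
    """Male/female coverage per target, with library-size-normalized ratio.

    ``normalized_ratio`` = log2((depth_m / total_m) / (depth_f / total_f));
    per-library totals default to the total aligned bases of each mapping
    set. Targets with zero female depth are flagged male-only and carry no
    ratio.
    """
    lengths = {tid: len(seq) for tid, seq in targets.items()}
    depth_m, breadth_m, tot_m = _per_target_stats(mappings_male, lengths)
    depth_f, breadth_f, tot_f = _per_target_stats(mappings_female, lengths)
    if total_male_bases is not None:
        tot_m = total_male_bases
    if total_female_bases is not None:
        tot_f = total_female_bases
    out: dict[str, CoverageProfile] = {}
    for tid in targets:
        dm, df = depth_m[tid], depth_f[tid]
        male_only = df == 0.0
        ratio = None
        if not male_only and dm > 0 and tot_m > 0 and tot_f > 0:
            ratio = math.log2((dm / tot_m) / (df / tot_f))
        out[tid] = CoverageProfile(
            tid, lengths[tid], dm, df, breadth_m[tid], breadth_f[tid], ratio, male_only
        )
    return out


def library_bases(reads: Iterable[Read]) -> float:
    """Total sequenced bases in a library (the sequencing-effort denominator
    for cross-library coverage normalization; preferable to aligned bases
    when the two libraries differ in how much of them can align, as male
    libraries do once Y-derived reads meet a female assembly)."""
    return float(sum(len(r.seq) for r in reads))


def effective_length(length_or_record, frag_len_mean: float) -> int:
    """Fragment-length-corrected transcript length: max(L − μ_frag + 1, 0)."""
    if frag_len_mean <= 0:
        raise ValueError("frag_len_mean must be > 0")
    length = getattr(length_or_record, "length", length_or_record)
    return max(int(length) - int(round(frag_len_mean)) + 1, 0)
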