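"""The nine-stage subtractive filter cascade and its sex-swapped control.

Starting from male RNA-seq reads, every stage removes transcripts that the
female genome or female expression can explain, leaving male-limited
(putative Y-linked) candidates:

1. map male RNA reads to the female genome assembly;
2. assemble the unmapped reads into a de novo transcriptome;
3. discard transcripts largely explained by the female assembly
   (> 90% of length at ≥ 98% identity; alignments scoring < 50 are
   treated as no hit);
4. discard transcripts whose sequence is ≥ 50% covered by female RNA
   reads mapping with ≤ 2 mismatches;
5. merge remaining fragments (≥ 30 bp overlap);
6. keep transcripts with > 60% male and < 10% female genomic breadth;
7. keep transcripts expressed > 2× more in males than females (RPKM);
8. discard transcripts hitting a k-mer-abundance repeat library;
9. discard transcripts whose effective length is ≤ 60% of their length.

The sex-swap control reruns the identical cascade with the sexes
exchanged; a dataset is considered usable when it yields more than twice
as many male-specific as female-specific transcripts.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import assemble as asm
from .align import SeedIndex, best_local_hit
from .assemble import TranscriptRecord
from .mapping import TargetIndex, compute_coverage, effective_length, map_reads
from .seqio import Read, ReadPair, flatten_pairs


class PipelineError(ValueError):
    """Invalid pipeline configuration or inconsistent inputs."""


@dataclass
class PipelineConfig:
    """All cascade thresholds, defaulting to the published values."""

    female_hit_len_frac: float = 0.90
    female_hit_identity: float = 0.98
    min_aln_score: int = 50
    female_rna_breadth: float = 0.50
    female_rna_max_mismatch: int = 2
    merge_min_overlap: int = 30
    merge_min_identity: float = 0.95
    male_breadth_min: float = 0.60
    female_breadth_max: float = 0.10
    expr_ratio_min: float = 2.0
    eff_len_frac_min: float = 0.60
    assembly_k: int = 25
    genome_k: int = 31
    sexswap_ratio_min: float = 2.0
    step1_max_mismatch: int = 2
    genomic_max_mismatch: int = 2
    rna_max_mismatch: int = 2
    assembly_min_count: int = 2
    min_contig_len: int = 100
    repeat_count_factor: float = 10.0

    def validate(self) -> None:
        for f in (
            "female_hit_len_frac",
            "female_hit_identity",
            "female_rna_breadth",
            "male_breadth_min",
            "female_breadth_max",
            "eff_len_frac_min",
            "merge_min_identity",
        ):
            v = getattr(self, f)
            if not 0 < v <= 1:
                raise PipelineError(f"{f}: must be in (0, 1], got {v}")
        for f in ("expr_ratio_min", "sexswap_ratio_min", "repeat_count_factor"):
            if getattr(self, f) <= 0:
                raise PipelineError(f"{f}: must be > 0")
        if self.assembly_k % 2 == 0 or not 15 <= self.assembly_k <= 31:
            raise PipelineError("assembly_k: must be odd and in [15, 31]")


@dataclass
class PipelineInputs:
    """Read sets and the opposite-sex genome assembly for one orientation."""

    female_assembly: dict[str, str]
    male_rna: list[ReadPair]
    female_rna: list[ReadPair]
    male_genomic: list[ReadPair]
    female_genomic: list[ReadPair]
    frag_len_mean: float
    male_assembly: dict[str, str] | None = None  # needed only for the sex swap

    def validate(self) -> None:
        for f in ("female_assembly", "male_rna", "male_genomic", "female_genomic"):
            if not getattr(self, f):
                raise PipelineError(f"{f}: required input is missing or empty")

    @classmethod
    def from_world(cls, world) -> "PipelineInputs":
        return cls(
            female_assembly=dict(world.female_genome),
            male_rna=world.rna_reads("male"),
            female_rna=world.rna_reads("female"),
            male_genomic=world.reads("male", "genomic"),
            female_genomic=world.reads("female", "genomic"),
            frag_len_mean=world.cfg.frag_len_mean,
            male_assembly=world.male_genome,
        )

    def swapped(self) -> "PipelineInputs":
        if self.male_assembly is None:
            raise PipelineError("male_assembly: required to run the sex-swapped control")
        return PipelineInputs(
            female_assembly=self.male_assembly,
            male_rna=self.female_rna,
            female_rna=self.male_rna,
            male_genomic=self.female_genomic,
            female_genomic=self.male_genomic,
            frag_len_mean=self.frag_len_mean,
            male_assembly=self.female_assembly,
        )


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_retained: int

    @property
    def n_discarded(self) -> int:
        return self.n_in - self.n_retained


@dataclass
class FilterReport:
    """Per-stage counts, per-transcript audit trails, final candidates."""

    stages: list[StageCount] = field(default_factory=list)
    discarded: list[TranscriptRecord] = field(default_factory=list)
    candidates: list[TranscriptRecord] = field(default_factory=list)
    n_reads_in: int = 0
    n_reads_unmapped: int = 0

    def add_stage(self, stage: str, kept: list[TranscriptRecord], dropped: list[TranscriptRecord]) -> None:
        self.stages.append(StageCount(stage, len(kept) + len(dropped), len(kept)))
        self.discarded.extend(dropped)

    def stage_counts(self) -> dict[str, tuple[int, int]]:
        return {s.stage: (s.n_in, s.n_retained) for s in self.stages}

    def audit_rows(self) -> list[dict]:
        rows = []
        for rec in list(self.candidates) + list(self.discarded):
            for stage, (passed, metric) in rec.audit.items():
                rows.append(
                    {"transcript_id": rec.id, "stage": stage, "passed": passed, "metric": metric}
                )
        return rows


def _partition(
    records: Sequence[TranscriptRecord], stage: str, keep_fn
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    kept, dropped = [], []
    for rec in records:
        ok, metric = keep_fn(rec)
        rec.record_stage(stage, ok, metric)
        (kept if ok else dropped).append(rec)
    return kept, dropped


# -- stage 3: female genome subtraction -------------------------------------


def filter_female_genome_hits(
    records: Sequence[TranscriptRecord],
    female_genome: dict[str, str] | SeedIndex,
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Discard transcripts mostly explained by the female assembly.

    A transcript is discarded iff its best local alignment (scoring at
    least ``min_aln_score``; weaker hits count as no hit) covers more than
    ``female_hit_len_frac`` of its length at ≥ ``female_hit_identity``.
    """
    index = female_genome if isinstance(female_genome, SeedIndex) else SeedIndex(female_genome)

    def keep(rec: TranscriptRecord):
        hit = best_local_hit(rec.sequence, index, min_score=cfg.min_aln_score)
        if hit is None:
            return True, "no_hit"
        cov = hit.query_coverage(rec.length)
        discard = cov > cfg.female_hit_len_frac and hit.identity >= cfg.female_hit_identity
        return not discard, f"cov={cov:.3f},id={hit.identity:.3f},score={hit.score}"

    kept, dropped = _partition(records, "step3_female_genome", keep)
    if report is not None:
        report.add_stage("step3_female_genome", kept, dropped)
    return kept


# -- stage 4: female RNA subtraction ----------------------------------------


def filter_female_rna(
    records: Sequence[TranscriptRecord],
    female_rna: Iterable[Read],
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Discard transcripts ≥ 50% covered by female RNA reads (≤ 2 mismatches)."""
    records = list(records)
    breadth: dict[str, float] = {rec.id: 0.0 for rec in records}
    if records:
        targets = {rec.id: rec.sequence for rec in records}
        mapped = map_reads(female_rna, targets, cfg.female_rna_max_mismatch)
        cov = compute_coverage(mapped, [], targets)
        breadth = {tid: p.breadth_male for tid, p in cov.items()}

    def keep(rec: TranscriptRecord):
        b = breadth[rec.id]
        return b < cfg.female_rna_breadth, round(b, 4)

    kept, dropped = _partition(records, "step4_female_rna", keep)
    if report is not None:
        report.add_stage("step4_female_rna", kept, dropped)
    return kept


# -- stage 6: genomic coverage ----------------------------------------------


def filter_genomic_coverage(
    records: Sequence[TranscriptRecord],
    coverage: dict[str, "CoverageProfile"],
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Keep transcripts with > 60% male and < 10% female genomic breadth."""
    for rec in records:
        if rec.id not in coverage:
            raise PipelineError(f"no coverage profile for transcript {rec.id!r}")

    def keep(rec: TranscriptRecord):
        p = coverage[rec.id]
        ok = p.breadth_male > cfg.male_breadth_min and p.breadth_female < cfg.female_breadth_max
        return ok, f"m={p.breadth_male:.3f},f={p.breadth_female:.3f}"

    kept, dropped = _partition(records, "step6_genomic_coverage", keep)
    if report is not None:
        report.add_stage("step6_genomic_coverage", kept, dropped)
    return kept


# -- stage 7: expression ratio ----------------------------------------------


def count_fragments(
    pairs: Iterable[ReadPair], index: TargetIndex, max_mismatches: int
) -> dict[str, int]:
    """Fragments per target; a pair counts once, to its first mapped mate's target."""
    counts: dict[str, int] = {}
    for r1, r2 in pairs:
        hit = index.map_read(r1.seq, max_mismatches) or index.map_read(r2.seq, max_mismatches)
        if hit is not None:
            counts[hit[0]] = counts.get(hit[0], 0) + 1
    return counts


def rpkm(count: int, eff_len: int, total_fragments: int) -> float:
    if eff_len <= 0 or total_fragments <= 0:
        return 0.0
    return count * 1e9 / (eff_len * total_fragments)


def filter_expression(
    records: Sequence[TranscriptRecord],
    male_rna: list[ReadPair],
    female_rna: list[ReadPair],
    frag_len_mean: float,
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Keep transcripts expressed more than ``expr_ratio_min`` times higher in
    males than in females (RPKM with effective-length denominator); zero
    female expression with male expression counts as male-specific."""
    records = list(records)
    m_counts: dict[str, int] = {}
    f_counts: dict[str, int] = {}
    if records:
        index = TargetIndex({rec.id: rec.sequence for rec in records})
        m_counts = count_fragments(male_rna, index, cfg.rna_max_mismatch)
        f_counts = count_fragments(female_rna, index, cfg.rna_max_mismatch)
    m_total = sum(m_counts.values())
    f_total = sum(f_counts.values())

    def keep(rec: TranscriptRecord):
        el = effective_length(rec.length, frag_len_mean)
        if el == 0:
            return False, "effective_length=0"
        m = rpkm(m_counts.get(rec.id, 0), el, m_total)
        f = rpkm(f_counts.get(rec.id, 0), el, f_total)
        if f == 0:
            return m > 0, f"rpkm_m={m:.2f},rpkm_f=0"
        return m > cfg.expr_ratio_min * f, f"rpkm_m={m:.2f},rpkm_f={f:.2f}"

    kept, dropped = _partition(records, "step7_expression", keep)
    if report is not None:
        report.add_stage("step7_expression", kept, dropped)
    return kept


# -- stage 8: repeat screen --------------------------------------------------


def build_repeat_library(
    genomic_reads: Iterable[Read], cfg: PipelineConfig
) -> dict[str, str]:
    """Repeat contigs assembled from high-abundance genomic k-mers.

    A k-mer is called repetitive when its count is at least
    ``repeat_count_factor`` times the median count of solid (count ≥ 2)
    k-mers — the median over solid k-mers estimates single-copy depth.
    """
    counts = asm.count_canonical_kmers((r.seq for r in genomic_reads), cfg.genome_k)
    solid = [c for c in counts.values() if c >= 2]
    if not solid:
        return {}
    from .seqio import revcomp

    threshold = cfg.repeat_count_factor * statistics.median(solid)
    expanded: set[str] = set()
    for km, c in counts.items():  # counts are over canonical k-mers
        if c >= threshold:
            expanded.add(km)
            expanded.add(revcomp(km))
    contigs = asm._unitigs_from_kmers(expanded, cfg.genome_k)
    seen: set[str] = set()
    library: dict[str, str] = {}
    i = 0
    for seq in sorted(contigs, key=lambda s: (-len(s), s)):
        if len(seq) < cfg.genome_k:
            continue
        can = asm.canonical(seq)
        if can in seen:
            continue
        seen.add(can)
        i += 1
        library[f"repeat_{i:04d}"] = seq
    return library


def filter_repeats(
    records: Sequence[TranscriptRecord],
    male_genomic_reads_or_library: Iterable[Read] | dict[str, str],
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Discard transcripts with a local hit (score ≥ min_aln_score) to the
    repeat library built from male genomic k-mer abundance."""
    if isinstance(male_genomic_reads_or_library, dict):
        library = male_genomic_reads_or_library
    else:
        library = build_repeat_library(male_genomic_reads_or_library, cfg)
    index = SeedIndex(library) if library else None

    def keep(rec: TranscriptRecord):
        if index is None:
            return True, "no_repeat_library"
        hit = best_local_hit(rec.sequence, index, min_score=cfg.min_aln_score)
        if hit is None:
            return True, "no_hit"
        return False, f"repeat_hit_score={hit.score}"

    kept, dropped = _partition(records, "step8_repeats", keep)
    if report is not None:
        report.add_stage("step8_repeats", kept, dropped)
    return kept


# -- stage 9: effective length ----------------------------------------------


def filter_effective_length(
    records: Sequence[TranscriptRecord],
    frag_len_mean: float,
    cfg: PipelineConfig,
    report: FilterReport | None = None,
) -> list[TranscriptRecord]:
    """Keep transcripts whose effective length exceeds 60% of their length."""

    def keep(rec: TranscriptRecord):
        frac = effective_length(rec.length, frag_len_mean) / rec.length
        return frac > cfg.eff_len_frac_min, round(frac, 4)

    kept, dropped = _partition(records, "step9_effective_length", keep)
    if report is not None:
        report.add_stage("step9_effective_length", kept, dropped)
    return kept


# -- full cascade ------------------------------------------------------------


def run_pipeline(inputs: PipelineInputs, cfg: PipelineConfig | None = None) -> FilterReport:
    """Execute stages 1–9 in order and return the audited report."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    inputs.validate()
    report = FilterReport()

    # step 1: male RNA reads vs the female genome assembly
    genome_index = TargetIndex(inputs.female_assembly)
    male_rna_reads = list(flatten_pairs(inputs.male_rna))
    unmapped = [
        r for r in male_rna_reads if genome_index.map_read(r.seq, cfg.step1_max_mismatch) is None
    ]
    report.n_reads_in = len(male_rna_reads)
    report.n_reads_unmapped = len(unmapped)

    # step 2: de novo assembly of the unmapped reads
    records = asm.assemble_transcripts(
        unmapped, k=cfg.assembly_k, min_count=cfg.assembly_min_count, min_len=cfg.min_contig_len
    )
    report.stages.append(StageCount("step2_assembly", len(unmapped), len(records)))

    # step 3: subtract female-genome-explained transcripts
    records = filter_female_genome_hits(records, inputs.female_assembly, cfg, report)

    # step 4: subtract transcripts covered by female RNA
    female_rna_reads = list(flatten_pairs(inputs.female_rna))
    records = filter_female_rna(records, female_rna_reads, cfg, report)

    # step 5: merge overlapping fragments
    n_before = len(records)
    records = asm.merge_transcripts(records, cfg.merge_min_overlap, cfg.merge_min_identity)
    report.stages.append(StageCount("step5_merge", n_before, len(records)))

    # step 6: male/female genomic breadth
    if records:
        targets = {rec.id: rec.sequence for rec in records}
        idx = TargetIndex(targets)
        m_map = map_reads(flatten_pairs(inputs.male_genomic), idx, cfg.genomic_max_mismatch)
        f_map = map_reads(flatten_pairs(inputs.female_genomic), idx, cfg.genomic_max_mismatch)
        coverage = compute_coverage(m_map, f_map, targets)
    else:
        coverage = {}
    records = filter_genomic_coverage(records, coverage, cfg, report)

    # step 7: male vs female expression
    records = filter_expression(
        records, inputs.male_rna, inputs.female_rna, inputs.frag_len_mean, cfg, report
    )

    # step 8: repeat screen
    records = filter_repeats(
        records, list(flatten_pairs(inputs.male_genomic)), cfg, report
    )

    # step 9: effective length
    records = filter_effective_length(records, inputs.frag_len_mean, cfg, report)

    report.candidates = records
    return report


def sexswap_include(n_male_specific: int, n_female_specific: int, ratio_min: float = 2.0) -> bool:
    """Species-inclusion rule: more than ``ratio_min`` times as many
    male-specific as female-specific transcripts."""
    return n_male_specific > ratio_min * n_female_specific


@dataclass
class SexSwapResult:
    n_male_specific: int
    n_female_specific: int
    include_species: bool
    male_report: FilterReport
    female_report: FilterReport


def sex_swap_control(inputs: PipelineInputs, cfg: PipelineConfig | None = None) -> SexSwapResult:
    """Run the cascade in both orientations; the dataset passes the control
    when male-specific transcripts outnumber female-specific ones more than
    ``sexswap_ratio_min``-fold."""
    cfg = cfg or PipelineConfig()
    male_report = run_pipeline(inputs, cfg)
    female_report = run_pipeline(inputs.swapped(), cfg)
    n_m = len(male_report.candidates)
    n_f = len(female_report.candidates)
    return SexSwapResult(
        n_m, n_f, sexswap_include(n_m, n_f, cfg.sexswap_ratio_min), male_report, female_report
    )
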