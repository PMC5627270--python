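"""Synthetic male/female genomes, transcriptomes and read sets with Y-gene truth.

The generator emulates the data regime the subtraction pipeline assumes: a
diploid genome of autosomes plus a hemizygous X (present twice in females,
once in males) and a male-limited Y carrying planted genes of distinct
origins — an X-linked "escapee" paralog, autosomal acquisitions at graded
divergence, a recent near-identical duplicate (the analogue of a young Y
gene still ~98% identical to its autosomal parent), repeat-embedded genes,
and unique Y genes with no paralog anywhere. Expression of Y genes is
gonad(testis)-biased by default. Every planted gene is recorded in a truth
table so each pipeline stage has a ground-truth acceptance surface.

Sequence model: i.i.d. uniform nucleotide backbones; paralogs are created
by copying a gene and applying point substitutions at exactly the
requested per-site divergence (distinct sites, stop codons never created,
start/stop codons protected), which keeps alignment and Ka/Ks oracles
exact. Reads are paired-end with normally distributed fragment lengths and
uniform per-base substitution errors; one RNG stream per
(sex, datatype, tissue) so adding a tissue never perturbs other outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
import numpy as np

from .seqio import Read, ReadPair, revcomp, STOP_CODONS

ORIGINS = ("X_escapee", "autosomal_acquisition", "recent_duplicate", "repeat_embedded", "unique")

BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class YGeneSpec:
    """One planted Y gene: its origin class, paralog divergence and expression."""

    name: str
    origin: str
    divergence: float = 0.0
    expression_profile: dict[str, float] = field(default_factory=lambda: {"head": 0.1, "gonad": 1.0})
    length: int = 900  # CDS length in bp incl. start and stop codons

    def __post_init__(self):
        if self.origin not in ORIGINS:
            raise ConfigError(f"y_gene_spec[{self.name}].origin: unknown origin {self.origin!r}")
        if self.origin == "unique" and self.divergence != 0:
            raise ConfigError(f"y_gene_spec[{self.name}].divergence: unique genes have no paralog")
        if self.origin == "recent_duplicate" and self.divergence > 0.02:
            raise ConfigError(
                f"y_gene_spec[{self.name}].divergence: recent duplicates must be ≤ 0.02 "
                "(≥98% nucleotide identity)"
            )
        if not 0 <= self.divergence <= 0.75:
            raise ConfigError(f"y_gene_spec[{self.name}].divergence: out of range")
        if self.length % 3 or self.length < 120:
            raise ConfigError(f"y_gene_spec[{self.name}].length: must be a multiple of 3, ≥ 120")

    @property
    def has_paralog(self) -> bool:
        return self.origin in ("X_escapee", "autosomal_acquisition", "recent_duplicate")

    @property
    def detectable(self) -> bool:
        """Expected to survive the full subtraction cascade.

        Near-identical duplicates are removed by the female-genome
        subtraction (by design) and repeat-embedded genes by the repeat
        screen. Genes with a paralog below ~12% divergence sit under the
        cascade's detectability floor: with 100-bp reads, windows of the
        paralog with ≤ 2 divergent sites let female genomic reads map onto
        the Y transcript, so its female breadth can exceed the 10% ceiling
        even though it clears the 98%-identity subtraction.
        """
        if self.origin == "repeat_embedded":
            return False
        return not self.has_paralog or self.divergence >= 0.12


def default_y_genes() -> list[YGeneSpec]:
    """The default study condition: 20 detectable Y genes (9 unique, 6
    autosomal acquisitions and 5 X escapees at graded divergence above the
    cascade's detectability floor), 2 near-identical recent duplicates, 2
    repeat-embedded genes, and 2 low-divergence boundary probes that clear
    the 98%-identity subtraction but sit below the coverage-filter floor.
    Expression is gonad(testis)-biased for most genes."""
    testis = {"head": 0.1, "gonad": 1.0}
    broad = {"head": 0.6, "gonad": 0.8}
    genes: list[YGeneSpec] = []
    for i, div in enumerate([0.15, 0.18, 0.20, 0.25, 0.30, 0.40]):
        genes.append(YGeneSpec(f"yacq_{i+1:02d}", "autosomal_acquisition", div, testis, 900 + 60 * (i % 4)))
    for i, div in enumerate([0.15, 0.18, 0.22, 0.25, 0.30]):
        prof = broad if i == 0 else testis
        genes.append(YGeneSpec(f"yesc_{i+1:02d}", "X_escapee", div, prof, 840 + 60 * (i % 4)))
    for i in range(9):
        prof = broad if i == 0 else testis
        genes.append(YGeneSpec(f"yuniq_{i+1:02d}", "unique", 0.0, prof, 780 + 60 * (i % 5)))
    genes.append(YGeneSpec("yfdy_01", "recent_duplicate", 0.02, testis, 900))
    genes.append(YGeneSpec("yfdy_02", "recent_duplicate", 0.015, testis, 960))
    genes.append(YGeneSpec("yrep_01", "repeat_embedded", 0.0, testis, 780))
    genes.append(YGeneSpec("yrep_02", "repeat_embedded", 0.0, testis, 840))
    genes.append(YGeneSpec("yprobe_01", "autosomal_acquisition", 0.05, testis, 900))
    genes.append(YGeneSpec("yprobe_02", "X_escapee", 0.08, testis, 840))
    return genes


@dataclass
class SimConfig:
    """Study-condition parameters for the simulated world."""

    seed: int = 0
    n_autosomal_scaffolds: int = 6
    n_x_scaffolds: int = 4
    n_y_scaffolds: int = 4
    scaffold_len: int = 8000
    y_gene_spec: list[YGeneSpec] = field(default_factory=default_y_genes)
    genomic_depth: float = 20.0
    rna_depth_by_tissue: dict[str, float] = field(default_factory=lambda: {"head": 50.0, "gonad": 50.0})
    read_len: int = 100
    frag_len_mean: float = 250.0
    frag_len_sd: float = 25.0
    error_rate: float = 0.002
    repeat_spec: tuple[int, int] = (150, 12)  # (motif_len bp, copy_number)
    n_shared_genes: int = 6  # autosomal genes expressed in both sexes
    n_x_genes: int = 3  # X-linked genes expressed in both sexes
    background_gene_len: int = 900
    utr_len: int = 50  # untranslated flank on each side of a planted CDS

    def validate(self) -> None:
        if self.genomic_depth <= 0:
            raise ConfigError("genomic_depth: must be > 0")
        for t, d in self.rna_depth_by_tissue.items():
            if d <= 0:
                raise ConfigError(f"rna_depth_by_tissue[{t}]: must be > 0")
        if self.read_len > self.frag_len_mean:
            raise ConfigError("read_len: must be ≤ frag_len_mean")
        if not 0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate: must be in [0, 0.05]")
        if self.scaffold_len < 1000:
            raise ConfigError("scaffold_len: must be ≥ 1000")
        for f in ("n_autosomal_scaffolds", "n_x_scaffolds", "n_y_scaffolds"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{f}: must be ≥ 1")
        if self.repeat_spec[0] < 5 or self.repeat_spec[1] < 2:
            raise ConfigError("repeat_spec: motif_len ≥ 5 and copy_number ≥ 2 required")
        names = [g.name for g in self.y_gene_spec]
        if len(names) != len(set(names)):
            raise ConfigError("y_gene_spec: duplicate gene names")


@dataclass
class GeneTruth:
    """Truth record for one planted gene (Y or background)."""

    gene_id: str
    chromosome_class: str  # autosome / X / Y
    scaffold: str
    span: tuple[int, int]
    transcript: str  # mature transcript sequence (UTR + CDS + UTR [+ tail])
    expression_profile: dict[str, float]
    sexes: tuple[str, ...]  # which sexes express it
    cds_span: tuple[int, int]  # CDS coordinates within the transcript
    spec: YGeneSpec | None = None  # set for Y genes
    paralog_scaffold: str | None = None
    paralog_span: tuple[int, int] | None = None

    @property
    def cds(self) -> str:
        return self.transcript[self.cds_span[0] : self.cds_span[1]]


def _stream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def random_cds(rng: np.random.Generator, length: int) -> str:
    """A single-ORF coding sequence: ATG + internal non-stop codons + TAA."""
    n_internal = length // 3 - 2
    codons = rng.integers(0, len(_NONSTOP_CODONS), n_internal)
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in codons) + "TAA"


def mutate_paralog(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    coding: bool = True,
    omega: float = 0.3,
) -> str:
    """Copy with point substitutions at exactly round(divergence × L) distinct
    sites, so nucleotide identity of the pair is exactly 1 − divergence.

    In coding mode the first and last codons are protected, substitutions
    that would create an in-frame stop are resampled (the copy keeps an
    intact ORF), and proposed amino-acid-changing substitutions are accepted
    with relative probability ``omega`` — mimicking purifying selection, so
    that even deeply diverged paralog pairs stay recognizably similar at the
    protein level (Ka/Ks < 1), as real surviving gene copies do.
    """
    from .paralogs import CODON_TABLE

    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    chars = list(seq)
    lo, hi = (3, len(seq) - 3) if coding else (0, len(seq))
    done = 0
    # strict pass applies the omega bias; relaxed pass tops up if needed
    for relax in (False, True):
        candidates = [p for p in range(lo, hi)]
        rng.shuffle(candidates)
        for pos in candidates:
            if done == n_sub:
                break
            if chars[pos] != seq[pos]:
                continue  # already substituted
            alts = [b for b in BASES if b != chars[pos]]
            rng.shuffle(alts)
            for alt in alts:
                if coding:
                    cstart = pos - pos % 3
                    codon = "".join(chars[cstart : cstart + 3])
                    new_codon = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
                    if new_codon in STOP_CODONS:
                        continue
                    nonsyn = CODON_TABLE[new_codon] != CODON_TABLE[codon]
                    if nonsyn and not relax and rng.random() >= omega:
                        continue
                chars[pos] = alt
                done += 1
                break
        if done == n_sub:
            break
    return "".join(chars)


def _syn_options(codon: str) -> list[tuple[int, str]]:
    from .paralogs import CODON_TABLE

    aa = CODON_TABLE[codon]
    opts = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                opts.append((pos, b))
    return opts


def evolve_synonymous(cds: str, divergence: float, rng: np.random.Generator) -> str:
    """Evolve a CDS by synonymous substitutions only, allowing multiple hits.

    ``divergence`` is the target number of synonymous substitutions per
    synonymous site (sensu the degeneracy-weighted site count), so the
    pathway-corrected Ks of (input, output) estimates it.
    """
    from .paralogs import ng86_sites

    s_sites, _ = ng86_sites(cds)
    n_events = rng.poisson(divergence * s_sites)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    weights = np.array([len(_syn_options(c)) for c in codons], dtype=float)
    for _ in range(n_events):
        w = weights / weights.sum()
        ci = rng.choice(len(codons), p=w)
        opts = _syn_options(codons[ci])
        pos, b = opts[rng.integers(0, len(opts))]
        codons[ci] = codons[ci][:pos] + b + codons[ci][pos + 1 :]
        weights[ci] = len(_syn_options(codons[ci]))
    return "".join(codons)


def _layout_scaffold(
    rng: np.random.Generator, nominal_len: int, elements: list[tuple[str, str]]
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Embed elements in a random backbone at random non-overlapping offsets."""
    content = sum(len(seq) for _, seq in elements)
    slack = max(nominal_len - content, 200 * (len(elements) + 1))
    cuts = np.sort(rng.integers(0, slack + 1, len(elements))) if elements else np.array([], int)
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    parts: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    for (name, seq), gap in zip(elements, gaps[:-1]):
        g = int(gap)
        parts.append(_random_seq(rng, g))
        pos += g
        parts.append(seq)
        spans[name] = (pos, pos + len(seq))
        pos += len(seq)
    parts.append(_random_seq(rng, int(gaps[-1]) if len(gaps) else nominal_len))
    return "".join(parts), spans


class SimulatedWorld:
    """Genomes, transcripts, truth labels, and lazily generated read sets."""

    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.cfg = cfg
        self.female_genome: dict[str, str] = {}
        self.scaffold_class: dict[str, str] = {}  # scaffold -> autosome/X/Y
        self.y_scaffolds: dict[str, str] = {}
        self.truth: dict[str, GeneTruth] = {}
        self.repeat_motif: str = ""
        self._read_cache: dict[tuple, list[ReadPair]] = {}
        self._build()

    # -- genome construction ------------------------------------------------

    def _build(self) -> None:
        cfg = self.cfg
        rng = _stream_rng(cfg.seed, "genome")
        motif_len, copies = cfg.repeat_spec
        self.repeat_motif = _random_seq(rng, motif_len)
        repeat_array = self.repeat_motif * copies

        y_genes = list(cfg.y_gene_spec)

        # Every gene is planted as a transcription unit: 5' UTR + single-ORF
        # CDS + 3' UTR. The UTRs keep the ORF interior, so losing a few
        # terminal bases during assembly (terminal k-mers sit below the
        # solidity threshold) never clips the start codon. A duplicated gene
        # copies the whole unit, so UTRs are homologous between paralogs and
        # diverge at the same rate as the CDS (without coding constraints).
        u = cfg.utr_len

        def transcription_unit(cds_len: int) -> str:
            return _random_seq(rng, u) + random_cds(rng, cds_len) + _random_seq(rng, u)

        def mutate_unit(unit: str, cds_len: int, divergence: float) -> str:
            utr5, cds, utr3 = unit[:u], unit[u : u + cds_len], unit[u + cds_len :]
            return (
                mutate_paralog(utr5, divergence, rng, coding=False)
                + mutate_paralog(cds, divergence, rng, coding=True)
                + mutate_paralog(utr3, divergence, rng, coding=False)
            )

        y_seq: dict[str, str] = {}
        paralog_seq: dict[str, str] = {}
        for g in y_genes:
            base = transcription_unit(g.length)
            if g.has_paralog:
                paralog_seq[g.name] = base
                y_seq[g.name] = mutate_unit(base, g.length, g.divergence)
            else:
                y_seq[g.name] = base

        shared = {f"ashared_{i+1:02d}": transcription_unit(cfg.background_gene_len) for i in range(cfg.n_shared_genes)}
        xgenes = {f"xgene_{i+1:02d}": transcription_unit(cfg.background_gene_len) for i in range(cfg.n_x_genes)}

        # distribute elements over scaffolds round-robin
        auto_elements: list[list[tuple[str, str]]] = [[] for _ in range(cfg.n_autosomal_scaffolds)]
        x_elements: list[list[tuple[str, str]]] = [[] for _ in range(cfg.n_x_scaffolds)]
        slot = 0
        for name, seq in shared.items():
            auto_elements[slot % cfg.n_autosomal_scaffolds].append((name, seq))
            slot += 1
        for g in y_genes:
            if g.origin in ("autosomal_acquisition", "recent_duplicate"):
                auto_elements[slot % cfg.n_autosomal_scaffolds].append((f"par_{g.name}", paralog_seq[g.name]))
                slot += 1
        auto_elements[0].append(("repeat_auto", repeat_array))
        slot = 0
        for name, seq in xgenes.items():
            x_elements[slot % cfg.n_x_scaffolds].append((name, seq))
            slot += 1
        for g in y_genes:
            if g.origin == "X_escapee":
                x_elements[slot % cfg.n_x_scaffolds].append((f"par_{g.name}", paralog_seq[g.name]))
                slot += 1

        placements: dict[str, tuple[str, tuple[int, int]]] = {}
        for i, elements in enumerate(auto_elements):
            sid = f"auto_{i+1:02d}"
            seq, spans = _layout_scaffold(rng, cfg.scaffold_len, elements)
            self.female_genome[sid] = seq
            self.scaffold_class[sid] = "autosome"
            placements.update({n: (sid, s) for n, s in spans.items()})
        for i, elements in enumerate(x_elements):
            sid = f"x_{i+1:02d}"
            seq, spans = _layout_scaffold(rng, cfg.scaffold_len, elements)
            self.female_genome[sid] = seq
            self.scaffold_class[sid] = "X"
            placements.update({n: (sid, s) for n, s in spans.items()})

        # Y scaffolds: transcripts planted contiguously; repeat arrays between genes.
        # Repeat-embedded transcripts carry a diverged (~12%) copy of one repeat
        # monomer as a transcribed tail: diverged enough that its k-mers are
        # unique (so assembly keeps it attached to the CDS and no female read
        # maps end-to-end), yet similar enough that the repeat screen's local
        # alignment to the genomic repeat family scores well above its floor.
        tail_len = min(100, motif_len)
        y_elements: list[list[tuple[str, str]]] = [[] for _ in range(cfg.n_y_scaffolds)]
        y_transcripts: dict[str, str] = {}
        for j, g in enumerate(y_genes):
            t = y_seq[g.name]
            if g.origin == "repeat_embedded":
                t += mutate_paralog(self.repeat_motif[:tail_len], 0.12, rng, coding=False)
            y_transcripts[g.name] = t
            y_elements[j % cfg.n_y_scaffolds].append((g.name, t))
        y_elements[0].append(("repeat_y", repeat_array))
        y_nominal = max(2000, sum(len(s) for _, s in y_elements[0]) + 1000)
        for i, elements in enumerate(y_elements):
            sid = f"y_{i+1:02d}"
            seq, spans = _layout_scaffold(rng, y_nominal, elements)
            self.y_scaffolds[sid] = seq
            self.scaffold_class[sid] = "Y"
            placements.update({n: (sid, s) for n, s in spans.items()})

        both = ("male", "female")
        flat = {"head": 1.0, "gonad": 1.0}
        bg_cds = (u, u + cfg.background_gene_len)
        for name, seq in shared.items():
            sid, span = placements[name]
            self.truth[name] = GeneTruth(name, "autosome", sid, span, seq, dict(flat), both, bg_cds)
        for name, seq in xgenes.items():
            sid, span = placements[name]
            self.truth[name] = GeneTruth(name, "X", sid, span, seq, dict(flat), both, bg_cds)
        for g in y_genes:
            if g.has_paralog:
                pname = f"par_{g.name}"
                sid, span = placements[pname]
                self.truth[pname] = GeneTruth(
                    pname, self.scaffold_class[sid], sid, span, paralog_seq[g.name],
                    dict(flat), both, (u, u + g.length),
                )
        for g in y_genes:
            sid, span = placements[g.name]
            psid, pspan = (None, None)
            if g.has_paralog:
                psid, pspan = placements[f"par_{g.name}"]
            self.truth[g.name] = GeneTruth(
                g.name, "Y", sid, span, y_transcripts[g.name], dict(g.expression_profile),
                ("male",), (u, u + g.length), g, psid, pspan,
            )

    # -- derived views -------------------------------------------------------

    @property
    def male_genome(self) -> dict[str, str]:
        return {**self.female_genome, **self.y_scaffolds}

    def genome_assembly(self, sex: str) -> dict[str, str]:
        return self.female_genome if sex == "female" else self.male_genome

    @property
    def y_gene_truth(self) -> dict[str, GeneTruth]:
        return {n: t for n, t in self.truth.items() if t.chromosome_class == "Y"}

    def expressed_genes(self, sex: str) -> list[GeneTruth]:
        return [t for t in self.truth.values() if sex in t.sexes]

    def truth_table(self) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for t in self.y_gene_truth.values():
            rows.append(
                {
                    "transcript_id": t.gene_id,
                    "origin": t.spec.origin,
                    "divergence": t.spec.divergence,
                    "paralog_scaffold": t.paralog_scaffold or ".",
                    "paralog_class": self.scaffold_class.get(t.paralog_scaffold, ".") if t.paralog_scaffold else ".",
                    "detectable": t.spec.detectable,
                    "y_scaffold": t.scaffold,
                }
            )
        return pd.DataFrame(rows)

    # -- read emission -------------------------------------------------------

    def reads(self, sex: str, datatype: str, tissue: str | None = None) -> list[ReadPair]:
        """Paired-end reads for one (sex, datatype, tissue) library (cached)."""
        key = (sex, datatype, tissue)
        if key not in self._read_cache:
            self._read_cache[key] = emit_reads(self, sex, datatype, tissue)
        return self._read_cache[key]

    def rna_reads(self, sex: str) -> list[ReadPair]:
        """All RNA read pairs for one sex, pooled over tissues."""
        out: list[ReadPair] = []
        for tissue in sorted(self.cfg.rna_depth_by_tissue):
            out.extend(self.reads(sex, "rna", tissue))
        return out


def simulate_world(cfg: SimConfig) -> SimulatedWorld:
    """Build the deterministic simulated world for a configuration."""
    return SimulatedWorld(cfg)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for p in pos:
        alts = [b for b in BASES if b != chars[p]]
        chars[p] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _emit_fragments(
    sources: list[tuple[str, str]],
    n_pairs_per_source: list[int],
    cfg: SimConfig,
    rng: np.random.Generator,
    prefix: str,
) -> list[ReadPair]:
    pairs: list[ReadPair] = []
    rl = cfg.read_len
    i = 0
    for (src_id, seq), n_pairs in zip(sources, n_pairs_per_source):
        if len(seq) < rl:
            continue
        for _ in range(n_pairs):
            frag_len = int(round(rng.normal(cfg.frag_len_mean, cfg.frag_len_sd)))
            frag_len = max(rl, min(frag_len, len(seq)))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            r1 = _add_errors(frag[:rl], cfg.error_rate, rng)
            r2 = _add_errors(revcomp(frag)[:rl], cfg.error_rate, rng)
            name = f"{prefix}|{src_id}|{start}|{i}"
            pairs.append((Read(name + "/1", r1), Read(name + "/2", r2)))
            i += 1
    return pairs


def emit_reads(
    world: SimulatedWorld, sex: str, datatype: str, tissue: str | None = None
) -> list[ReadPair]:
    """Generate one library of paired-end reads.

    Genomic libraries sample uniformly over a copy-number-expanded pool
    (autosomes ×2 in both sexes; X ×2 in females, ×1 in males; Y ×1 in
    males only), so autosomal depth equals ``genomic_depth`` and the male X
    sits at half of it. RNA libraries sample each expressed transcript at
    ``rna_depth × profile[tissue]``. Read names encode the source for
    debugging only; the pipeline never reads them.
    """
    cfg = world.cfg
    if sex not in ("male", "female"):
        raise KeyError(f"unknown sex {sex!r}")
    if datatype == "genomic":
        rng = _stream_rng(cfg.seed, f"genomic:{sex}")
        pool: list[tuple[str, str]] = []
        for sid in sorted(world.female_genome):
            copies = 2 if world.scaffold_class[sid] == "autosome" else (2 if sex == "female" else 1)
            pool.extend([(sid, world.female_genome[sid])] * copies)
        if sex == "male":
            pool.extend((sid, world.y_scaffolds[sid]) for sid in sorted(world.y_scaffolds))
        pool_len = sum(len(s) for _, s in pool)
        total_pairs = int(round(cfg.genomic_depth / 2 * pool_len / (2 * cfg.read_len)))
        lens = np.array([len(s) for _, s in pool], dtype=float)
        counts = rng.multinomial(total_pairs, lens / lens.sum())
        return _emit_fragments(pool, list(counts), cfg, rng, f"{sex}|genomic|na")
    if datatype == "rna":
        if tissue not in cfg.rna_depth_by_tissue:
            raise KeyError(f"unknown tissue {tissue!r}")
        rng = _stream_rng(cfg.seed, f"rna:{sex}:{tissue}")
        depth = cfg.rna_depth_by_tissue[tissue]
        sources, n_pairs = [], []
        for t in sorted(world.expressed_genes(sex), key=lambda t: t.gene_id):
            w = t.expression_profile.get(tissue, 0.0)
            if w <= 0:
                continue
            sources.append((t.gene_id, t.transcript))
            n_pairs.append(int(rng.poisson(depth * w * len(t.transcript) / (2 * cfg.read_len))))
        return _emit_fragments(sources, n_pairs, cfg, rng, f"{sex}|rna|{tissue}")
    raise KeyError(f"unknown datatype {datatype!r}")
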