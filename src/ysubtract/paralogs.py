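"""Paralog search, Ka/Ks divergence, and coverage-based sex-linkage calls.

For each Y candidate the translated peptide is searched against all six
reading frames of every female-genome scaffold (Smith–Waterman, BLOSUM62);
the best hit, if it clears the score and identity floors, defines the
candidate's closest paralog. The paralog's scaffold is then classified as
X-linked or autosomal from its library-normalized log2(male/female)
genomic depth ratio — X scaffolds sit near −1 (hemizygous in males),
autosomes near 0 — which in turn classifies the Y gene's origin:
an X-linked paralog marks an ancestral/X-derived gene, an autosomal
paralog a secondary acquisition.

Divergence between a Y gene and its paralog is estimated with the
Nei–Gojobori (1986) method: synonymous and nonsynonymous sites are counted
from codon degeneracy averaged over both sequences, differences are
averaged over all shortest substitution pathways per codon (pathways
through stop codons excluded), and both proportions receive the
Jukes–Cantor correction. Mutations to stop codons count as nonsynonymous
in the site tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .mapping import CoverageProfile
from .seqio import revcomp, translate

BASES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


# -- NG86 -------------------------------------------------------------------


def _codon_site_fractions(codon: str) -> float:
    """Synonymous site count of one codon (stop targets count nonsynonymous)."""
    aa = CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa and CODON_TABLE[alt] != "*":
                syn += 1
    return syn / 3.0


_SYN_SITES: dict[str, float] = {
    c: _codon_site_fractions(c) for c in CODON_TABLE if CODON_TABLE[c] != "*"
}


def _split_codons(seq: str, label: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"{label}: length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if CODON_TABLE.get(c) is None:
            raise ValueError(f"{label}: invalid codon {c!r} at codon {i}")
        if CODON_TABLE[c] == "*":
            raise ValueError(f"{label}: internal stop codon {c!r} at codon {i}")
    return codons


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences for one codon pair, averaged over all
    substitution orderings; orderings passing through a stop codon are
    excluded unless every ordering does."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != c2:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    valid = [(s, n) for b, s, n in paths if not b]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PAIR_DIFFS:
        _PAIR_DIFFS[key] = _pathway_diffs(c1, c2)
    return _PAIR_DIFFS[key]


def ng86_sites(seq: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one in-frame CDS."""
    codons = _split_codons(seq, "cds")
    s = sum(_SYN_SITES[c] for c in codons)
    return s, 3 * len(codons) - s


def ng86_counts(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """NG86 raw counts: (S sites, N sites, syn diffs, nonsyn diffs).

    Sites are averaged over the two sequences; differences averaged over
    substitution pathways per codon.
    """
    c1 = _split_codons(seq1, "cds_1")
    c2 = _split_codons(seq2, "cds_2")
    if len(c1) != len(c2):
        raise ValueError(f"sequences differ in codon count: {len(c1)} vs {len(c2)}")
    s1 = sum(_SYN_SITES[c] for c in c1)
    s2 = sum(_SYN_SITES[c] for c in c2)
    s_sites = (s1 + s2) / 2.0
    n_sites = 3 * len(c1) - s_sites
    sd = nd = 0.0
    for a, b in zip(c1, c2):
        ds, dn = _pair_diffs(a, b)
        sd += ds
        nd += dn
    return s_sites, n_sites, sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance from a raw proportion of differences."""
    if p < 0:
        raise ValueError("proportion must be ≥ 0")
    if p == 0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.inf
    return -0.75 * math.log(arg)


def kaks(y_cds: str, paralog_cds: str) -> tuple[float, float, float | None]:
    """Nei–Gojobori Ka, Ks and their ratio for an in-frame codon alignment.

    Inputs must be equal-length, gap-stripped, stop-free codon sequences.
    Ka/Ks is None when Ks = 0 (undefined, not infinity).
    """
    s_sites, n_sites, sd, nd = ng86_counts(y_cds, paralog_cds)
    ks = jukes_cantor(sd / s_sites) if s_sites > 0 else 0.0
    ka = jukes_cantor(nd / n_sites) if n_sites > 0 else 0.0
    ratio = ka / ks if ks > 0 and math.isfinite(ks) else None
    return ka, ks, ratio


# -- translated paralog search ---------------------------------------------


@dataclass
class ParalogPair:
    """A Y candidate linked to its closest female-genome paralog."""

    y_transcript_id: str
    paralog_scaffold_id: str
    paralog_span: tuple[int, int]  # 0-based half-open nucleotide span
    frame_strand: str
    aln_score: float
    pct_identity: float
    ka: float | None = None
    ks: float | None = None
    kaks: float | None = None
    scaffold_class: str | None = None


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _frames(scaffold: str):
    """Yield (strand, frame_offset, aa_sequence) for all 6 frames."""
    for strand, seq in (("+", scaffold), ("-", revcomp(scaffold))):
        for off in range(3):
            yield strand, off, translate(seq[off:])


# Karlin–Altschul parameters for gapped BLOSUM62 (open 11 / extend 1),
# used to put raw Smith–Waterman scores on the BLAST bit-score scale.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def bit_score(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)


def find_paralog(
    y_peptide: str,
    female_genome: dict[str, str],
    min_score: float = 50.0,
    min_identity: float = 0.40,
    y_transcript_id: str = "query",
) -> ParalogPair | None:
    """Best translated (6-frame Smith–Waterman) hit of a Y peptide in the
    female genome, or None below the score/identity floors.

    ``min_score`` is interpreted on the BLAST bit-score scale (Karlin–
    Altschul conversion of the raw BLOSUM62 Smith–Waterman score): a raw
    floor would admit the chance hits any genome-sized search produces.
    Ties broken by longer alignment, then lexicographic scaffold id.
    """
    if len(y_peptide) < 20:
        raise ValueError("peptide must be ≥ 20 aa")
    aligner = _make_aligner()
    best = None
    best_key = None
    for sid in sorted(female_genome):
        scaffold = female_genome[sid]
        for strand, off, aa in _frames(scaffold):
            if len(aa) < 10:
                continue
            score = aligner.score(aa, y_peptide)
            if bit_score(score) < min_score:
                continue
            aln = aligner.align(aa, y_peptide)[0]
            blocks = aln.aligned[0]
            t_aa_start, t_aa_end = int(blocks[0][0]), int(blocks[-1][1])
            ident = aligned = 0
            for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
                for k in range(te - ts):
                    aligned += 1
                    if aa[ts + k] == y_peptide[qs + k]:
                        ident += 1
            identity = ident / aligned if aligned else 0.0
            if identity < min_identity:
                continue
            n = len(scaffold)
            if strand == "+":
                span = (off + 3 * t_aa_start, off + 3 * t_aa_end)
            else:
                span = (n - (off + 3 * t_aa_end), n - (off + 3 * t_aa_start))
            key = (-score, -(t_aa_end - t_aa_start), sid)
            if best_key is None or key < best_key:
                best_key = key
                best = ParalogPair(
                    y_transcript_id, sid, span, f"{strand}{off}", bit_score(score), identity
                )
    return best


def paralog_codon_alignment(
    y_cds: str, pair: ParalogPair, female_genome: dict[str, str]
) -> tuple[str, str]:
    """Back-thread the protein alignment into a gap-stripped codon alignment.

    Aligns the Y peptide to the paralog peptide (extracted from the hit
    span) and returns the two concatenated codon sequences over columns
    where both peptides are aligned without gaps or stops.
    """
    scaffold = female_genome[pair.paralog_scaffold_id]
    sub = scaffold[pair.paralog_span[0] : pair.paralog_span[1]]
    if pair.frame_strand.startswith("-"):
        sub = revcomp(sub)
    y_pep = translate(y_cds)
    p_pep = translate(sub)
    aligner = _make_aligner()
    aln = aligner.align(p_pep, y_pep)[0]
    y_codons: list[str] = []
    p_codons: list[str] = []
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(te - ts):
            pc = sub[3 * (ts + k) : 3 * (ts + k) + 3]
            yc = y_cds[3 * (qs + k) : 3 * (qs + k) + 3]
            if len(pc) < 3 or len(yc) < 3:
                continue
            if CODON_TABLE.get(pc, "*") == "*" or CODON_TABLE.get(yc, "*") == "*":
                continue
            p_codons.append(pc)
            y_codons.append(yc)
    return "".join(y_codons), "".join(p_codons)


# -- coverage-based sex-linkage classification -------------------------------


@dataclass(frozen=True)
class ScaffoldClassCall:
    scaffold_id: str
    log2_ratio: float | None
    scaffold_class: str  # X / autosome / ambiguous / male_only
    x_max_log2: float
    auto_band: float


def classify_scaffold(
    profile: CoverageProfile, x_max_log2: float = -0.5, auto_band: float = 0.5
) -> ScaffoldClassCall:
    """Call a scaffold X-linked or autosomal from its normalized log2(M/F)
    depth ratio (X expected near −1, autosomes near 0)."""
    if profile.length < 1000:
        raise ValueError(f"scaffold {profile.target_id}: length < 1000 bp")
    if profile.male_only or profile.normalized_ratio is None:
        cls = "male_only" if profile.male_only else "ambiguous"
        return ScaffoldClassCall(profile.target_id, None, cls, x_max_log2, auto_band)
    r = profile.normalized_ratio
    if r < x_max_log2:
        cls = "X"
    elif abs(r) <= auto_band:
        cls = "autosome"
    else:
        cls = "ambiguous"
    return ScaffoldClassCall(profile.target_id, r, cls, x_max_log2, auto_band)


def classify_origin(
    pairs: dict[str, ParalogPair | None],
    scaffold_calls: dict[str, ScaffoldClassCall],
) -> dict[str, str]:
    """Per-transcript origin call from the paralog's scaffold class.

    X-linked paralog → the gene descends from the ancestral X/Y pair
    ("ancestral_X_derived"); autosomal paralog → secondary acquisition;
    no or ambiguous paralog → unknown.
    """
    out: dict[str, str] = {}
    for tid, pair in pairs.items():
        if pair is None:
            out[tid] = "unknown"
            continue
        call = scaffold_calls.get(pair.paralog_scaffold_id)
        if call is None:
            out[tid] = "unknown"
        elif call.scaffold_class == "X":
            out[tid] = "ancestral_X_derived"
        elif call.scaffold_class == "autosome":
            out[tid] = "autosomal_acquisition"
        else:
            out[tid] = "unknown"
    return out


def truncate_for_display(kaks_value: float | None, cap: float = 3.0) -> float | None:
    """Display convention for Ka/Ks: values above the cap plot at the cap."""
    if kaks_value is None:
        return None
    return min(kaks_value, cap)
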