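"""NG86 Ka/Ks against an independent pathway-enumeration oracle; paralog
search and coverage-based scaffold/origin classification."""

import itertools
import math

import numpy as np
import pytest

from ysubtract.mapping import CoverageProfile
from ysubtract.paralogs import (
    CODON_TABLE,
    ParalogPair,
    classify_origin,
    classify_scaffold,
    find_paralog,
    jukes_cantor,
    kaks,
    ng86_counts,
    ng86_sites,
    paralog_codon_alignment,
    truncate_for_display,
)
from ysubtract.seqio import longest_orf, orf_nucleotides, orf_peptide
from ysubtract.simulate import SimConfig, evolve_synonymous, random_cds, simulate_world
from conftest import small_config
from oracle_ng86 import oracle_counts

BASES = "ACGT"
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


# -- oracle equivalence -------------------------------------------------------


def test_ng86_equals_oracle_on_all_single_codon_pairs():
    """Exhaustive: every ordered pair of sense codons, exact equality."""
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            got = ng86_counts(c1, c2)
            want = oracle_counts(c1, c2)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-12), (c1, c2)


def test_ng86_equals_oracle_on_short_multicodon_pairs(rng):
    """2–3-codon sequences: per-codon additivity against the oracle."""
    for _ in range(200):
        n = int(rng.integers(2, 4))
        s1 = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))
        s2 = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))
        got, want = ng86_counts(s1, s2), oracle_counts(s1, s2)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-12)


def test_ng86_equals_oracle_on_random_100codon_pairs(rng):
    """100 random 100-codon pairs at ~5% divergence; counts exact, JC to 1e-12."""
    for _ in range(100):
        cds = random_cds(rng, 306)[3:-3]
        other = list(cds)
        n_mut = int(rng.integers(5, 20))
        for _ in range(n_mut):
            while True:
                pos = int(rng.integers(0, len(other)))
                alt = BASES[rng.integers(0, 4)]
                cand = other.copy()
                cand[pos] = alt
                codon = "".join(cand[pos - pos % 3 : pos - pos % 3 + 3])
                if CODON_TABLE[codon] != "*":
                    other = cand
                    break
        s2 = "".join(other)
        got, want = ng86_counts(cds, s2), oracle_counts(cds, s2)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-12)
        ka_g, ks_g, _ = kaks(cds, s2)
        s, n, sd, nd = want
        assert ks_g == pytest.approx(jukes_cantor(sd / s), abs=1e-12)
        assert ka_g == pytest.approx(jukes_cantor(nd / n), abs=1e-12)


# -- kaks contract ------------------------------------------------------------


def test_identical_sequences_have_zero_divergence_and_undefined_ratio():
    cds = "ATGAAACCCGGG"
    ka, ks, ratio = kaks(cds, cds)
    assert ka == 0.0 and ks == 0.0 and ratio is None


def test_single_synonymous_change():
    # Phe → Phe: no nonsynonymous signal; the lone synonymous site saturates
    ka, ks, _ = kaks("TTT", "TTC")
    assert ka == 0.0 and ks > 0.0


def test_single_nonsynonymous_change():
    ka, ks, ratio = kaks("TTT", "TGT")  # Phe → Cys
    assert ks == 0.0 and ka > 0.0 and ratio is None


@pytest.mark.parametrize("bad", ["ATGA", "ATGTAAGGG"])
def test_invalid_cds_rejected(bad):
    with pytest.raises(ValueError):
        kaks(bad, bad)


def test_ks_recovery_for_synonymous_only_divergence(rng):
    """JC-corrected Ks recovers the simulated synonymous divergence.

    3000 codons keep the Poisson noise on the event count (~1/√(dS))
    well inside the 15% band being asserted.
    """
    cds = random_cds(rng, 9003)[3:-3]
    for d in (0.1, 0.2, 0.3):
        evolved = evolve_synonymous(cds, d, rng)
        ka, ks, _ = kaks(cds, evolved)
        assert ka < 0.01
        assert ks == pytest.approx(d, rel=0.15)


def test_kaks_display_truncation():
    assert truncate_for_display(5.2) == 3.0
    assert truncate_for_display(1.7) == 1.7
    assert truncate_for_display(None) is None


# -- paralog search -----------------------------------------------------------


@pytest.fixture(scope="module")
def small_world():
    return simulate_world(small_config(seed=21))


def test_planted_paralog_found_on_correct_scaffold(small_world):
    t = small_world.truth["ya_01"]  # autosomal acquisition at 20% divergence
    orf = longest_orf(t.transcript)
    pair = find_paralog(orf_peptide(t.transcript, orf), small_world.female_genome)
    assert pair is not None
    assert pair.paralog_scaffold_id == t.paralog_scaffold
    assert pair.pct_identity >= 0.40 and pair.aln_score >= 50


def test_gene_without_homolog_finds_none(small_world):
    t = small_world.truth["yu_01"]
    orf = longest_orf(t.transcript)
    assert find_paralog(orf_peptide(t.transcript, orf), small_world.female_genome) is None


def test_identity_floor_suppresses_weak_hits(small_world):
    t = small_world.truth["ya_01"]
    orf = longest_orf(t.transcript)
    pep = orf_peptide(t.transcript, orf)
    pair = find_paralog(pep, small_world.female_genome)
    assert pair is not None
    assert find_paralog(pep, small_world.female_genome, min_identity=pair.pct_identity + 0.01) is None


def test_short_peptides_are_rejected():
    with pytest.raises(ValueError):
        find_paralog("MKF" * 5, {"s": "ACGT" * 100})


def test_codon_backthreading_recovers_planted_divergence(small_world):
    t = small_world.truth["ya_01"]
    orf = longest_orf(t.transcript)
    cds = orf_nucleotides(t.transcript, orf)
    pair = find_paralog(orf_peptide(t.transcript, orf), small_world.female_genome)
    y_cd, p_cd = paralog_codon_alignment(cds, pair, small_world.female_genome)
    assert len(y_cd) == len(p_cd) and len(y_cd) % 3 == 0
    ka, ks, ratio = kaks(y_cd, p_cd)
    # planted at 20% nt divergence with purifying bias: Ks > Ka > 0
    assert 0 < ka < ks


# -- scaffold and origin classification ---------------------------------------


def _prof(sid, ratio, length=2000, female_zero=False):
    return CoverageProfile(
        sid, length, 10.0, 0.0 if female_zero else 10.0, 1.0, 0.0 if female_zero else 1.0,
        None if female_zero else ratio, female_zero,
    )


@pytest.mark.parametrize(
    "ratio,expected",
    [(-1.02, "X"), (-0.95, "X"), (0.05, "autosome"), (-0.45, "autosome"), (-0.6, "X"), (0.8, "ambiguous")],
)
def test_scaffold_classification_bands(ratio, expected):
    call = classify_scaffold(_prof("s", ratio))
    assert call.scaffold_class == expected


def test_zero_female_depth_is_male_only():
    assert classify_scaffold(_prof("s", None, female_zero=True)).scaffold_class == "male_only"


def test_short_scaffolds_are_rejected():
    with pytest.raises(ValueError):
        classify_scaffold(_prof("s", -1.0, length=999))


def test_origin_calls_follow_paralog_scaffold_class():
    pairs = {
        "esc": ParalogPair("esc", "x1", (0, 300), "+0", 100.0, 0.8),
        "acq": ParalogPair("acq", "a1", (0, 300), "+0", 100.0, 0.8),
        "amb": ParalogPair("amb", "w1", (0, 300), "+0", 100.0, 0.8),
        "none": None,
    }
    calls = {
        "x1": classify_scaffold(_prof("x1", -1.0)),
        "a1": classify_scaffold(_prof("a1", 0.0)),
        "w1": classify_scaffold(_prof("w1", 0.8)),
    }
    out = classify_origin(pairs, calls)
    assert out == {
        "esc": "ancestral_X_derived",
        "acq": "autosomal_acquisition",
        "amb": "unknown",
        "none": "unknown",
    }


def test_origin_concordance_with_simulator_truth(default_world, scaffold_coverage):
    """Origin calls match the planted truth for genes with divergence ≤ 0.4."""
    world = default_world
    profiles = dict(scaffold_coverage[0][1])
    calls = {sid: classify_scaffold(p) for sid, p in profiles.items() if p.length >= 1000}
    expected_of = {"X_escapee": "ancestral_X_derived", "autosomal_acquisition": "autosomal_acquisition",
                   "recent_duplicate": "autosomal_acquisition"}
    n_ok = n_tot = 0
    for gid, t in world.y_gene_truth.items():
        if not t.spec.has_paralog or t.spec.divergence > 0.4:
            continue
        orf = longest_orf(t.transcript)
        pair = find_paralog(orf_peptide(t.transcript, orf), world.female_genome, y_transcript_id=gid)
        call = classify_origin({gid: pair}, calls)[gid]
        n_tot += 1
        n_ok += call == expected_of[t.spec.origin]
    assert n_tot >= 10
    assert n_ok / n_tot >= 0.95
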