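"""Simulator contracts: determinism, ploidy calibration, truth completeness."""

import math

import numpy as np
import pytest

from ysubtract.seqio import revcomp
from ysubtract.simulate import (
    ConfigError,
    SimConfig,
    YGeneSpec,
    emit_reads,
    evolve_synonymous,
    mutate_paralog,
    random_cds,
    simulate_world,
)
from conftest import small_config


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


# -- configuration validation ------------------------------------------------


@pytest.mark.parametrize(
    "overrides,field",
    [
        (dict(genomic_depth=0), "genomic_depth"),
        (dict(error_rate=0.2), "error_rate"),
        (dict(read_len=500, frag_len_mean=250), "read_len"),
        (dict(rna_depth_by_tissue={"head": -1}), "rna_depth_by_tissue"),
    ],
)
def test_invalid_config_names_the_field(overrides, field):
    with pytest.raises(ConfigError, match=field):
        SimConfig(**overrides).validate()


def test_gene_spec_invariants():
    with pytest.raises(ConfigError, match="divergence"):
        YGeneSpec("g", "recent_duplicate", divergence=0.05)  # must stay ≥98% identical
    with pytest.raises(ConfigError, match="divergence"):
        YGeneSpec("g", "unique", divergence=0.1)  # unique genes have no paralog
    with pytest.raises(ConfigError, match="origin"):
        YGeneSpec("g", "plasmid")


# -- sequence-level construction --------------------------------------------


def test_random_cds_is_single_orf(rng):
    cds = random_cds(rng, 300)
    assert cds.startswith("ATG") and cds.endswith("TAA")
    internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
    assert not any(c in ("TAA", "TAG", "TGA") for c in internal)


def test_mutate_paralog_hits_exact_divergence(rng):
    cds = random_cds(rng, 900)
    for d in (0.02, 0.05, 0.15):
        copy = mutate_paralog(cds, d, rng)
        assert _identity(cds, copy) == pytest.approx(1 - d, abs=1e-9)
        # ORF preserved: same start/stop, no internal stop created
        assert copy.startswith("ATG") and copy.endswith("TAA")
        internal = [copy[i : i + 3] for i in range(3, len(copy) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)


def test_recent_duplicate_copy_is_98pct_identical():
    cfg = small_config(seed=7)
    world = simulate_world(cfg)
    t = world.truth["yf_01"]
    paralog_unit = world.truth["par_yf_01"].transcript
    assert _identity(t.transcript, paralog_unit) == pytest.approx(0.98, abs=0.005)


# -- determinism and stream independence ------------------------------------


def test_same_seed_reproduces_reads_byte_identically():
    cfg = small_config(seed=3)
    w1, w2 = simulate_world(cfg), simulate_world(cfg)
    for sex, dt, tissue in [("male", "genomic", None), ("female", "rna", "head")]:
        r1, r2 = w1.reads(sex, dt, tissue), w2.reads(sex, dt, tissue)
        assert [(a.id, a.seq, b.id, b.seq) for a, b in r1] == [
            (a.id, a.seq, b.id, b.seq) for a, b in r2
        ]


def test_adding_a_tissue_does_not_perturb_other_streams():
    base = small_config(seed=3)
    more = small_config(seed=3, rna_depth_by_tissue={"head": 50.0, "gonad": 50.0, "carcass": 20.0})
    w1, w2 = simulate_world(base), simulate_world(more)
    r1 = w1.reads("male", "rna", "head")
    r2 = w2.reads("male", "rna", "head")
    assert [(a.seq, b.seq) for a, b in r1] == [(a.seq, b.seq) for a, b in r2]


def test_unknown_tissue_or_datatype_raise_lookup_errors(default_world):
    with pytest.raises(KeyError):
        emit_reads(default_world, "male", "rna", "antenna")
    with pytest.raises(KeyError):
        emit_reads(default_world, "male", "methylome")


# -- ploidy and depth calibration -------------------------------------------


def _depth_by_class(world, sex):
    """Mean depth per scaffold class, computed from read-name provenance."""
    bases = {}
    for a, b in world.reads(sex, "genomic"):
        src = a.id.split("|")[3]
        bases[src] = bases.get(src, 0) + len(a.seq) + len(b.seq)
    by_class = {}
    genome = world.male_genome
    for sid, n in bases.items():
        cls = world.scaffold_class[sid]
        by_class.setdefault(cls, [0, 0])
        by_class[cls][0] += n
        by_class[cls][1] += len(genome[sid])
    return {cls: n / ln for cls, (n, ln) in by_class.items()}


def test_hemizygous_x_gets_half_male_depth():
    cfg = small_config(seed=11, n_x_scaffolds=1, genomic_depth=20.0)
    world = simulate_world(cfg)
    male = _depth_by_class(world, "male")
    female = _depth_by_class(world, "female")
    assert male["X"] == pytest.approx(10.0, rel=0.15)
    assert female["X"] == pytest.approx(20.0, rel=0.15)
    assert male["autosome"] == pytest.approx(20.0, rel=0.15)
    assert female["autosome"] == pytest.approx(20.0, rel=0.15)


def test_read_count_matches_depth_length_formula():
    # depth × length / (2 × read_len) pairs per copy of a scaffold
    cfg = small_config(seed=13, genomic_depth=20.0, scaffold_len=10000)
    world = simulate_world(cfg)
    reads = world.reads("female", "genomic")
    per_scaffold = {}
    for a, b in reads:
        src = a.id.split("|")[3]
        per_scaffold[src] = per_scaffold.get(src, 0) + 2
    sid = "auto_01"
    expected = 20.0 * len(world.female_genome[sid]) / 100  # reads, both copies
    assert per_scaffold[sid] == pytest.approx(expected, rel=0.15)


def test_female_data_contain_no_y_sequence(default_world):
    y_ids = set(default_world.y_scaffolds)
    for a, b in default_world.reads("female", "genomic"):
        assert a.id.split("|")[3] not in y_ids
    female_expressed = {t.gene_id for t in default_world.expressed_genes("female")}
    assert not any(default_world.truth[g].chromosome_class == "Y" for g in female_expressed)


def test_error_free_reads_are_exact_substrings():
    cfg = small_config(seed=17, error_rate=0.0)
    world = simulate_world(cfg)
    genome = world.male_genome
    for a, b in world.reads("male", "genomic")[:200]:
        src = a.id.split("|")[3]
        assert a.seq in genome[src] or revcomp(a.seq) in genome[src]
        assert b.seq in genome[src] or revcomp(b.seq) in genome[src]


# -- coverage & expression calibration (empirical log-ratios) -----------------


def test_log2_depth_ratio_calibration(scaffold_coverage):
    """X scaffolds sit near −1, autosomes near 0, at 20× genomic depth."""
    for world, profiles in scaffold_coverage:
        for sid, prof in profiles.items():
            cls = world.scaffold_class[sid]
            assert prof.normalized_ratio is not None
            if cls == "X":
                assert -1.3 <= prof.normalized_ratio <= -0.7
            else:
                assert -0.3 <= prof.normalized_ratio <= 0.3


def test_expression_rank_order_follows_profile(default_world):
    """Realized per-tissue read output ranks as the expression profile ranks."""
    for tissue_pair in [("gonad", "head")]:
        hi, lo = tissue_pair
        counts = {t: {} for t in tissue_pair}
        for t in tissue_pair:
            for a, _ in default_world.reads("male", "rna", t):
                src = a.id.split("|")[3]
                counts[t][src] = counts[t].get(src, 0) + 1
        for gid, truth in default_world.y_gene_truth.items():
            w_hi, w_lo = truth.expression_profile[hi], truth.expression_profile[lo]
            if w_hi > 2 * w_lo:
                assert counts[hi].get(gid, 0) > counts[lo].get(gid, 0)


# -- truth completeness ------------------------------------------------------


def test_truth_covers_every_planted_gene(default_world):
    cfg_names = {g.name for g in default_world.cfg.y_gene_spec}
    assert cfg_names == set(default_world.y_gene_truth)
    for gid, t in default_world.y_gene_truth.items():
        assert t.spec is not None
        # planted Y transcript present verbatim on its Y scaffold
        assert t.transcript in default_world.y_scaffolds[t.scaffold]
        if t.spec.has_paralog:
            assert t.paralog_scaffold in default_world.female_genome
        else:
            assert t.paralog_scaffold is None


def test_truth_table_lists_origin_and_detectability(default_world):
    df = default_world.truth_table()
    assert set(df["transcript_id"]) == set(default_world.y_gene_truth)
    assert df["detectable"].sum() == 20


# -- synonymous evolution helper ---------------------------------------------


def test_evolve_synonymous_changes_no_amino_acid(rng):
    from ysubtract.seqio import translate

    cds = random_cds(rng, 600)[:-3]  # stop-free in-frame CDS
    evolved = evolve_synonymous(cds, 0.2, rng)
    assert translate(evolved) == translate(cds)
    assert evolved != cds
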