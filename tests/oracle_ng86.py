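"""Independent NG86 oracle: exhaustive enumeration of one-step mutations
(sites) and substitution pathways (differences). Shares only the genetic
code with the implementation it checks."""

import itertools

from ysubtract.paralogs import CODON_TABLE

BASES = "ACGT"

# pathways. Shares only the genetic code with the implementation.


def oracle_sites(codon):
    syn = 0
    for pos, alt in itertools.product(range(3), BASES):
        if alt == codon[pos]:
            continue
        mutant = codon[:pos] + alt + codon[pos + 1 :]
        if CODON_TABLE[mutant] != "*" and CODON_TABLE[mutant] == CODON_TABLE[codon]:
            syn += 1
    return syn / 3.0, 3 - syn / 3.0


def oracle_pathways(c1, c2):
    """All substitution orderings c1→c2 as (passes_stop, n_syn, n_nonsyn)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []

    def walk(cur, remaining, syn, nonsyn, blocked):
        if not remaining:
            results.append((blocked, syn, nonsyn))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            is_stop = CODON_TABLE[nxt] == "*" and nxt != c2
            is_syn = CODON_TABLE[nxt] == CODON_TABLE[cur]
            walk(
                nxt,
                [p for p in remaining if p != pos],
                syn + (1 if is_syn else 0),
                nonsyn + (0 if is_syn else 1),
                blocked or is_stop,
            )

    walk(c1, diffs, 0, 0, False)
    return results


def oracle_diffs(c1, c2):
    paths = oracle_pathways(c1, c2)
    valid = [(s, n) for b, s, n in paths if not b] or [(s, n) for _, s, n in paths]
    return (
        sum(s for s, _ in valid) / len(valid),
        sum(n for _, n in valid) / len(valid),
    )


def oracle_counts(seq1, seq2):
    c1 = [seq1[i : i + 3] for i in range(0, len(seq1), 3)]
    c2 = [seq2[i : i + 3] for i in range(0, len(seq2), 3)]
    s1 = sum(oracle_sites(c)[0] for c in c1)
    s2 = sum(oracle_sites(c)[0] for c in c2)
    sd = nd = 0.0
    for a, b in zip(c1, c2):
        ds, dn = oracle_diffs(a, b)
        sd += ds
        nd += dn
    s_sites = (s1 + s2) / 2
    return s_sites, 3 * len(c1) - s_sites, sd, nd


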