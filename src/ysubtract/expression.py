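"""Tissue expression quantification and testis-enrichment statistics.

TPM quantification counts fragments per transcript (best-target
assignment), divides by effective length and renormalizes each sample to
one million; heatmap-style comparison uses per-transcript (row) z-scores.
Overrepresentation of testis/accessory-gland-biased genes in a Y-linked
set relative to a genome-wide background is tested with a one-sided exact
binomial tail: with p0 the background proportion, P = P(X ≥ k_y),
X ~ Binomial(n_y, p0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assemble import TranscriptRecord
from .mapping import TargetIndex, effective_length
from .pipeline import count_fragments
from .seqio import ReadPair, longest_orf

TESTIS_TISSUES = frozenset({"testis", "accessory_gland"})


def quantify_tpm(
    records: Sequence[TranscriptRecord],
    rna_by_sample: Mapping[str, list[ReadPair]],
    frag_len_mean: float,
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """TPM matrix (transcripts × samples).

    TPM_i = (c_i / el_i) × 10⁶ / Σ_j (c_j / el_j), with c the fragment
    count and el the effective length. Transcripts with zero effective
    length get zero TPM.
    """
    if not records:
        raise ValueError("records must be non-empty")
    ids = [rec.id for rec in records]
    els = np.array([effective_length(rec.length, frag_len_mean) for rec in records], dtype=float)
    if not np.any(els > 0):
        raise ValueError("all effective lengths are zero; cannot quantify")
    index = TargetIndex({rec.id: rec.sequence for rec in records})
    cols = {}
    for sample in rna_by_sample:
        counts = count_fragments(rna_by_sample[sample], index, max_mismatches)
        c = np.array([counts.get(tid, 0) for tid in ids], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(els > 0, c / np.where(els > 0, els, 1.0), 0.0)
        total = rate.sum()
        cols[sample] = rate * 1e6 / total if total > 0 else rate
    return pd.DataFrame(cols, index=ids)


def row_zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row z-scores (mean 0, sd 1 with the n−1 denominator).

    Returns the normalized matrix and a boolean flag per row marking
    constant rows, which are set to all-zero.
    """
    if matrix.shape[1] < 2:
        raise ValueError("each row needs at least 2 samples")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    constant = sds == 0
    safe_sd = sds.replace(0, 1.0)
    z = matrix.sub(means, axis=0).div(safe_sd, axis=0)
    z[constant] = 0.0
    return z, constant


def coding_call(record_or_seq, min_orf_aa: int = 80) -> str:
    """'coding' iff the longest ORF (ATG..stop, either strand) is ≥ min_orf_aa."""
    seq = getattr(record_or_seq, "sequence", record_or_seq)
    orf = longest_orf(seq)
    return "coding" if orf is not None and orf.aa_len >= min_orf_aa else "noncoding"


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided exact binomial test for overrepresentation."""

    k_y: int
    n_y: int
    k_bg: int
    n_bg: int
    p0: float
    p_value: float


def binomial_enrichment(k_y: int, n_y: int, k_bg: int, n_bg: int) -> EnrichmentResult:
    """Exact upper-tail binomial P-value: P(X ≥ k_y), X ~ Bin(n_y, k_bg/n_bg)."""
    if n_y <= 0 or n_bg <= 0:
        raise ValueError("set sizes must be positive")
    if not (0 <= k_y <= n_y and 0 <= k_bg <= n_bg):
        raise ValueError("counts must satisfy 0 ≤ k ≤ n")
    p0 = k_bg / n_bg
    p_value = float(stats.binom.sf(k_y - 1, n_y, p0))
    return EnrichmentResult(k_y, n_y, k_bg, n_bg, p0, p_value)


def testis_bias_flags(
    matrix: pd.DataFrame,
    tissue_labels: Mapping[str, str],
    expr_present_min: float = 1.0,
) -> pd.DataFrame:
    """Per-transcript flags for male-tissue expression bias.

    ``max_in_testis_or_gland``: the highest-TPM sample is a testis or
    accessory-gland sample. ``exclusive_to_testis_and_gland``: TPM exceeds
    ``expr_present_min`` only in testis/accessory-gland samples (and in at
    least one of them). All-zero rows get both flags False.
    """
    unknown = [c for c in matrix.columns if c not in tissue_labels]
    if unknown:
        raise KeyError(f"no tissue label for sample(s): {unknown}")
    target_cols = [c for c in matrix.columns if tissue_labels[c] in TESTIS_TISSUES]
    if not target_cols:
        raise KeyError("tissue labels identify no testis/accessory-gland sample")
    other_cols = [c for c in matrix.columns if c not in target_cols]
    vals = matrix.to_numpy(dtype=float)
    max_flag = []
    excl_flag = []
    for i, tid in enumerate(matrix.index):
        row = matrix.iloc[i]
        if (row <= 0).all():
            max_flag.append(False)
            excl_flag.append(False)
            continue
        max_flag.append(row.idxmax() in target_cols)
        present_target = (row[target_cols] > expr_present_min).any()
        present_other = (row[other_cols] > expr_present_min).any() if other_cols else False
        excl_flag.append(bool(present_target and not present_other))
    return pd.DataFrame(
        {"max_in_testis_or_gland": max_flag, "exclusive_to_testis_and_gland": excl_flag},
        index=matrix.index,
    )
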