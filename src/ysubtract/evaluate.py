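"""Truth-vs-called evaluation of pipeline output on simulated worlds."""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import SeedIndex, best_local_hit
from .assemble import TranscriptRecord
from .simulate import SimulatedWorld


@dataclass
class ConfusionTable:
    """Gene-level recovery of planted Y genes by the candidate set.

    A planted gene counts as detected when some candidate aligns to its
    true transcript with score ≥ 50 at ≥ 95% identity (fragmented
    recovery still counts; the identity floor keeps matches unambiguous).
    """

    detected: dict[str, bool] = field(default_factory=dict)
    candidate_source: dict[str, str | None] = field(default_factory=dict)
    n_detectable: int = 0
    n_detected_detectable: int = 0
    false_candidates: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        if self.n_detectable == 0:
            return float("nan")
        return self.n_detected_detectable / self.n_detectable


def match_candidates(
    candidates: list[TranscriptRecord],
    world: SimulatedWorld,
    min_score: int = 50,
    min_identity: float = 0.95,
) -> ConfusionTable:
    """Assign each candidate to the planted gene it derives from (if any)
    and tabulate per-gene detection against the truth table."""
    truth_seqs = {t.gene_id: t.transcript for t in world.truth.values()}
    index = SeedIndex(truth_seqs)
    table = ConfusionTable()
    detected_y: set[str] = set()
    for rec in candidates:
        hit = best_local_hit(rec.sequence, index, min_score=min_score)
        src = hit.target_id if hit is not None and hit.identity >= min_identity else None
        table.candidate_source[rec.id] = src
        if src is None:
            table.false_candidates.append(rec.id)
        elif world.truth[src].chromosome_class == "Y":
            detected_y.add(src)
        else:
            table.false_candidates.append(rec.id)  # originates from an X/autosomal gene
    for gid, t in world.y_gene_truth.items():
        table.detected[gid] = gid in detected_y
        if t.spec.detectable:
            table.n_detectable += 1
            if gid in detected_y:
                table.n_detected_detectable += 1
    return table
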