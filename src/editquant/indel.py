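"""On-target indel-frequency quantification from amplicon sequencing.

Pipeline: merge each read pair, align the merged read to the amplicon
reference (affine-gap local alignment), keep alignments passing the mapping
-quality filter that overlap the target window — the region within
``half_window`` bp upstream or downstream of the predicted cleavage site,
endpoints inclusive (41 positions at the default 20) — and compute

    indel frequency = indel-containing reads / reads mapped to the window.

A read is indel-containing iff it carries at least one insertion or deletion
whose reference locus falls inside the window (for a deletion, any deleted
base; for an insertion, its anchor point). Substitutions never count. Reads
that fail to merge are excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Alignment, Scoring, align_to_reference, shuffled_decoy
from .errors import InputError, UndefinedStatisticError
from .reads import ReadPair, merge_pair

__all__ = ["IndelResult", "indel_frequency", "run_indel_pipeline"]


@dataclass(frozen=True)
class IndelResult:
    """Per-sample indel-frequency statistic."""

    window: tuple[int, int]  # inclusive endpoints
    n_mapped_in_window: int
    n_indel_reads: int

    @property
    def frequency(self) -> float:
        return self.n_indel_reads / self.n_mapped_in_window


def _overlaps_window(aln: Alignment, lo: int, hi: int) -> bool:
    return aln.ref_start <= hi and aln.ref_end > lo


def _indel_in_window(aln: Alignment, lo: int, hi: int) -> bool:
    for op, s, e in aln.indel_ref_loci():
        if op == "D" and s <= hi and e - 1 >= lo:
            return True
        if op == "I" and lo <= s <= hi:
            return True
    return False


def indel_frequency(
    alignments: list[Alignment],
    cleavage_pos: int,
    half_window: int = 20,
    mapq_min: int = 20,
) -> IndelResult:
    """The indel statistic over pre-computed alignments."""
    if half_window < 0:
        raise InputError("half_window must be >= 0")
    lo, hi = cleavage_pos - half_window, cleavage_pos + half_window
    n_mapped = 0
    n_indel = 0
    for aln in alignments:
        if aln.mapq_proxy < mapq_min or not _overlaps_window(aln, lo, hi):
            continue
        n_mapped += 1
        if _indel_in_window(aln, lo, hi):
            n_indel += 1
    if n_mapped == 0:
        raise UndefinedStatisticError("no reads mapped to the target window")
    return IndelResult((lo, hi), n_mapped, n_indel)


def run_indel_pipeline(
    pairs: list[ReadPair],
    ref: str,
    cleavage_pos: int,
    *,
    half_window: int = 20,
    mapq_min: int = 20,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    scoring: Scoring = Scoring(),
) -> tuple[IndelResult, list[dict]]:
    """Merge, align, and count; returns the statistic and a per-read audit trail."""
    if cleavage_pos < 0 or cleavage_pos > len(ref):
        raise InputError("cleavage_pos outside the reference")
    decoy = shuffled_decoy(ref)
    lo, hi = cleavage_pos - half_window, cleavage_pos + half_window
    alignments: list[Alignment] = []
    audit: list[dict] = []
    cache: dict[str, Alignment] = {}
    for pair in pairs:
        merged = merge_pair(pair, min_overlap, max_mismatch_frac)
        if not merged.merged:
            audit.append({"id": pair.id, "merged": False, "reason": merged.reason})
            continue
        aln = cache.get(merged.bases)
        if aln is None:
            aln = align_to_reference(merged.bases, ref, scoring, decoy=decoy)
            cache[merged.bases] = aln
        aln = Alignment(
            pair.id, aln.ref_start, aln.ref_end, aln.ops, aln.score,
            aln.n_matches, aln.query_length, aln.mapq_proxy,
        )
        alignments.append(aln)
        in_denom = aln.mapq_proxy >= mapq_min and _overlaps_window(aln, lo, hi)
        audit.append(
            {
                "id": pair.id,
                "merged": True,
                "mapq": aln.mapq_proxy,
                "cigar": aln.cigar(),
                "ops_in_window": [
                    (op, s, e)
                    for op, s, e in aln.indel_ref_loci()
                    if (op == "D" and s <= hi and e - 1 >= lo) or (op == "I" and lo <= s <= hi)
                ],
                "counted": in_denom,
                "indel": in_denom and _indel_in_window(aln, lo, hi),
            }
        )
    result = indel_frequency(alignments, cleavage_pos, half_window, mapq_min)
    return result, audit
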