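"""Read pairs, FASTQ IO, and overlap-based pair merging.

Pair merging re-implements the contract of read-assembly tools (PEAR-style):
find the maximal-scoring ungapped overlap between R1 and the reverse
complement of R2, subject to a minimum overlap length and a maximum mismatch
fraction, and take the higher-quality base at disagreements. Pairs that fail
to merge carry a failure reason and are excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from numba import njit

from .errors import InputError
from .seqs import revcomp

__all__ = ["ReadPair", "MergedRead", "merge_pair", "read_fastq_pairs", "write_fastq"]


@dataclass(frozen=True)
class ReadPair:
    """One FR-oriented paired-end read (bases + Phred+33 qualities)."""

    id: str
    r1: str
    q1: str
    r2: str
    q2: str

    def __post_init__(self) -> None:
        if len(self.r1) != len(self.q1) or len(self.r2) != len(self.q2):
            raise InputError(f"read {self.id}: bases/qualities length mismatch")
        if not self.r1 or not self.r2:
            raise InputError(f"read {self.id}: empty mate")


@dataclass(frozen=True)
class MergedRead:
    id: str
    bases: str
    qualities: str
    merged: bool
    merge_overlap: int = 0
    reason: str = ""


@njit(cache=True)
def _best_overlap(a, b, min_overlap):  # pragma: no cover - numba
    """Scan offsets of b (=revcomp R2) along a (=R1); score = matches - mismatches.

    Returns (best_score, offset, overlap_len, mismatches); offset -1 if none.
    """
    la, lb = a.shape[0], b.shape[0]
    best_score = -(1 << 30)
    best_off = -1
    best_len = 0
    best_mm = 0
    for off in range(0, la - min_overlap + 1):
        L = min(la - off, lb)
        if L < min_overlap:
            break
        score = 0
        mm = 0
        for k in range(L):
            if a[off + k] == b[k]:
                score += 1
            else:
                score -= 1
                mm += 1
        if score > best_score:
            best_score = score
            best_off = off
            best_len = L
            best_mm = mm
    return best_score, best_off, best_len, best_mm


def merge_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> MergedRead:
    """Merge an FR pair into a single consensus read via its best ungapped overlap."""
    from .seqs import encode

    rc2 = revcomp(pair.r2)
    qc2 = pair.q2[::-1]
    a = encode(pair.r1)
    b = encode(rc2)
    _, off, L, mm = _best_overlap(a, b, min_overlap)
    if off < 0:
        return MergedRead(pair.id, "", "", False, reason="no-overlap")
    if mm > max_mismatch_frac * L:
        return MergedRead(pair.id, "", "", False, reason="too-many-mismatches")
    head = pair.r1[:off]
    qhead = pair.q1[:off]
    mid = []
    qmid = []
    for k in range(L):
        b1, b2 = pair.r1[off + k], rc2[k]
        p1, p2 = pair.q1[off + k], qc2[k]
        if b1 == b2 or p1 >= p2:  # tie on quality -> R1 base
            mid.append(b1)
            qmid.append(max(p1, p2) if b1 == b2 else p1)
        else:
            mid.append(b2)
            qmid.append(p2)
    tail = rc2[L:]
    qtail = qc2[L:]
    return MergedRead(
        pair.id, head + "".join(mid) + tail, qhead + "".join(qmid) + qtail, True, L
    )


# ---------------------------------------------------------------------------
# FASTQ IO


def write_fastq(path, reads) -> None:
    """Write ``(id, bases, qualities)`` triples as 4-line Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, bases, quals in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{quals}\n")


def read_fastq_pairs(path_r1, path_r2) -> list[ReadPair]:
    """Read two parallel FASTQ files into ReadPairs (ids must agree)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs = []
    with open(path_r1) as f1, open(path_r2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            base1 = id1.split()[0]
            if base1 != id2.split()[0]:
                raise InputError(f"unpaired reads: {id1!r} vs {id2!r}")
            pairs.append(ReadPair(base1, s1.upper(), q1, s2.upper(), q2))
    return pairs
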