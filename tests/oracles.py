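"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations, written without reference to the
production code paths they check.
"""

from __future__ import annotations


def naive_site_scan(sequence: str, recognition: str, cut_offset: int) -> list[int]:
    """All-substrings scan for recognition-site cut positions."""
    k = len(recognition)
    return [
        i + cut_offset
        for i in range(len(sequence) - k + 1)
        if sequence[i : i + k] == recognition
    ]


def naive_affine_local_score(
    query: str, ref: str, match=1, mismatch=-4, gap_open=6, gap_extend=1
) -> int:
    """Full O(nm) affine-gap local-alignment score, three explicit matrices.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(query), len(ref)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = match if query[i - 1] == ref[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def enumerate_overlap_merges(r1: str, r2: str, min_overlap: int) -> list[tuple[int, int, str]]:
    """All candidate ungapped merges of R1 with revcomp(R2).

    Returns (score, offset, merged sequence) for every admissible offset,
    score = matches - mismatches over the overlap.
    """
    rc2 = naive_revcomp(r2)
    out = []
    for off in range(0, len(r1) - min_overlap + 1):
        L = min(len(r1) - off, len(rc2))
        if L < min_overlap:
            break
        score = sum(1 if r1[off + k] == rc2[k] else -1 for k in range(L))
        merged = r1[:off] + r1[off : off + L] + rc2[L:]
        out.append((score, off, merged))
    return out
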