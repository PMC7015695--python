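"""Synthetic edited-allele populations and library simulation.

Generates molecule populations with known truth labels (parental, cut-site
indel, HDR knock-in, NHEJ-captured vector fragment) and converts them into
errored paired-end reads for the two assays:

* amplicon deep sequencing of a window centered on the cleavage site
  (for indel-frequency calling), and
* the ligation-mediated UMI PCR (LMU-PCR) library: restriction digestion,
  UMI-tagged adapter ligation, and nested-primer-anchored read pairs
  (for HDR-integration quantification).

PCR (three rounds of touchdown in the wet protocol) is collapsed into a
single per-molecule duplication draw: the downstream analysis only needs the
duplicate structure, not cycle-accurate chemistry. Quality strings are flat
Phred encodings of the configured substitution rate.

Everything is a pure function of (inputs, seed); identical calls produce
byte-identical reads and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConstraintInfeasibleError, InputError, NoFragmentError
from .reads import ReadPair
from .reference import DonorModel, LocusModel, RestrictionEnzyme, VectorModel
from .reference import build_hdr_allele, ligation_fragment
from .seqs import BASES, revcomp

__all__ = [
    "AlleleMix",
    "EditedAllele",
    "SimConfig",
    "DEFAULT_ADAPTER",
    "simulate_alleles",
    "simulate_indel_reads",
    "simulate_lmu_library",
    "truth_table",
    "write_truth_table",
]

#: constant portion of the Y-adapter read 3' of the UMI on the adapter-side mate
DEFAULT_ADAPTER = "CTGAGCGGTCAT"

DEFAULT_FRAGMENT_WEIGHTS = {
    "ITR": 0.40,
    "TBG": 0.15,
    "hOTCco": 0.15,
    "polyA": 0.15,
    "SaCas9": 0.10,
    "other": 0.05,
}


@dataclass(frozen=True)
class AlleleMix:
    """Outcome-category fractions for the simulated allele population."""

    f_parental: float = 1.0
    f_indel: float = 0.0
    f_hdr: float = 0.0
    f_vector_fragment: float = 0.0
    #: categorical support for indel sizes (negative = deletion)
    indel_sizes: tuple[int, ...] = tuple(range(-20, 0)) + tuple(range(1, 21))
    fragment_source_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENT_WEIGHTS)
    )

    def __post_init__(self) -> None:
        fracs = (self.f_parental, self.f_indel, self.f_hdr, self.f_vector_fragment)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise InputError("mix fractions must be >= 0 and sum to 1")
        if 0 in self.indel_sizes:
            raise InputError("indel size 0 is not an indel")
        w = self.fragment_source_weights
        if any(v < 0 for v in w.values()) or (self.f_vector_fragment > 0 and not any(w.values())):
            raise InputError("fragment weights must be >= 0 with at least one positive")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.f_parental, self.f_indel, self.f_hdr, self.f_vector_fragment)


@dataclass(frozen=True)
class EditedAllele:
    """One simulated molecule with its truth label and edit detail."""

    id: str
    truth_label: str  # parental | indel | HDR | vector_fragment
    detail: dict
    sequence: str


@dataclass(frozen=True)
class SimConfig:
    """Library-preparation and sequencing parameters for both assays."""

    n_molecules: int = 1000
    read_length: int = 250
    #: the indel amplicon spans cut-halfwidth .. cut+halfwidth inclusive
    #: (default 216 -> a 433-bp amplicon)
    amplicon_halfwidth: int = 216
    umi_length: int = 8
    #: ("constant", k) or ("geometric", mean)
    duplication_dist: tuple = ("geometric", 5)
    sub_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    #: draw UMIs without replacement (used to isolate PCR-bias effects)
    unique_umis: bool = False
    fragment_length_range: tuple[int, int] = (10, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise InputError("n_molecules must be >= 1")
        if self.read_length < 50:
            raise InputError("read_length must be >= 50")
        for rate in (self.sub_error_rate, self.indel_error_rate):
            if not (0.0 <= rate <= 1.0):
                raise InputError("error rates must be in [0, 1]")
        kind = self.duplication_dist[0]
        if kind not in ("constant", "geometric"):
            raise InputError(f"unknown duplication distribution {kind!r}")


def _draw_duplication(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind, param = dist
    if kind == "constant":
        return np.full(n, int(param), dtype=np.int64)
    # geometric with mean `param`, support >= 1
    return rng.geometric(1.0 / float(param), size=n)


def _flat_quality(length: int, sub_rate: float) -> str:
    q = 40 if sub_rate <= 0 else min(40, round(-10.0 * math.log10(sub_rate)))
    return chr(q + 33) * length


_BASE_ORD = np.frombuffer("ACGT".encode(), dtype=np.uint8)
_ORD2CODE = np.zeros(256, dtype=np.uint8)
for _i, _o in enumerate(_BASE_ORD):
    _ORD2CODE[_o] = _i


def _apply_sub_errors_batch(
    seqs: list[str], rng: np.random.Generator, rate: float
) -> list[str]:
    """Substitution errors over a whole read batch in one vectorized pass."""
    if rate <= 0 or not seqs:
        return seqs
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).copy()
    idx = np.nonzero(rng.random(arr.size) < rate)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASE_ORD[(_ORD2CODE[arr[idx]] + shift) % 4]
    cat = arr.tobytes().decode()
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    return [cat[a:b] for a, b in zip(bounds, bounds[1:])]


def _apply_errors(seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> str:
    if sub_rate > 0:
        seq = _apply_sub_errors_batch([seq], rng, sub_rate)[0]
    if indel_rate > 0:
        out = []
        for c in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # 1-bp deletion
            out.append(c)
            if indel_rate / 2 <= r < indel_rate:
                out.append(BASES[rng.integers(4)])  # 1-bp insertion
        seq = "".join(out)
    return seq


# ---------------------------------------------------------------------------
# allele population


def _indel_allele(seq: str, cut: int, size: int, rng: np.random.Generator) -> tuple[str, dict]:
    if size < 0:
        d = -size
        start = cut - d // 2
        return seq[:start] + seq[start + d :], {"type": "del", "size": d, "start": start}
    ins = "".join(BASES[i] for i in rng.integers(0, 4, size=size))
    return seq[:cut] + ins + seq[cut:], {"type": "ins", "size": size, "bases": ins}


def _fragment_sources(
    donor: DonorModel, nuclease: VectorModel | None
) -> dict[str, str]:
    """Map classification label -> source sequence for NHEJ capture."""
    src = {
        "ITR": donor.feature_sequence("ITR_L"),
        "TBG": donor.feature_sequence("TBG"),
        "hOTCco": donor.feature_sequence("hOTCco"),
        "polyA": donor.feature_sequence("polyA"),
        "other": donor.feature_sequence("U6_sgRNA"),
    }
    if nuclease is not None:
        src["SaCas9"] = nuclease.feature_sequence("SaCas9")
    return src


def _vector_fragment_allele(
    seq: str,
    cut: int,
    sources: dict[str, str],
    labels: list[str],
    probs: np.ndarray,
    length_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[str, dict]:
    lo, hi = length_range
    for _ in range(100):
        label = labels[rng.choice(len(labels), p=probs)]
        feat = sources[label]
        top = min(hi, len(feat))
        if top < lo:
            continue
        length = int(rng.integers(lo, top + 1))
        start = int(rng.integers(0, len(feat) - length + 1))
        # a promoter fragment beginning at the cassette 5' end inserted at the
        # cut is molecularly identical to an HDR left junction; keep truth
        # labels identifiable (see methods note)
        if label == "TBG" and start < 5:
            continue
        frag = feat[start : start + length]
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            frag = revcomp(frag)
        detail = {"label": label, "start": start, "length": length, "orientation": orientation}
        return seq[:cut] + frag + seq[cut:], detail
    raise ConstraintInfeasibleError("could not draw a feasible vector fragment")


def simulate_alleles(
    locus: LocusModel,
    donor: DonorModel,
    mix: AlleleMix,
    n: int,
    seed: int,
    nuclease: VectorModel | None = None,
    fragment_length_range: tuple[int, int] = (10, 200),
) -> list[EditedAllele]:
    """Draw ``n`` edited alleles with multinomial category counts under ``mix``."""
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, mix.fractions)
    hdr_seq = build_hdr_allele(locus, donor) if counts[2] else ""
    sources = _fragment_sources(donor, nuclease)
    labels = [l for l in mix.fragment_source_weights if l in sources and mix.fragment_source_weights[l] > 0]
    if counts[3] and not labels:
        raise InputError("vector fragments requested but no usable fragment source")
    probs = None
    if labels:
        w = np.array([mix.fragment_source_weights[l] for l in labels], dtype=float)
        probs = w / w.sum()

    alleles: list[EditedAllele] = []
    cut = locus.cleavage_pos
    idx = 0
    for _ in range(counts[0]):
        alleles.append(EditedAllele(f"mol{idx:06d}", "parental", {}, locus.sequence))
        idx += 1
    for _ in range(counts[1]):
        size = int(mix.indel_sizes[rng.integers(len(mix.indel_sizes))])
        seq, detail = _indel_allele(locus.sequence, cut, size, rng)
        alleles.append(EditedAllele(f"mol{idx:06d}", "indel", detail, seq))
        idx += 1
    for _ in range(counts[2]):
        alleles.append(EditedAllele(f"mol{idx:06d}", "HDR", {"cassette": True}, hdr_seq))
        idx += 1
    for _ in range(counts[3]):
        seq, detail = _vector_fragment_allele(
            locus.sequence, cut, sources, labels, probs, fragment_length_range, rng,
        )
        alleles.append(EditedAllele(f"mol{idx:06d}", "vector_fragment", detail, seq))
        idx += 1
    return alleles


def truth_table(alleles: list[EditedAllele]) -> pd.DataFrame:
    import json

    return pd.DataFrame(
        {
            "id": [a.id for a in alleles],
            "truth_label": [a.truth_label for a in alleles],
            "detail": [json.dumps(a.detail, sort_keys=True) for a in alleles],
        }
    )


def write_truth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assay libraries


def simulate_indel_reads(
    alleles: list[EditedAllele],
    locus: LocusModel,
    config: SimConfig,
) -> list[ReadPair]:
    """Paired reads from the amplicon window centered on the cleavage site.

    Each allele contributes ``duplication_dist`` read pairs drawn from
    ``allele[cut-hw : cut+hw+1]`` (the window is taken in edited-allele
    coordinates: the left primer keeps its locus position, the cassette or
    indel shifts everything downstream of the cut). R1 reads the window
    forward, R2 reads it from the far end, FR-oriented.
    """
    rng = np.random.default_rng(config.seed)
    cut = locus.cleavage_pos
    hw = config.amplicon_halfwidth
    dups = _draw_duplication(rng, config.duplication_dist, len(alleles))
    ids: list[str] = []
    raw1: list[str] = []
    raw2: list[str] = []
    for allele, k in zip(alleles, dups):
        lo = max(0, cut - hw)
        hi = min(len(allele.sequence), cut + hw + 1)
        amp = allele.sequence[lo:hi]
        fwd = amp[: config.read_length]
        rev = revcomp(amp)[: config.read_length]
        for j in range(int(k)):
            ids.append(f"{allele.id}:{j}")
            raw1.append(fwd)
            raw2.append(rev)
    return _pairs_with_errors(ids, raw1, raw2, rng, config)


def _decode_umi(code: int, length: int) -> str:
    return "".join(BASES[(code >> (2 * i)) & 3] for i in range(length))


def _pairs_with_errors(
    ids: list[str],
    raw1: list[str],
    raw2: list[str],
    rng: np.random.Generator,
    config: SimConfig,
) -> list[ReadPair]:
    """Apply sequencing errors to raw read batches and assemble ReadPairs."""
    half = len(raw1)
    seqs = _apply_sub_errors_batch(raw1 + raw2, rng, config.sub_error_rate)
    if config.indel_error_rate > 0:
        seqs = [_apply_errors(s, rng, 0.0, config.indel_error_rate) for s in seqs]
    qual_cache: dict[int, str] = {}

    def qual(n: int) -> str:
        q = qual_cache.get(n)
        if q is None:
            q = _flat_quality(n, config.sub_error_rate)
            qual_cache[n] = q
        return q

    return [
        ReadPair(rid, s1, qual(len(s1)), s2, qual(len(s2)))
        for rid, s1, s2 in zip(ids, seqs[:half], seqs[half:])
    ]


def _draw_umis(rng: np.random.Generator, n: int, length: int, unique: bool) -> list[str]:
    space = 4**length
    if not unique:
        return [_decode_umi(int(c), length) for c in rng.integers(0, space, size=n)]
    # ``unique`` isolates PCR-bias effects: UMIs are drawn without replacement
    # from a single-parity-check code over GF(4) (last base = -sum of the
    # others mod 4), giving pairwise Hamming distance >= 2 so directional
    # deduplication is unambiguous.
    if n > 4 ** (length - 1):
        raise InputError("too many molecules for unambiguous unique UMIs")
    prefixes = rng.choice(4 ** (length - 1), size=n, replace=False)
    umis = []
    for code in prefixes:
        code = int(code)
        digits = [(code >> (2 * i)) & 3 for i in range(length - 1)]
        digits.append((-sum(digits)) % 4)
        umis.append("".join(BASES[d] for d in digits))
    return umis


def simulate_lmu_library(
    alleles: list[EditedAllele],
    enzyme: RestrictionEnzyme,
    locus: LocusModel,
    config: SimConfig,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """LMU-PCR library: digestion, UMI tagging, duplication, paired reads.

    For each allele the ligation fragment (GSP3 primer to the first downstream
    restriction cut) is tagged with a fresh random UMI and sequenced as
    ``duplication_dist`` read pairs: R1 starts at the GSP3 primer, R2 starts
    at the adapter/UMI end (``[UMI][adapter][fragment, reverse strand]``).
    Alleles whose fragment no longer contains the intact primer site are
    dropped and recorded as unrecoverable in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    gsp3_seq = locus.gsp3_sequence
    umis = _draw_umis(rng, len(alleles), config.umi_length, config.unique_umis)
    dups = _draw_duplication(rng, config.duplication_dist, len(alleles))
    ids: list[str] = []
    raw1: list[str] = []
    raw2: list[str] = []
    rows = []
    for allele, umi, k in zip(alleles, umis, dups):
        try:
            frag = ligation_fragment(
                allele.sequence, enzyme, locus.gsp3_site, locus.gsp3_strand
            )
            recovered = frag.startswith(gsp3_seq)
        except NoFragmentError:
            frag = ""
            recovered = False
        rows.append(
            {
                "id": allele.id,
                "umi": umi,
                "truth_label": allele.truth_label,
                "fragment_length": len(frag),
                "recovered": recovered,
            }
        )
        if not recovered:
            continue
        r2_insert_len = config.read_length - config.umi_length - len(config.adapter)
        fwd = frag[: config.read_length]
        rev = umi + config.adapter + revcomp(frag)[:r2_insert_len]
        for j in range(int(k)):
            ids.append(f"{allele.id}:{j}")
            raw1.append(fwd)
            raw2.append(rev)
    pairs = _pairs_with_errors(ids, raw1, raw2, rng, config)
    return pairs, pd.DataFrame(rows)
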