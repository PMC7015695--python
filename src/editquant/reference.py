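"""Reference models: target locus, donor/nuclease vectors, restriction digestion.

This module builds the synthetic sequence universe the rest of the package
operates on: a target locus with a single nuclease cleavage site flanked by
homology arms, a donor vector carrying a promoter-transgene-polyA cassette
between the same arms, the knock-in (HDR) allele, and the restriction-anchored
ligation fragments that the LMU-PCR assay sequences.

Coordinates are 0-based half-open throughout; restriction cut positions are
between-base offsets (a cut at position ``p`` splits ``s`` into ``s[:p]`` and
``s[p:]``). The nuclease (SaCas9) is modeled as a blunt cutter ``cut_offset``
bases 5' of the PAM (default 3).

All builders are pure functions of their parameters and a seed: the same call
always returns the same sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConstraintInfeasibleError, InputError, ModelError, NoFragmentError
from .seqs import check_dna, random_dna, revcomp

__all__ = [
    "Interval",
    "Feature",
    "RestrictionEnzyme",
    "HAEIII",
    "TAQI",
    "DEFAULT_ENZYMES",
    "LocusModel",
    "VectorModel",
    "DonorModel",
    "find_restriction_sites",
    "digest",
    "build_synthetic_locus",
    "build_donor_vector",
    "build_nuclease_vector",
    "build_hdr_allele",
    "cassette_sequence",
    "ligation_fragment",
    "write_fasta",
    "read_fasta",
]

FEATURE_LABELS = frozenset(
    {"ITR", "U6_sgRNA", "HA_L", "TBG", "hOTCco", "polyA", "HA_R", "SaCas9", "other"}
)


@dataclass(frozen=True)
class Interval:
    """Half-open 0-based interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ModelError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class Feature:
    """A named, stranded interval on a vector sequence."""

    name: str
    label: str
    interval: Interval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.label not in FEATURE_LABELS:
            raise ModelError(f"unknown feature label {self.label!r}")
        if self.strand not in "+-":
            raise ModelError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A type II restriction enzyme with a blunt/offset cut inside its site."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        check_dna(self.recognition, name=f"{self.name} recognition")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ModelError("cut_offset outside recognition site")


#: HaeIII, GG^CC: blunt cutter, 4-bp palindromic site.
HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
#: TaqI, T^CGA: 4-bp palindromic site (sticky ends; end-repair is assumed).
TAQI = RestrictionEnzyme("TaqI", "TCGA", 1)

DEFAULT_ENZYMES = {"HaeIII": HAEIII, "TaqI": TAQI}


@dataclass(frozen=True)
class LocusModel:
    """The target locus: sequence plus editing and assay landmarks.

    The cut occurs between ``cleavage_pos - 1`` and ``cleavage_pos``; the two
    homology arms abut the cut. ``gsp3_site`` is the landing site of the
    innermost nested primer of the LMU-PCR assay and lies inside one arm.
    """

    name: str
    sequence: str
    cleavage_pos: int
    protospacer_interval: Interval
    pam_interval: Interval
    left_arm: Interval
    right_arm: Interval
    gsp3_site: Interval
    gsp3_strand: str = "+"

    def __post_init__(self) -> None:
        check_dna(self.sequence, name="locus sequence")
        if self.left_arm.end != self.cleavage_pos or self.right_arm.start != self.cleavage_pos:
            raise ModelError("homology arms must abut the cleavage position")
        if len(self.left_arm) != len(self.right_arm):
            raise ModelError("homology arms must have equal length")
        arm = self.left_arm if self.gsp3_site.end <= self.cleavage_pos else self.right_arm
        if not (arm.start <= self.gsp3_site.start and self.gsp3_site.end <= arm.end):
            raise ModelError("gsp3_site must lie entirely within one homology arm")

    @property
    def arm_length(self) -> int:
        return len(self.left_arm)

    @property
    def gsp3_sequence(self) -> str:
        seq = self.sequence[self.gsp3_site.start : self.gsp3_site.end]
        return seq if self.gsp3_strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class VectorModel:
    """A vector sequence with named features."""

    name: str
    sequence: str
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        check_dna(self.sequence, name=f"{self.name} sequence")
        for f in self.features:
            if f.interval.end > len(self.sequence):
                raise ModelError(f"feature {f.name} outside sequence bounds")

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise ModelError(f"no feature named {name!r} on {self.name}")

    def feature_sequence(self, name: str) -> str:
        f = self.feature(name)
        seq = self.sequence[f.interval.start : f.interval.end]
        return seq if f.strand == "+" else revcomp(seq)


DONOR_FEATURE_ORDER = ("ITR_L", "U6_sgRNA", "HA_L", "TBG", "hOTCco", "polyA", "HA_R", "ITR_R")


@dataclass(frozen=True)
class DonorModel(VectorModel):
    """The donor vector: U6-sgRNA and promoter-transgene-polyA cassette between arms.

    ``targeted`` records whether the vector carries the protospacer for
    nuclease self-cleavage (the untargeted control lacks the 20/21-nt target
    sequence but is otherwise identical).
    """

    targeted: bool = True

    def __post_init__(self) -> None:
        super().__post_init__()
        names = [f.name for f in self.features]
        if tuple(names) != DONOR_FEATURE_ORDER:
            raise ModelError(f"donor features must be {DONOR_FEATURE_ORDER}, got {names}")
        ivs = [f.interval for f in self.features]
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ModelError("donor features overlap")
        tbg, hotc, pa = (self.feature(n).interval for n in ("TBG", "hOTCco", "polyA"))
        if not (tbg.end == hotc.start and hotc.end == pa.start):
            raise ModelError("TBG-hOTCco-polyA cassette must be contiguous")

    @property
    def cassette_interval(self) -> Interval:
        return Interval(self.feature("TBG").interval.start, self.feature("polyA").interval.end)


# ---------------------------------------------------------------------------
# restriction scanning / digestion


def find_restriction_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut positions of ``enzyme`` on the forward strand of ``sequence``.

    Overlapping occurrences are all reported; positions are strictly
    increasing between-base offsets. Both default enzymes are palindromic, so
    forward-strand scanning is exhaustive (non-palindromic enzymes would need
    a reverse-strand scan; documented limitation).
    """
    check_dna(sequence)
    cuts = []
    start = 0
    while True:
        i = sequence.find(enzyme.recognition, start)
        if i < 0:
            break
        cuts.append(i + enzyme.cut_offset)
        start = i + 1  # overlapping occurrences
    return cuts


def digest(sequence: str, enzyme: RestrictionEnzyme) -> list[str]:
    """Split ``sequence`` at every cut position; concatenation is conserved."""
    cuts = find_restriction_sites(sequence, enzyme)
    bounds = [0, *cuts, len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# synthetic locus / vector construction

_PAM = "TTGAAT"  # SaCas9 NNGRRT-compatible PAM planted 3' of the cut
_PROTOSPACER_LEN = 21


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def _mask_unwanted_sites(
    seq: list[str],
    region: Interval,
    enzymes: list[RestrictionEnzyme],
    planted: set[int],
    protected: set[int],
    rng: np.random.Generator,
    max_rounds: int = 200,
) -> None:
    """Point-mutate away recognition-site occurrences inside ``region`` that
    do not start at a ``planted`` position, avoiding ``protected`` columns."""
    for _ in range(max_rounds):
        dirty = False
        text = "".join(seq)
        for enz in enzymes:
            start = region.start
            while True:
                i = text.find(enz.recognition, start, region.end)
                if i < 0 or i + len(enz.recognition) > region.end:
                    break
                if i not in planted:
                    free = [p for p in range(i, i + len(enz.recognition)) if p not in protected]
                    if not free:
                        raise ConstraintInfeasibleError(
                            "cannot mask recognition site overlapping protected bases"
                        )
                    p = free[rng.integers(len(free))]
                    choices = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = choices[rng.integers(3)]
                    dirty = True
                    text = "".join(seq)
                start = i + 1
        if not dirty:
            return
    raise ConstraintInfeasibleError("site masking did not converge")


def build_synthetic_locus(
    arm_length: int = 900,
    seed: int = 0,
    enzyme_layout: dict[RestrictionEnzyme, int] | None = None,
    *,
    flank: int = 100,
    cut_offset: int = 3,
    gsp3_offset: int = 120,
    gsp3_length: int = 20,
    name: str = "synthetic_locus",
) -> LocusModel:
    """Construct a synthetic target locus with planted assay landmarks.

    Parameters
    ----------
    arm_length
        Length of each homology arm (default 900, i.e. 0.9-kb arms).
    enzyme_layout
        Map enzyme -> distance (bp) of the planted cut site from the cleavage
        position; one site is planted in each arm at that distance, and no
        other occurrence of the recognition sequence survives within the arms
        (rejection masking). Defaults place HaeIII at 870 and TaqI at 850 so
        the parental and knock-in ligation fragments come out near 1 kb with
        relatively similar sizes.
    gsp3_offset
        Distance from the cleavage position back to the 5' end of the nested
        (GSP3) primer site. Must leave the primer inside the left arm and
        close enough to the cut that a 250-bp read crosses the junction.
    """
    if arm_length < 100:
        raise InputError("arm_length must be >= 100")
    if enzyme_layout is None:
        enzyme_layout = {HAEIII: 870, TAQI: 850}
    for enz, dist in enzyme_layout.items():
        if not (len(enz.recognition) < dist < arm_length):
            raise InputError(
                f"{enz.name} distance {dist} must be within (len(site), arm_length)"
            )
    if not (gsp3_length < gsp3_offset <= arm_length):
        raise InputError("gsp3_offset must place the primer inside the left arm")

    rng = np.random.default_rng(seed)
    total = flank + 2 * arm_length + flank
    cleavage = flank + arm_length
    seq = list(random_dna(rng, total))

    # protospacer spans the cut; PAM sits cut_offset bases 3' of it
    proto = Interval(cleavage + cut_offset - _PROTOSPACER_LEN, cleavage + cut_offset)
    pam = Interval(proto.end, proto.end + len(_PAM))
    _plant(seq, pam.start, _PAM)

    planted: set[int] = set()
    protected: set[int] = set(range(pam.start, pam.end))
    for enz, dist in enzyme_layout.items():
        for cut in (cleavage - dist, cleavage + dist):
            start = cut - enz.cut_offset
            if start < flank or start + len(enz.recognition) > flank + 2 * arm_length:
                raise InputError(f"{enz.name} site at distance {dist} falls outside the arms")
            _plant(seq, start, enz.recognition)
            planted.add(start)
            protected.update(range(start, start + len(enz.recognition)))

    arms = Interval(flank, flank + 2 * arm_length)
    _mask_unwanted_sites(seq, arms, list(enzyme_layout), planted, protected, rng)

    return LocusModel(
        name=name,
        sequence="".join(seq),
        cleavage_pos=cleavage,
        protospacer_interval=proto,
        pam_interval=pam,
        left_arm=Interval(flank, cleavage),
        right_arm=Interval(cleavage, cleavage + arm_length),
        gsp3_site=Interval(cleavage - gsp3_offset, cleavage - gsp3_offset + gsp3_length),
        gsp3_strand="+",
    )


_DONOR_LENGTHS = {"ITR": 145, "U6_sgRNA": 250, "TBG": 400, "hOTCco": 650, "polyA": 200}


def build_donor_vector(
    locus: LocusModel,
    seed: int = 1,
    cassette_site_layout: dict[RestrictionEnzyme, int] | None = None,
    *,
    targeted: bool = True,
    name: str = "donor_vector",
) -> DonorModel:
    """Construct the donor vector: ITR-U6.sgRNA-[HA_L-TBG.hOTCco.pA-HA_R]-ITR.

    The homology arms are copied verbatim from the locus. One cut site per
    enzyme is planted inside the cassette (``cassette_site_layout`` maps
    enzyme -> cut offset from cassette start; defaults HaeIII 830, TaqI 910)
    and all other occurrences within the cassette, and any occurrence created
    at the arm/cassette junctions of the knock-in allele, are masked so the
    knock-in ligation fragment is uniquely determined.
    """
    if cassette_site_layout is None:
        cassette_site_layout = {HAEIII: 830, TAQI: 910}
    rng = np.random.default_rng(seed)

    ha_l = locus.sequence[locus.left_arm.start : locus.left_arm.end]
    ha_r = locus.sequence[locus.right_arm.start : locus.right_arm.end]
    u6 = random_dna(rng, _DONOR_LENGTHS["U6_sgRNA"])
    if targeted:
        proto = locus.sequence[locus.protospacer_interval.start : locus.protospacer_interval.end]
        u6 = u6[:100] + proto + u6[100 + len(proto) :]
    parts = {
        "ITR_L": random_dna(rng, _DONOR_LENGTHS["ITR"]),
        "U6_sgRNA": u6,
        "HA_L": ha_l,
        "TBG": random_dna(rng, _DONOR_LENGTHS["TBG"]),
        "hOTCco": random_dna(rng, _DONOR_LENGTHS["hOTCco"]),
        "polyA": random_dna(rng, _DONOR_LENGTHS["polyA"]),
        "HA_R": ha_r,
        "ITR_R": random_dna(rng, _DONOR_LENGTHS["ITR"]),
    }

    # assemble, then mask the cassette and knock-in junctions
    seq: list[str] = []
    features: list[Feature] = []
    pos = 0
    for fname in DONOR_FEATURE_ORDER:
        label = {"ITR_L": "ITR", "ITR_R": "ITR", "HA_L": "HA_L", "HA_R": "HA_R"}.get(fname, fname)
        piece = parts[fname]
        features.append(Feature(fname, label, Interval(pos, pos + len(piece))))
        seq.extend(piece)
        pos += len(piece)

    cas_start = features[3].interval.start  # TBG
    cas_end = features[5].interval.end  # polyA
    cassette_len = cas_end - cas_start
    enzymes = list(cassette_site_layout)
    planted: set[int] = set()
    protected: set[int] = set()
    for enz, off in cassette_site_layout.items():
        if not (len(enz.recognition) < off < cassette_len - len(enz.recognition)):
            raise InputError(f"{enz.name} cassette cut offset {off} outside cassette")
        start = cas_start + off - enz.cut_offset
        _plant(seq, start, enz.recognition)
        planted.add(start)
        protected.update(range(start, start + len(enz.recognition)))
    _mask_unwanted_sites(seq, Interval(cas_start, cas_end), enzymes, planted, protected, rng)

    # Knock-in junction constraints, may only touch cassette bases (the arms
    # are locus sequence): (a) no recognition site may span an arm|cassette
    # junction of the HDR allele; (b) the junctions must be alignment-sharp —
    # the first/last cassette base may not continue the parental sequence
    # across the cut, or the locus alignment of a junction read would wobble
    # into the cassette.
    k = max(len(e.recognition) for e in enzymes)
    for _ in range(100):
        bad = False
        if seq[cas_start] == ha_r[0]:
            choices = [b for b in "ACGT" if b != ha_r[0]]
            seq[cas_start] = choices[rng.integers(len(choices))]
            bad = True
        if seq[cas_end - 1] == ha_l[-1]:
            choices = [b for b in "ACGT" if b != ha_l[-1]]
            seq[cas_end - 1] = choices[rng.integers(len(choices))]
            bad = True
        cassette = "".join(seq[cas_start:cas_end])
        left_j = ha_l[-k:] + cassette[:k]
        right_j = cassette[-k:] + ha_r[:k]
        for enz in enzymes:
            if enz.recognition in left_j:
                i = rng.integers(1, min(k, 3))  # early cassette base, not the first
                choices = [b for b in "ACGT" if b != seq[cas_start + i]]
                seq[cas_start + i] = choices[rng.integers(3)]
                bad = True
            if enz.recognition in right_j:
                i = rng.integers(1, min(k, 3))
                choices = [b for b in "ACGT" if b != seq[cas_end - 1 - i]]
                seq[cas_end - 1 - i] = choices[rng.integers(3)]
                bad = True
        if bad:
            _mask_unwanted_sites(
                seq, Interval(cas_start, cas_end), enzymes, planted, protected, rng
            )
            continue
        break
    else:
        raise ConstraintInfeasibleError("could not satisfy junction constraints")

    return DonorModel(name=name, sequence="".join(seq), features=tuple(features), targeted=targeted)


def build_nuclease_vector(seed: int = 2, *, name: str = "nuclease_vector") -> VectorModel:
    """A minimal nuclease (SaCas9) vector: ITR-promoter-SaCas9-polyA-ITR.

    Only used as a source of classification references and simulated NHEJ
    capture fragments; its sequences are synthetic and independent of the
    donor so SaCas9-derived fragments are distinguishable.
    """
    rng = np.random.default_rng(seed)
    pieces = [
        ("ITR_L", "ITR", random_dna(rng, 145)),
        ("promoter", "other", random_dna(rng, 300)),
        ("SaCas9", "SaCas9", random_dna(rng, 600)),
        ("polyA", "polyA", random_dna(rng, 200)),
        ("ITR_R", "ITR", random_dna(rng, 145)),
    ]
    seq = ""
    feats = []
    for fname, label, piece in pieces:
        feats.append(Feature(fname, label, Interval(len(seq), len(seq) + len(piece))))
        seq += piece
    return VectorModel(name=name, sequence=seq, features=tuple(feats))


def cassette_sequence(donor: DonorModel) -> str:
    """The TBG-hOTCco-polyA insert (U6-sgRNA and ITRs excluded)."""
    iv = donor.cassette_interval
    return donor.sequence[iv.start : iv.end]


def build_hdr_allele(locus: LocusModel, donor: DonorModel) -> str:
    """The knock-in allele: cassette inserted seamlessly at the cleavage position."""
    cassette = cassette_sequence(donor)
    ha_l = donor.feature_sequence("HA_L")
    ha_r = donor.feature_sequence("HA_R")
    if ha_l != locus.sequence[locus.left_arm.start : locus.left_arm.end] or ha_r != locus.sequence[
        locus.right_arm.start : locus.right_arm.end
    ]:
        raise ModelError("donor homology arms do not match the locus arms")
    return locus.sequence[: locus.cleavage_pos] + cassette + locus.sequence[locus.cleavage_pos :]


def ligation_fragment(
    allele: str,
    enzyme: RestrictionEnzyme,
    gsp3_site: Interval,
    gsp3_strand: str = "+",
) -> str:
    """The molecule LMU-PCR amplifies: primer 5' end to the nearest downstream cut.

    On the "+" strand the fragment runs rightward from the primer start to the
    first cut at/after the primer 3' end; on the "-" strand it runs leftward
    from the primer (and is returned reverse-complemented, primer first).
    """
    check_dna(allele)
    if gsp3_site.end > len(allele):
        raise InputError("gsp3_site outside allele")
    cuts = find_restriction_sites(allele, enzyme)
    if gsp3_strand == "+":
        downstream = [c for c in cuts if c >= gsp3_site.end]
        if not downstream:
            raise NoFragmentError(f"no {enzyme.name} cut downstream of the primer")
        return allele[gsp3_site.start : downstream[0]]
    upstream = [c for c in cuts if c <= gsp3_site.start]
    if not upstream:
        raise NoFragmentError(f"no {enzyme.name} cut downstream of the primer (- strand)")
    return revcomp(allele[upstream[-1] : gsp3_site.end])


# ---------------------------------------------------------------------------
# model serialization


def locus_to_json(locus: LocusModel, path) -> None:
    """Persist a LocusModel (sequence + landmarks) as JSON."""
    import json

    data = {
        "name": locus.name,
        "sequence": locus.sequence,
        "cleavage_pos": locus.cleavage_pos,
        "protospacer_interval": [locus.protospacer_interval.start, locus.protospacer_interval.end],
        "pam_interval": [locus.pam_interval.start, locus.pam_interval.end],
        "left_arm": [locus.left_arm.start, locus.left_arm.end],
        "right_arm": [locus.right_arm.start, locus.right_arm.end],
        "gsp3_site": [locus.gsp3_site.start, locus.gsp3_site.end],
        "gsp3_strand": locus.gsp3_strand,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def locus_from_json(path) -> LocusModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return LocusModel(
        name=d["name"],
        sequence=d["sequence"],
        cleavage_pos=d["cleavage_pos"],
        protospacer_interval=Interval(*d["protospacer_interval"]),
        pam_interval=Interval(*d["pam_interval"]),
        left_arm=Interval(*d["left_arm"]),
        right_arm=Interval(*d["right_arm"]),
        gsp3_site=Interval(*d["gsp3_site"]),
        gsp3_strand=d["gsp3_strand"],
    )


# ---------------------------------------------------------------------------
# FASTA IO (Biopython)


def write_fasta(path, records) -> None:
    """Write ``(id, sequence)`` pairs (or a mapping) to a FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    if hasattr(records, "items"):
        records = records.items()
    recs = [SeqRecord(Seq(s), id=str(i), description="") for i, s in records]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}
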