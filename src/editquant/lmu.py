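"""LMU-PCR quantification: UMI molecules, filters, classification, HDR percentage.

The ligation-mediated UMI PCR assay counts unique genomic molecules spanning
the nuclease cut. Analysis steps:

1. extract the UMI from the adapter-side mate and trim adapter bases;
2. collapse PCR duplicates into unique molecules via a directional UMI
   network (UMIs at Hamming distance 1 merge when the larger count >=
   2 x smaller - 1), consensus by per-column majority;
3. align each consensus to the target locus and filter on (a) mapping
   quality >= 20, (b) aligned-portion length >= 60 bp (HaeIII assay) or
   >= 55 bp (TaqI assay), (c) consensus starting with the GSP3 primer
   sequence plus a homology-arm prefix;
4. classify each surviving molecule: < 10 bp of unaligned (soft-clipped)
   sequence -> "mOTC locus"; otherwise realign the unaligned portion to the
   element panel (HDR junctions, ITR, SaCas9, polyA, hOTCco, TBG, other
   vector) and take the best qualifying hit;
5. HDR percentage = 100 x HDR molecules / total molecules after filtering.

Because every retained read begins at the GSP3 primer, the locus alignment
uses the primer-anchored reference window, and the alignment start position
that would normally partition UMI groups is a single constant here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, Scoring, align_to_reference, local_align, shuffled_decoy
from .errors import InputError, UndefinedStatisticError
from .reads import ReadPair, merge_pair
from .reference import DonorModel, LocusModel, RestrictionEnzyme, VectorModel, cassette_sequence
from .seqs import revcomp

__all__ = [
    "AdapterSpec",
    "UmiMolecule",
    "ElementPanel",
    "MoleculeClass",
    "HdrResult",
    "MIN_ALIGNED_BY_ASSAY",
    "build_element_panel",
    "extract_umi_and_trim",
    "group_unique_molecules",
    "filter_molecules",
    "classify_molecule",
    "hdr_percentage",
    "run_lmu_pipeline",
]

#: aligned-portion length thresholds per digestion assay
MIN_ALIGNED_BY_ASSAY = {"HaeIII": 60, "TaqI": 55}

#: tie precedence for classification (earlier wins on equal score)
CATEGORY_PRECEDENCE = ["HDR", "hOTCco", "TBG", "polyA", "ITR", "SaCas9", "other_vector"]

FILTER_REASONS = ("mapq", "length", "primer_prefix")


@dataclass(frozen=True)
class AdapterSpec:
    """Layout of the adapter-side mate: [UMI][adapter][insert]."""

    adapter: str
    umi_length: int = 8
    #: tolerated adapter mismatches: 1 per 10 adapter bases (ceil)
    max_mismatch_per10: int = 1


@dataclass
class UmiMolecule:
    """A UMI-collapsed unique molecule."""

    umi: str
    consensus: str
    read_count: int
    position: int = 0  # alignment start; constant (primer-anchored) in this assay
    alignment: Alignment | None = None

    @property
    def unaligned_portion(self) -> str:
        """Maximal terminal soft-clipped segment of the consensus."""
        if self.alignment is None:
            return ""
        lead, trail = self.alignment.leading_clip, self.alignment.trailing_clip
        if trail >= lead:
            return self.consensus[len(self.consensus) - trail :] if trail else ""
        return self.consensus[:lead]


@dataclass(frozen=True)
class ElementPanel:
    """Classification references for unaligned portions.

    ``junction_offsets`` marks, for the HDR junction references, the position
    of the arm|cassette boundary: a hit only counts as HDR evidence if it
    contains that boundary (distinguishing true junctions from NHEJ-captured
    cassette-element fragments that merely resemble one side of it).
    """

    references: dict[str, str]
    junction_offsets: dict[str, int] = field(default_factory=dict)

    def category(self, ref_name: str) -> str:
        return "HDR" if ref_name in self.junction_offsets else ref_name


def build_element_panel(
    locus: LocusModel,
    donor: DonorModel,
    nuclease: VectorModel | None = None,
    junction_halfwidth: int = 150,
) -> ElementPanel:
    """The reference panel: the two expected arm-cassette junctions (+-150 bp
    around each boundary of the knock-in allele) plus the vector elements."""
    cassette = cassette_sequence(donor)
    j = junction_halfwidth
    left_arm = locus.sequence[locus.left_arm.start : locus.left_arm.end]
    right_arm = locus.sequence[locus.right_arm.start : locus.right_arm.end]
    refs = {
        "HDR_left": left_arm[-j:] + cassette[:j],
        "HDR_right": cassette[-j:] + right_arm[:j],
        "ITR": donor.feature_sequence("ITR_L"),
        "polyA": donor.feature_sequence("polyA"),
        "hOTCco": donor.feature_sequence("hOTCco"),
        "TBG": donor.feature_sequence("TBG"),
        "other_vector": donor.feature_sequence("U6_sgRNA"),
    }
    if nuclease is not None:
        refs["SaCas9"] = nuclease.feature_sequence("SaCas9")
    offsets = {"HDR_left": j, "HDR_right": j}
    return ElementPanel(refs, offsets)


@dataclass(frozen=True)
class MoleculeClass:
    """Exactly one category per molecule; filtered molecules carry a reason."""

    category: str  # mOTC_locus | HDR | ITR | SaCas9 | polyA | hOTCco | TBG |
    # other_vector | unclassified | filtered_out
    filter_reason: str = ""
    best_hit: str = ""
    clip_length: int = 0


@dataclass(frozen=True)
class HdrResult:
    assay: str
    counts: dict[str, int]
    total_after_filtering: int

    @property
    def hdr_percent(self) -> float:
        return 100.0 * self.counts.get("HDR", 0) / self.total_after_filtering


# ---------------------------------------------------------------------------
# UMI extraction and grouping


def _hamming(a: str, b: str) -> int:
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def extract_umi_and_trim(pair: ReadPair, spec: AdapterSpec) -> tuple[str, ReadPair] | None:
    """Locate the adapter on the adapter-side mate (R2), excise the UMI, trim.

    Returns ``None`` when the adapter cannot be found at the tolerated
    mismatch level (the pair is excluded upstream with a logged reason).
    """
    ad = spec.adapter
    tol = spec.max_mismatch_per10 * -(-len(ad) // 10)  # ceil(len/10) mismatches
    best_pos, best_mm = -1, tol + 1
    lo = max(0, spec.umi_length - 2)
    hi = min(len(pair.r2) - len(ad), spec.umi_length + 2)
    for p in range(lo, hi + 1):
        mm = _hamming(pair.r2[p : p + len(ad)], ad)
        if mm < best_mm:
            best_pos, best_mm = p, mm
    if best_pos < 0 or best_mm > tol:
        return None
    umi = pair.r2[max(0, best_pos - spec.umi_length) : best_pos]
    insert_start = best_pos + len(ad)
    if insert_start >= len(pair.r2) or not umi:
        return None
    trimmed = ReadPair(
        pair.id,
        pair.r1,
        pair.q1,
        pair.r2[insert_start:],
        pair.q2[insert_start:],
    )
    return umi, trimmed


def _umi_networks(counts: dict[str, int]) -> dict[str, str]:
    """Directional adjacency clustering; returns umi -> cluster root."""
    order = sorted(counts, key=lambda u: (-counts[u], u))
    root: dict[str, str] = {}
    by_umi = set(counts)
    for u in order:
        best_parent = None
        for i in range(len(u)):
            for b in "ACGT":
                if b == u[i]:
                    continue
                v = u[:i] + b + u[i + 1 :]
                if v in by_umi and v in root and counts[v] >= 2 * counts[u] - 1:
                    if best_parent is None or counts[v] > counts[best_parent]:
                        best_parent = v
        root[u] = root[best_parent] if best_parent is not None else u
    return root


def _column_majority(seqs: list[str]) -> str:
    if len(seqs) == 1:
        return seqs[0]
    length = max(len(s) for s in seqs)
    out = []
    for i in range(length):
        votes: dict[str, int] = {}
        for s in seqs:
            if i < len(s):
                votes[s[i]] = votes.get(s[i], 0) + 1
        out.append(max(votes, key=lambda b: (votes[b], b)))
    return "".join(out)


def group_unique_molecules(
    tagged_reads: list[tuple[str, str]], position: int = 0
) -> list[UmiMolecule]:
    """Collapse ``(umi, read sequence)`` records into unique molecules.

    Reads sharing a directional-network UMI cluster become one molecule with
    a per-column majority consensus. Singletons are allowed.
    """
    counts: dict[str, int] = {}
    by_umi: dict[str, list[str]] = {}
    for umi, seq in tagged_reads:
        counts[umi] = counts.get(umi, 0) + 1
        by_umi.setdefault(umi, []).append(seq)
    root = _umi_networks(counts)
    clusters: dict[str, list[str]] = {}
    for umi, seqs in by_umi.items():
        clusters.setdefault(root[umi], []).extend(seqs)
    mols = []
    for rep in sorted(clusters):
        seqs = clusters[rep]
        mols.append(UmiMolecule(rep, _column_majority(seqs), len(seqs), position))
    return mols


# ---------------------------------------------------------------------------
# filtering and classification


def filter_molecules(
    mols: list[UmiMolecule],
    assay: str,
    gsp3_with_arm_prefix: str,
    mapq_min: int = 20,
    min_aligned: dict[str, int] | None = None,
    primer_length: int | None = None,
    arm_prefix_mismatch: int = 1,
) -> tuple[list[UmiMolecule], list[tuple[UmiMolecule, str]]]:
    """Partition molecules into (kept, filtered-with-reason).

    The first failing rule in the order mapq, length, primer_prefix is
    recorded. ``gsp3_with_arm_prefix`` is the GSP3 primer sequence followed
    by a stretch of homology arm; the primer portion must match exactly and
    the arm portion with at most ``arm_prefix_mismatch`` mismatches.
    """
    if assay not in MIN_ALIGNED_BY_ASSAY and min_aligned is None:
        raise InputError(f"unknown assay {assay!r}")
    thresholds = min_aligned or MIN_ALIGNED_BY_ASSAY
    if primer_length is None:
        primer_length = max(len(gsp3_with_arm_prefix) - 10, 1)
    kept: list[UmiMolecule] = []
    dropped: list[tuple[UmiMolecule, str]] = []
    for mol in mols:
        if mol.alignment is None or mol.alignment.mapq_proxy < mapq_min:
            dropped.append((mol, "mapq"))
            continue
        if mol.alignment.aligned_query_length < thresholds[assay]:
            dropped.append((mol, "length"))
            continue
        primer = gsp3_with_arm_prefix[:primer_length]
        arm = gsp3_with_arm_prefix[primer_length:]
        head = mol.consensus[: len(gsp3_with_arm_prefix)]
        if (
            len(head) < len(gsp3_with_arm_prefix)
            or head[:primer_length] != primer
            or _hamming(head[primer_length:], arm) > arm_prefix_mismatch
        ):
            dropped.append((mol, "primer_prefix"))
            continue
        kept.append(mol)
    return kept, dropped


#: alignment-wobble tolerance at the junction boundary (bases); sequencing
#: errors near the junction can shift where the locus alignment hands over
JUNCTION_SLACK = 3


def _hit_is_junction_anchored(
    aln, ref_name: str, ref_len: int, panel: ElementPanel, orient: str
) -> bool:
    """Is this hit genuine junction evidence, not a lone cassette element?

    For the left (arm|cassette) junction reference the arm side of a real
    junction read is consumed by the locus alignment, so the clip must begin
    at the cassette start: the hit's reference start lies within
    ``JUNCTION_SLACK`` of the junction offset (hit end, for the reverse
    orientation). For the right (cassette|arm) junction reference the clip
    must genuinely cross the boundary with sequence on both sides. Either
    way, a captured fragment internal to one element never qualifies.
    """
    j = panel.junction_offsets[ref_name]
    left_style = ref_name.endswith("_left")
    if orient == "-":
        j = ref_len - j
        # in reverse-complement coordinates the cassette side of the left
        # junction precedes the boundary, so the hit must END at it
        if left_style:
            return abs(aln.ref_end - j) <= JUNCTION_SLACK
        return aln.ref_start <= j - JUNCTION_SLACK and aln.ref_end >= j + JUNCTION_SLACK
    if left_style:
        return abs(aln.ref_start - j) <= JUNCTION_SLACK
    return aln.ref_start <= j - JUNCTION_SLACK and aln.ref_end >= j + JUNCTION_SLACK


def _qualifying_hit(
    clip: str,
    ref_name: str,
    ref: str,
    panel: ElementPanel,
    scoring: Scoring,
    min_identity: float,
    min_coverage: float,
    min_len: int,
) -> tuple[int, str] | None:
    """Best qualifying alignment of ``clip`` against ``ref`` in either
    orientation; returns (score, orientation) or None.

    A hit qualifies when identity >= min_identity, it is anchored at the clip
    5' end (query start <= 2) or covers >= min_coverage of the clip, and it
    aligns at least ``min_len`` clip bases. Hits on junction references must
    additionally contain the junction boundary.
    """
    best: tuple[int, str] | None = None
    for orient, oriented_ref in (("+", ref), ("-", revcomp(ref))):
        aln = local_align(clip, oriented_ref, scoring)
        if aln.score <= 0:
            continue
        if aln.identity < min_identity or aln.aligned_query_length < min_len:
            continue
        coverage = aln.aligned_query_length / len(clip)
        if coverage < min_coverage and aln.query_start > 2:
            continue
        if ref_name in panel.junction_offsets:
            if not _hit_is_junction_anchored(aln, ref_name, len(ref), panel, orient):
                continue
        if best is None or aln.score > best[0]:
            best = (aln.score, orient)
    return best


def classify_molecule(
    mol: UmiMolecule,
    assay: str,
    panel: ElementPanel,
    min_unaligned: int = 10,
    scoring: Scoring = Scoring(),
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
) -> MoleculeClass:
    """Assign one category to a filtered molecule.

    Molecules with < ``min_unaligned`` bp of unaligned sequence are the
    unmodified (or merely indel-bearing) target locus. Longer unaligned
    portions — terminal soft clips, or internal insertions >= min_unaligned —
    are aligned to every panel reference in both orientations; the best-
    scoring qualifying reference wins, with precedence
    HDR > hOTCco > TBG > polyA > ITR > SaCas9 > other_vector on score ties.
    """
    if not mol.consensus:
        raise InputError("molecule has empty consensus")
    if mol.alignment is None:
        raise InputError("molecule must be aligned before classification")
    clip = mol.unaligned_portion
    if len(clip) < min_unaligned:
        ins = [
            seq
            for _, seq in mol.alignment.insertion_sequences(mol.consensus)
            if len(seq) >= min_unaligned
        ]
        if not ins:
            return MoleculeClass("mOTC_locus", clip_length=len(clip))
        clip = max(ins, key=len)
    hits: list[tuple[int, int, str]] = []  # (-score, precedence, ref_name)
    for ref_name, ref in panel.references.items():
        hit = _qualifying_hit(
            clip, ref_name, ref, panel, scoring, min_identity, min_coverage, min_unaligned
        )
        if hit is not None:
            cat = panel.category(ref_name)
            hits.append((-hit[0], CATEGORY_PRECEDENCE.index(cat), ref_name))
    if not hits:
        return MoleculeClass("unclassified", clip_length=len(clip))
    hits.sort()
    _, prec, ref_name = hits[0]
    return MoleculeClass(CATEGORY_PRECEDENCE[prec], best_hit=ref_name, clip_length=len(clip))


def hdr_percentage(classes: list[MoleculeClass], assay: str) -> HdrResult:
    """HDR percentage and the full category composition."""
    counts: dict[str, int] = {}
    for c in classes:
        if c.category == "filtered_out":
            continue
        counts[c.category] = counts.get(c.category, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError("no molecules after filtering")
    return HdrResult(assay, counts, total)


# ---------------------------------------------------------------------------
# pipeline


def run_lmu_pipeline(
    pairs: list[ReadPair],
    locus: LocusModel,
    panel: ElementPanel,
    enzyme: RestrictionEnzyme,
    *,
    adapter_spec: AdapterSpec,
    arm_prefix_length: int = 10,
    mapq_min: int = 20,
    min_unaligned: int = 10,
    scoring: Scoring = Scoring(),
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    window_pad: int = 30,
) -> tuple[HdrResult, list[dict]]:
    """Full LMU-PCR analysis of one sample; returns (result, per-molecule audit).

    The consensus of each molecule is aligned against the primer-anchored
    reference window (every valid molecule begins at the GSP3 primer, and the
    primer-prefix filter enforces this); molecules are then filtered,
    classified, and summarized into the HDR percentage.
    """
    assay = enzyme.name
    # 1) UMI extraction + merge (read pairs from ~1-kb fragments rarely merge;
    #    the GSP3-side mate then carries all classification signal)
    tagged: list[tuple[str, str]] = []
    n_adapter_fail = 0
    for pair in pairs:
        got = extract_umi_and_trim(pair, adapter_spec)
        if got is None:
            n_adapter_fail += 1
            continue
        umi, trimmed = got
        merged = merge_pair(trimmed, min_overlap, max_mismatch_frac)
        tagged.append((umi, merged.bases if merged.merged else trimmed.r1))

    # 2) unique molecules
    mols = group_unique_molecules(tagged, position=locus.gsp3_site.start)

    # 3) primer-anchored locus alignment
    gsp3 = locus.gsp3_site
    max_len = max((len(m.consensus) for m in mols), default=0)
    w_lo = max(0, gsp3.start - window_pad)
    w_hi = min(len(locus.sequence), gsp3.start + max_len + window_pad)
    window = locus.sequence[w_lo:w_hi]
    decoy = shuffled_decoy(window) if window else ""
    cache: dict[str, Alignment] = {}
    for mol in mols:
        aln = cache.get(mol.consensus)
        if aln is None:
            aln = align_to_reference(
                mol.consensus, window, scoring, decoy=decoy, ref_offset=w_lo
            )
            cache[mol.consensus] = aln
        mol.alignment = aln

    gsp3_with_arm = locus.sequence[gsp3.start : gsp3.end + arm_prefix_length]
    if locus.gsp3_strand == "-":
        gsp3_with_arm = revcomp(locus.sequence[gsp3.start - arm_prefix_length : gsp3.end])
    kept, dropped = filter_molecules(mols, assay, gsp3_with_arm, mapq_min)

    classes: list[MoleculeClass] = []
    audit: list[dict] = []
    for mol, reason in dropped:
        audit.append(
            {
                "umi": mol.umi,
                "read_count": mol.read_count,
                "class": "filtered_out",
                "filter_reason": reason,
            }
        )
    class_cache: dict[str, MoleculeClass] = {}
    for mol in kept:
        mc = class_cache.get(mol.consensus)
        if mc is None:
            mc = classify_molecule(mol, assay, panel, min_unaligned, scoring)
            class_cache[mol.consensus] = mc
        classes.append(mc)
        audit.append(
            {
                "umi": mol.umi,
                "read_count": mol.read_count,
                "class": mc.category,
                "clip_length": mc.clip_length,
                "best_hit": mc.best_hit,
            }
        )
    result = hdr_percentage(classes, assay)
    return result, audit
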