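"""LMU-PCR pipeline: UMI handling, filters, classification, HDR statistic."""

import collections

import numpy as np
import pytest

from editquant import (
    HAEIII,
    TAQI,
    AlleleMix,
    SimConfig,
    cassette_sequence,
    hdr_sample,
    simulate_alleles,
    simulate_lmu_library,
)
from editquant.align import Alignment, align_to_reference
from editquant.errors import InputError, UndefinedStatisticError
from editquant.lmu import (
    AdapterSpec,
    MoleculeClass,
    UmiMolecule,
    classify_molecule,
    extract_umi_and_trim,
    filter_molecules,
    group_unique_molecules,
    hdr_percentage,
    run_lmu_pipeline,
)
from editquant.reads import ReadPair
from editquant.seqs import random_dna, revcomp

SPEC = AdapterSpec("CTGAGCGGTCAT", 8)


def _pair(r2_bases):
    r1 = "ACGT" * 10
    return ReadPair("p", r1, "I" * len(r1), r2_bases, "I" * len(r2_bases))


class TestUmiExtraction:
    def test_clean_adapter(self, rng):
        insert = random_dna(rng, 60)
        got = extract_umi_and_trim(_pair("ACGTACGT" + SPEC.adapter + insert), SPEC)
        assert got is not None
        umi, trimmed = got
        assert umi == "ACGTACGT" and trimmed.r2 == insert

    def test_missing_adapter_excluded(self, rng):
        assert extract_umi_and_trim(_pair(random_dna(rng, 80)), SPEC) is None

    def test_one_substitution_tolerated(self, rng):
        """Hamming-scan oracle: adapter with one error is still located."""
        insert = random_dna(rng, 60)
        mutated = "A" + SPEC.adapter[1:] if SPEC.adapter[0] != "A" else "C" + SPEC.adapter[1:]
        got = extract_umi_and_trim(_pair("TTTTAAAA" + mutated + insert), SPEC)
        assert got is not None and got[0] == "TTTTAAAA" and got[1].r2 == insert


class TestGrouping:
    def test_identical_umis_collapse(self):
        reads = [("ACGTACGT", "AAAACCCC")] * 3
        mols = group_unique_molecules(reads)
        assert len(mols) == 1
        assert mols[0].read_count == 3 and mols[0].consensus == "AAAACCCC"

    def test_directional_merge_rule(self):
        reads = [("ACGTACGT", "AAAA")] * 9 + [("ACGTACGA", "AAAA")]
        assert len(group_unique_molecules(reads)) == 1  # 9 >= 2*1 - 1
        reads = [("ACGTACGT", "AAAA")] * 2 + [("TTTTTTTT", "AAAA")] * 2
        assert len(group_unique_molecules(reads)) == 2  # distance > 1

    def test_balanced_counts_stay_separate(self):
        reads = [("ACGTACGT", "AAAA")] * 5 + [("ACGTACGA", "AAAA")] * 5
        assert len(group_unique_molecules(reads)) == 2  # 5 < 2*5 - 1

    def test_consensus_majority_corrects_errors(self):
        reads = [("ACGTACGT", "AAAACCCC"), ("ACGTACGT", "AAAACCCC"), ("ACGTACGT", "AATACCCC")]
        assert group_unique_molecules(reads)[0].consensus == "AAAACCCC"


def _stub_molecule(consensus, aligned_len, mapq):
    ops = [("M", aligned_len)]
    if aligned_len < len(consensus):
        ops.append(("S", len(consensus) - aligned_len))
    aln = Alignment("m", 0, aligned_len, ops, aligned_len, aligned_len, len(consensus), mapq)
    return UmiMolecule("AAAAAAAA", consensus, 1, alignment=aln)


class TestFilters:
    def test_toy_partition_matches_hand_count(self, locus):
        """2 mapq failures, 1 length failure, 3 passes -> (3 kept, 3 dropped)."""
        g = locus.gsp3_site
        prefix = locus.sequence[g.start : g.end + 10]
        good = locus.sequence[g.start : g.start + 120]
        mols = [
            _stub_molecule(good, 120, mapq=5),
            _stub_molecule(good, 120, mapq=19),
            _stub_molecule(good, 45, mapq=60),
            _stub_molecule(good, 120, mapq=60),
            _stub_molecule(good, 90, mapq=60),
            _stub_molecule(good, 61, mapq=60),
        ]
        kept, dropped = filter_molecules(mols, "HaeIII", prefix)
        assert (len(kept), len(dropped)) == (3, 3)
        reasons = collections.Counter(r for _, r in dropped)
        assert reasons == {"mapq": 2, "length": 1}

    def test_assay_specific_length_threshold(self, locus):
        g = locus.gsp3_site
        prefix = locus.sequence[g.start : g.end + 10]
        mol58 = _stub_molecule(locus.sequence[g.start : g.start + 58], 58, mapq=60)
        assert filter_molecules([mol58], "TaqI", prefix)[0]  # >= 55 passes
        kept, dropped = filter_molecules([mol58], "HaeIII", prefix)
        assert not kept and dropped[0][1] == "length"

    def test_primer_prefix_rule(self, locus):
        g = locus.gsp3_site
        prefix = locus.sequence[g.start : g.end + 10]
        wrong = "T" if prefix[0] != "T" else "G"
        bad = _stub_molecule(wrong + locus.sequence[g.start + 1 : g.start + 120], 120, 60)
        kept, dropped = filter_molecules([bad], "HaeIII", prefix)
        assert dropped[0][1] == "primer_prefix"
        # one mismatch in the arm-prefix portion is tolerated
        seq = list(locus.sequence[g.start : g.start + 120])
        pos = len(prefix) - 3
        seq[pos] = "A" if seq[pos] != "A" else "C"
        ok = _stub_molecule("".join(seq), 120, 60)
        assert filter_molecules([ok], "HaeIII", prefix)[0]


def _classify(consensus, locus, panel, **kw):
    g = locus.gsp3_site
    w_lo = max(0, g.start - 30)
    window = locus.sequence[w_lo : g.start + len(consensus) + 30]
    mol = UmiMolecule("AAAAAAAA", consensus, 1)
    mol.alignment = align_to_reference(consensus, window, ref_offset=w_lo)
    return classify_molecule(mol, "HaeIII", panel, **kw)


class TestClassification:
    def test_parental_molecule_is_motc_locus(self, locus, panel):
        g = locus.gsp3_site
        mc = _classify(locus.sequence[g.start : g.start + 250], locus, panel)
        assert mc.category == "mOTC_locus"

    def test_junction_clip_is_hdr(self, locus, donor, panel):
        cassette = cassette_sequence(donor)
        consensus = locus.sequence[locus.gsp3_site.start : locus.cleavage_pos] + cassette[:40]
        mc = _classify(consensus, locus, panel)
        assert mc.category == "HDR" and mc.best_hit == "HDR_left"

    def test_promoter_fragment_is_not_hdr(self, locus, donor, panel):
        # NHEJ capture of an internal promoter piece: clip matches TBG but
        # does not contain the junction boundary
        tbg = donor.feature_sequence("TBG")
        consensus = locus.sequence[locus.gsp3_site.start : locus.cleavage_pos] + tbg[50:120]
        mc = _classify(consensus, locus, panel)
        assert mc.category == "TBG"

    def test_reverse_orientation_fragment_classified(self, locus, donor, panel):
        itr = donor.feature_sequence("ITR_L")
        consensus = (
            locus.sequence[locus.gsp3_site.start : locus.cleavage_pos] + revcomp(itr[10:80])
        )
        mc = _classify(consensus, locus, panel)
        assert mc.category == "ITR"

    def test_short_clip_below_threshold_is_locus(self, locus, donor, panel):
        cassette = cassette_sequence(donor)
        consensus = locus.sequence[locus.gsp3_site.start : locus.cleavage_pos] + cassette[:6]
        mc = _classify(consensus, locus, panel)
        assert mc.category == "mOTC_locus"

    def test_random_clip_unclassified(self, locus, panel, rng):
        consensus = (
            locus.sequence[locus.gsp3_site.start : locus.cleavage_pos] + random_dna(rng, 80)
        )
        mc = _classify(consensus, locus, panel)
        assert mc.category == "unclassified"


def _visible_insert_length(locus, enzyme, ins: str, read_length: int = 250) -> int:
    """How many inserted bases the assay can see at zero noise.

    The ligation fragment ends at the first restriction cut downstream of the
    primer — which may fall inside the inserted sequence itself — and the
    read is capped at ``read_length``.
    """
    from .oracles import naive_site_scan

    cut = locus.cleavage_pos
    seq = locus.sequence[:cut] + ins + locus.sequence[cut:]
    cuts = [
        c
        for c in naive_site_scan(seq, enzyme.recognition, enzyme.cut_offset)
        if c >= locus.gsp3_site.end
    ]
    consensus_len = min(read_length, cuts[0] - locus.gsp3_site.start)
    return min(consensus_len - (cut - locus.gsp3_site.start), len(ins))


def expected_class(locus, enzyme, row_label: str, detail: dict, donor, nuclease) -> str:
    """Truth label -> expected classification at zero noise."""
    if row_label == "parental":
        return "mOTC_locus"
    if row_label == "HDR":
        return "HDR"
    if row_label == "indel":
        if detail["type"] == "ins" and _visible_insert_length(
            locus, enzyme, detail["bases"]
        ) >= 10:
            return "unclassified"  # random inserted bases match no panel element
        return "mOTC_locus"
    label = detail["label"]
    sources = {
        "ITR": donor.feature_sequence("ITR_L"),
        "TBG": donor.feature_sequence("TBG"),
        "hOTCco": donor.feature_sequence("hOTCco"),
        "polyA": donor.feature_sequence("polyA"),
        "other": donor.feature_sequence("U6_sgRNA"),
        "SaCas9": nuclease.feature_sequence("SaCas9"),
    }
    frag = sources[label][detail["start"] : detail["start"] + detail["length"]]
    if detail["orientation"] == "-":
        frag = revcomp(frag)
    if _visible_insert_length(locus, enzyme, frag) < 10:
        return "mOTC_locus"  # insert truncated by an internal restriction site
    return "other_vector" if label == "other" else label


def test_zero_noise_classification_equals_truth(models):
    """Every molecule's class matches its truth label, for both enzymes."""
    import json

    from editquant.simulate import truth_table

    mix = AlleleMix(f_parental=0.55, f_indel=0.25, f_hdr=0.1, f_vector_fragment=0.1)
    alleles = simulate_alleles(
        models.locus, models.donor, mix, 400, seed=5, nuclease=models.nuclease
    )
    tt = truth_table(alleles)
    for enzyme in (HAEIII, TAQI):
        cfg = SimConfig(
            n_molecules=400, duplication_dist=("geometric", 5), unique_umis=True, seed=6
        )
        pairs, truth = simulate_lmu_library(alleles, enzyme, models.locus, cfg)
        _, audit = run_lmu_pipeline(
            pairs, models.locus, models.panel, enzyme, adapter_spec=SPEC
        )
        umi_to_class = {r["umi"]: r["class"] for r in audit}
        details = dict(zip(tt.id, tt.detail))
        labels = dict(zip(truth.id, truth.truth_label))
        umi_of = dict(zip(truth.id, truth.umi))
        assert len(umi_to_class) == 400
        for mol_id, label in labels.items():
            expect = expected_class(
                models.locus, enzyme, label, json.loads(details[mol_id]),
                models.donor, models.nuclease,
            )
            assert umi_to_class[umi_of[mol_id]] == expect, mol_id


def test_umi_pcr_bias_immunity(models):
    """Unique UMIs: molecule count and composition ignore duplication depth."""
    mix = AlleleMix(f_parental=0.8, f_indel=0.1, f_hdr=0.05, f_vector_fragment=0.05)
    results = {}
    for dup in (("constant", 1), ("geometric", 20)):
        res, _ = hdr_sample(
            models, mix, 200, seed=9, enzyme=HAEIII, duplication=dup, unique_umis=True
        )
        assert res.total_after_filtering == 200
        results[dup[0]] = res.counts
    assert results["constant"] == results["geometric"]


class TestHdrPercentage:
    def test_formula(self):
        classes = (
            [MoleculeClass("mOTC_locus")] * 90
            + [MoleculeClass("HDR")] * 6
            + [MoleculeClass("ITR")] * 4
        )
        res = hdr_percentage(classes, "HaeIII")
        assert res.hdr_percent == pytest.approx(6.0)
        assert res.total_after_filtering == 100

    def test_no_hdr_gives_zero(self):
        res = hdr_percentage([MoleculeClass("mOTC_locus")] * 100, "HaeIII")
        assert res.hdr_percent == 0.0

    def test_empty_input_is_error(self):
        with pytest.raises(UndefinedStatisticError):
            hdr_percentage([], "HaeIII")
        with pytest.raises(UndefinedStatisticError):
            hdr_percentage([MoleculeClass("filtered_out", "mapq")], "HaeIII")

    def test_zero_noise_hdr_matches_truth(self, models):
        mix = AlleleMix(f_parental=0.94, f_hdr=0.06)
        res, truth = hdr_sample(models, mix, 500, seed=10, enzyme=TAQI, unique_umis=True)
        assert res.hdr_percent == pytest.approx(100 * truth, abs=1e-9)


def test_classification_partition_sums_to_input(models):
    mix = AlleleMix(f_parental=0.7, f_indel=0.2, f_hdr=0.05, f_vector_fragment=0.05)
    alleles = simulate_alleles(
        models.locus, models.donor, mix, 300, seed=11, nuclease=models.nuclease
    )
    cfg = SimConfig(n_molecules=300, sub_error_rate=0.005, seed=12)
    pairs, _ = simulate_lmu_library(alleles, HAEIII, models.locus, cfg)
    res, audit = run_lmu_pipeline(pairs, models.locus, models.panel, HAEIII, adapter_spec=SPEC)
    n_filtered = sum(1 for r in audit if r["class"] == "filtered_out")
    assert res.total_after_filtering + n_filtered == len(audit)
    assert sum(res.counts.values()) == res.total_after_filtering


def test_empty_consensus_rejected(panel):
    mol = UmiMolecule("AAAAAAAA", "", 1)
    with pytest.raises(InputError):
        classify_molecule(mol, "HaeIII", panel)
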