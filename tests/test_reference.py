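"""Reference model: restriction scanning, locus/vector builders, fragments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editquant import (
    HAEIII,
    TAQI,
    Interval,
    build_donor_vector,
    build_hdr_allele,
    build_synthetic_locus,
    cassette_sequence,
    digest,
    find_restriction_sites,
    ligation_fragment,
)
from editquant.errors import InputError, ModelError, NoFragmentError
from editquant.reference import locus_from_json, locus_to_json, read_fasta, write_fasta
from editquant.seqs import random_dna, revcomp

from .oracles import naive_site_scan

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@pytest.mark.parametrize(
    "seq,enzyme,cuts",
    [
        ("AAGGCCAA", HAEIII, [4]),
        ("AAAA", HAEIII, []),
        ("GGCCGGCC", HAEIII, [2, 6]),
        ("ATCGAT", TAQI, [2]),
    ],
)
def test_restriction_site_positions(seq, enzyme, cuts):
    assert find_restriction_sites(seq, enzyme) == cuts


@pytest.mark.parametrize(
    "seq,enzyme,frags",
    [
        ("AAGGCCAA", HAEIII, ["AAGG", "CCAA"]),
        ("AAAA", HAEIII, ["AAAA"]),
        ("GGCCGGCC", HAEIII, ["GG", "CCGG", "CC"]),
    ],
)
def test_digest_fragments(seq, enzyme, frags):
    assert digest(seq, enzyme) == frags


@pytest.mark.parametrize("bad", ["aaggcc", "ACGNT", ""])
def test_non_acgt_input_rejected(bad):
    with pytest.raises(InputError):
        find_restriction_sites(bad, HAEIII)


@settings(max_examples=200, deadline=None)
@given(dna)
def test_digestion_conserves_sequence(seq):
    for enz in (HAEIII, TAQI):
        frags = digest(seq, enz)
        assert "".join(frags) == seq
        assert len(frags) == len(find_restriction_sites(seq, enz)) + 1


def test_site_scan_matches_naive_oracle(rng):
    for _ in range(200):
        seq = random_dna(rng, 200)
        for enz in (HAEIII, TAQI):
            assert find_restriction_sites(seq, enz) == naive_site_scan(
                seq, enz.recognition, enz.cut_offset
            )


class TestSyntheticLocus:
    def test_planted_sites_at_requested_distances(self, locus):
        for enz, dist in ((HAEIII, 870), (TAQI, 850)):
            arms = locus.sequence[locus.left_arm.start : locus.right_arm.end]
            cuts = [
                c + locus.left_arm.start - locus.cleavage_pos
                for c in find_restriction_sites(arms, enz)
            ]
            assert cuts == [-dist, dist]

    def test_arm_geometry(self, locus):
        assert locus.left_arm.end == locus.cleavage_pos == locus.right_arm.start
        assert len(locus.left_arm) == len(locus.right_arm) == 900
        g = locus.gsp3_site
        assert locus.left_arm.start <= g.start and g.end <= locus.left_arm.end

    def test_deterministic_for_fixed_seed(self):
        a = build_synthetic_locus(arm_length=300, seed=7, enzyme_layout={HAEIII: 250})
        b = build_synthetic_locus(arm_length=300, seed=7, enzyme_layout={HAEIII: 250})
        assert a.sequence == b.sequence and a == b

    def test_infeasible_layout_rejected(self):
        with pytest.raises(InputError):
            build_synthetic_locus(arm_length=900, seed=0, enzyme_layout={HAEIII: 1000})
        with pytest.raises(InputError):
            build_synthetic_locus(arm_length=50, seed=0)


class TestHdrAllele:
    def test_insertion_at_cut_and_length(self, locus, donor, hdr_allele):
        cassette = cassette_sequence(donor)
        cut = locus.cleavage_pos
        assert len(hdr_allele) == len(locus.sequence) + len(cassette)
        assert hdr_allele[:cut] == locus.sequence[:cut]
        assert hdr_allele[cut : cut + len(cassette)] == cassette
        assert hdr_allele[cut + len(cassette) :] == locus.sequence[cut:]

    def test_round_trip_removal_restores_parental(self, locus, donor, hdr_allele):
        cassette = cassette_sequence(donor)
        cut = locus.cleavage_pos
        restored = hdr_allele[:cut] + hdr_allele[cut + len(cassette) :]
        assert restored == locus.sequence

    def test_arm_sites_survive_at_unchanged_distances(self, locus, donor, hdr_allele):
        # re-run the naive scan oracle on the knock-in allele
        cassette_len = len(cassette_sequence(donor))
        for enz, dist in ((HAEIII, 870), (TAQI, 850)):
            cuts = naive_site_scan(hdr_allele, enz.recognition, enz.cut_offset)
            assert locus.cleavage_pos - dist in cuts
            assert locus.cleavage_pos + cassette_len + dist in cuts

    def test_mismatched_arms_rejected(self, locus, donor):
        other = build_synthetic_locus(seed=99)
        with pytest.raises(ModelError):
            build_hdr_allele(other, donor)


class TestLigationFragment:
    def test_plus_strand_runs_to_first_downstream_cut(self, rng):
        body = random_dna(rng, 120).replace("GGCC", "GGAC")
        allele = body[:98] + "GGCC" + body[98:]  # single cut at 100
        frag = ligation_fragment(allele, HAEIII, Interval(0, 10), "+")
        assert frag == allele[:100] and len(frag) == 100

    def test_minus_strand_reverse_complements(self):
        #            cut at 3 (T^CGA)        primer at [12, 18) on "-"
        allele = "AATCGAGGTTCCAAGGTTCC"
        frag = ligation_fragment(allele, TAQI, Interval(12, 18), "-")
        assert frag == revcomp(allele[3:18])

    def test_no_downstream_cut_is_reported(self):
        with pytest.raises(NoFragmentError):
            ligation_fragment("ATATATATAT", HAEIII, Interval(0, 4), "+")

    def test_default_layout_fragment_sizes(self, locus, donor, hdr_allele):
        # parental fragment = gsp3_offset + arm site distance; knock-in
        # fragment = gsp3_offset + cassette cut offset (near-equal sizes)
        gsp3_offset = locus.cleavage_pos - locus.gsp3_site.start
        for enz, arm_d, cas_d in ((HAEIII, 870, 830), (TAQI, 850, 910)):
            par = ligation_fragment(locus.sequence, enz, locus.gsp3_site, "+")
            hdr = ligation_fragment(hdr_allele, enz, locus.gsp3_site, "+")
            assert len(par) == gsp3_offset + arm_d
            assert len(hdr) == gsp3_offset + cas_d
            assert len(hdr) - len(par) == cas_d - arm_d


class TestDonor:
    def test_cassette_contiguous_and_arms_verbatim(self, locus, donor):
        assert donor.feature_sequence("HA_L") == locus.sequence[
            locus.left_arm.start : locus.left_arm.end
        ]
        assert donor.feature_sequence("HA_R") == locus.sequence[
            locus.right_arm.start : locus.right_arm.end
        ]
        iv = donor.cassette_interval
        assert len(cassette_sequence(donor)) == len(iv)

    def test_untargeted_donor_lacks_protospacer(self, locus, donor):
        untargeted = build_donor_vector(locus, seed=8, targeted=False)
        proto = locus.sequence[
            locus.protospacer_interval.start : locus.protospacer_interval.end
        ]
        assert proto in donor.sequence
        assert proto not in untargeted.sequence


def test_fasta_and_locus_json_round_trip(tmp_path, locus):
    path = tmp_path / "refs.fasta"
    write_fasta(path, [("a", "ACGT"), ("b", "GGCC")])
    assert read_fasta(path) == {"a": "ACGT", "b": "GGCC"}
    jpath = tmp_path / "locus.json"
    locus_to_json(locus, jpath)
    assert locus_from_json(jpath) == locus
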