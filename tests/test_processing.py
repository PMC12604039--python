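"""Cleavage rule engine and mature-peptide derivation.

The site predictor is checked against an independent brute-force
position-by-position rule scan; the segment partition and amidation
soundness invariants are property-tested over random sequences and rule
configurations.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuropep.catalog import CurationOverride
from neuropep.processing import (
    CleavageSite,
    ProcessingError,
    RuleConfig,
    _segments,
    derive_mature_peptides,
    predict_cleavage_sites,
)

ALL_ON = RuleConfig(kr=True, rr=True, kk=True, rk=True, mono_r=True,
                    furin_rxxr=True)


def brute_force_sites(seq, rules):
    """Independent site scan applying the rule predicates one position at
    a time (oracle for predict_cleavage_sites)."""
    out = []
    n = len(seq)
    for p in range(1, n + 1):
        r = seq[p - 1]
        if r not in "KR":
            continue
        if rules.proline_block and p < n and seq[p] == "P":
            continue
        pair = seq[p - 2:p] if p >= 2 else ""
        enabled_pairs = {m for m in ("KR", "RR", "RK", "KK")
                         if getattr(rules, m.lower())}
        if pair in enabled_pairs:
            conf = "high" if pair in ("KR", "RR") else "low"
            out.append((p, pair, conf))
            continue
        if r == "R" and rules.furin_rxxr and p >= 4 and seq[p - 4] == "R":
            out.append((p, "furin_RXXR", "high"))
            continue
        if r == "R" and rules.mono_r:
            has_context = any(p - k >= 1 and seq[p - k - 1] in "KR"
                              for k in (4, 6, 8))
            if has_context and (p == n or seq[p] != "P"):
                out.append((p, "mono_R", "low"))
    return out


rule_configs = st.builds(
    RuleConfig,
    kr=st.booleans(), rr=st.booleans(), kk=st.booleans(), rk=st.booleans(),
    mono_r=st.booleans(), furin_rxxr=st.booleans(),
    proline_block=st.booleans(),
)
proproteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1,
                      max_size=80)


class TestPredictSites:
    def test_dibasic_kr_sites(self):
        sites = predict_cleavage_sites("AYSFGLGKRSPFYGKR")
        assert [(s.position, s.motif) for s in sites] == [(9, "KR"), (16, "KR")]
        assert all(s.confidence == "high" for s in sites)

    def test_proline_blocks_all_motifs(self):
        assert predict_cleavage_sites("AAKPAA", RuleConfig()) == []
        assert predict_cleavage_sites("AAKPAA", ALL_ON) == []

    def test_kk_rk_excluded_unless_enabled(self):
        seq = "AAKKAARKAA"
        assert predict_cleavage_sites(seq, RuleConfig()) == []
        sites = predict_cleavage_sites(seq, RuleConfig(kk=True, rk=True))
        assert [(s.position, s.motif, s.confidence) for s in sites] == [
            (4, "KK", "low"), (8, "RK", "low")]

    def test_monobasic_requires_upstream_basic_context(self):
        # K at position 3 provides the -4 context for R at position 7
        sites = predict_cleavage_sites("AAKAAARAA", RuleConfig(mono_r=True))
        assert [(s.position, s.motif) for s in sites] == [(7, "mono_R")]
        # no context anywhere: nothing proposed
        assert predict_cleavage_sites("AAAAAARAA",
                                      RuleConfig(mono_r=True)) == []

    def test_furin_rxxr(self):
        sites = predict_cleavage_sites("ARAARAAA", RuleConfig(furin_rxxr=True))
        assert [(s.position, s.motif) for s in sites] == [(5, "furin_RXXR")]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(proproteins, rule_configs)
    def test_matches_brute_force_scan(self, seq, rules):
        got = [(s.position, s.motif, s.confidence)
               for s in predict_cleavage_sites(seq, rules)]
        assert got == brute_force_sites(seq, rules)

    def test_force_cleavage_on_non_basic_rejected(self):
        ov = CurationOverride("p", "force_cleavage", position=2)
        with pytest.raises(ProcessingError, match="not basic"):
            predict_cleavage_sites("AAAKR", overrides=[ov])

    def test_override_position_out_of_range(self):
        ov = CurationOverride("p", "force_cleavage", position=99)
        with pytest.raises(ProcessingError, match="outside"):
            predict_cleavage_sites("AAAKR", overrides=[ov])

    def test_force_and_suppress(self):
        seq = "AAKAAAKRAA"
        forced = predict_cleavage_sites(
            seq, overrides=[CurationOverride("p", "force_cleavage",
                                             position=3)])
        assert [(s.position, s.confidence) for s in forced] == [
            (3, "curated"), (8, "high")]
        suppressed = predict_cleavage_sites(
            seq, overrides=[CurationOverride("p", "suppress_cleavage",
                                             position=8)])
        assert suppressed == []


class TestDerive:
    def test_amidated_products(self):
        seq = "AYSFGLGKRSPFYGKR"
        sites = predict_cleavage_sites(seq)
        peps = derive_mature_peptides(seq, sites, precursor_id="p")
        assert [(p.sequence, p.start, p.end, p.ptm_label()) for p in peps] == [
            ("AYSFGL", 1, 6, "amidation"),
            ("SPFY", 10, 13, "amidation"),
        ]
        assert all(p.role == "bioactive_candidate" for p in peps)

    def test_pyroglu_variant_emitted_alongside_base(self):
        seq = "QVNFSPNWGKR"
        sites = predict_cleavage_sites(seq)
        peps = derive_mature_peptides(seq, sites, precursor_id="p")
        labels = sorted(p.ptm_label() for p in peps)
        assert labels == ["amidation", "amidation+pyroglu_Q"]
        assert all(p.sequence == "QVNFSPNW" for p in peps)

    def test_unsignalled_segment_is_precursor_peptide(self):
        seq = "ASPFYTKR"
        peps = derive_mature_peptides(seq, predict_cleavage_sites(seq),
                                      precursor_id="p")
        assert len(peps) == 1
        assert peps[0].ptms == frozenset()
        assert peps[0].role == "precursor_peptide"

    def test_disulfide_variant_for_even_cysteines(self):
        seq = "ACDCAKR"
        peps = derive_mature_peptides(seq, predict_cleavage_sites(seq),
                                      precursor_id="p")
        labels = sorted(p.ptm_label() for p in peps)
        assert labels == ["disulfide(2,4)", "none"]

    def test_duplicate_sites_rejected(self):
        site = CleavageSite(8, "KR", "high")
        with pytest.raises(ProcessingError, match="duplicate"):
            derive_mature_peptides("AYSFGLGKR", [site, site])

    def test_coordinate_offset_maps_to_preproprotein(self):
        seq = "AYSFGLGKR"
        peps = derive_mature_peptides(seq, predict_cleavage_sites(seq),
                                      precursor_id="p", coordinate_offset=20)
        assert (peps[0].start, peps[0].end) == (21, 26)

    def test_set_role_override(self):
        seq = "ARYLPTKR"
        ov = CurationOverride("p", "set_role", position=2,
                              payload="bioactive_candidate")
        peps = derive_mature_peptides(seq, predict_cleavage_sites(seq),
                                      precursor_id="p", overrides=[ov])
        assert peps[0].role == "bioactive_candidate"


class TestInvariants:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(proproteins, rule_configs)
    def test_partition_property(self, seq, rules):
        """Segments plus motif residues account for every residue exactly
        once, for any rule configuration."""
        sites = predict_cleavage_sites(seq, rules)
        segments, motif_positions = _segments(seq, sites)
        seg_positions = [p for a, b in segments for p in range(a, b + 1)]
        assert len(seg_positions) + len(motif_positions) == len(seq)
        assert set(seg_positions).isdisjoint(motif_positions)
        assert set(seg_positions) | motif_positions == set(
            range(1, len(seq) + 1))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(proproteins, rule_configs)
    def test_amidation_soundness(self, seq, rules):
        """Every amidated output has its Gly donor at end + 1."""
        sites = predict_cleavage_sites(seq, rules)
        for pep in derive_mature_peptides(seq, sites, rules):
            if any(p.kind == "amidation" for p in pep.ptms):
                assert seq[pep.end] == "G"
            assert seq[pep.start - 1:pep.end] == pep.sequence

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(proproteins, rule_configs)
    def test_deterministic_and_sorted(self, seq, rules):
        sites = predict_cleavage_sites(seq, rules)
        a = derive_mature_peptides(seq, sites, rules)
        b = derive_mature_peptides(seq, sites, rules)
        assert a == b
        assert [p.start for p in a] == sorted(p.start for p in a)
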