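"""Fingerprint matching, candidate filters and target-decoy FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuropep.masses import IonSpec, Ptm
from neuropep.matching import (
    FilterParams,
    MaldiTolerance,
    MatchingError,
    Peak,
    PeakList,
    Tolerance,
    estimate_fdr,
    filter_candidates,
    match_peaks,
    read_peaklist,
    reverse_decoy,
)
from neuropep.processing import MaturePeptide


def ion(mz, ref, adduct="M+H"):
    return IonSpec(mz=mz, adduct=adduct, charge=1, parent_ref=ref)


def peaklist(*mzs, snr=None, source="AME"):
    return PeakList(source_id=source,
                    peaks=[Peak(mz=m, intensity=1.0, snr=snr) for m in mzs])


class TestMatchPeaks:
    def test_two_predictions_within_window_are_both_ambiguous(self):
        """Two predicted masses 0.1 Da apart cannot be told apart at a
        0.1 Da window; both are reported with mutual partners."""
        preds = [ion(1279.59, "MIP-7"), ion(1279.49, "CCHa-1")]
        recs = match_peaks(preds, peaklist(1279.52), Tolerance(0.1, "da"))
        assert len(recs) == 2
        assert all(r.status == "ambiguous" for r in recs)
        partners = {r.peptide_ref: r.ambiguity_partners for r in recs}
        assert partners["MIP-7"] == ("CCHa-1",)
        assert partners["CCHa-1"] == ("MIP-7",)

    def test_below_snr_gate(self):
        recs = match_peaks([ion(649.3668, "Proc")],
                           peaklist(649.38, snr=2.1), Tolerance(0.1, "da"),
                           snr_min=3.0)
        assert len(recs) == 1
        assert recs[0].status == "below_snr"
        assert not recs[0].snr_pass

    def test_no_peak_within_tolerance(self):
        recs = match_peaks([ion(649.3668, "Proc")], peaklist(800.0),
                           Tolerance(0.1, "da"))
        assert recs == []

    def test_error_fields_consistent(self):
        recs = match_peaks([ion(1000.0, "x")], peaklist(1000.05),
                           Tolerance(0.1, "da"))
        r = recs[0]
        assert r.error_da == pytest.approx(0.05, abs=1e-9)
        assert r.error_ppm == pytest.approx(r.error_da / 1000.0 * 1e6)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(MatchingError):
            Tolerance(0.0, "da")

    def test_maldi_default_window_switches_units(self):
        t = MaldiTolerance()
        assert t.window(1000.0) == pytest.approx(0.1)
        assert t.window(8000.0) == pytest.approx(8000 * 50e-6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=600, max_value=4000), min_size=1,
                    max_size=20),
           st.lists(st.floats(min_value=600, max_value=4000), min_size=1,
                    max_size=20),
           st.floats(min_value=0.01, max_value=0.2),
           st.floats(min_value=0.01, max_value=0.5))
    def test_tolerance_monotonicity(self, pred_mzs, peak_mzs, t1, extra):
        """The match set at a narrow window is a subset of the match set at
        any wider window."""
        preds = [ion(m, f"p{i}") for i, m in enumerate(sorted(pred_mzs))]
        pl = peaklist(*sorted(set(peak_mzs)))
        narrow = {(r.peptide_ref, r.observed_mz)
                  for r in match_peaks(preds, pl, Tolerance(t1, "da"))}
        wide = {(r.peptide_ref, r.observed_mz)
                for r in match_peaks(preds, pl, Tolerance(t1 + extra, "da"))}
        assert narrow <= wide

    def test_ambiguity_is_symmetric_under_many_hits(self):
        preds = [ion(1000.00, "a"), ion(1000.05, "b"), ion(1000.08, "c")]
        recs = match_peaks(preds, peaklist(1000.03), Tolerance(0.1, "da"))
        by_ref = {r.peptide_ref: set(r.ambiguity_partners) for r in recs}
        for x in "abc":
            for y in by_ref[x]:
                assert x in by_ref[y]


def pep(seq, ptms=(), pid="p"):
    return MaturePeptide(precursor_id=pid, start=1, end=len(seq),
                         sequence=seq, ptms=frozenset(ptms),
                         role="bioactive_candidate")


class TestFilters:
    def test_short_peptide_rejected(self):
        kept, rejected = filter_candidates([pep("FMRF")])
        assert kept == []
        assert rejected[0][1] == "min_len"

    def test_heavy_peptide_rejected(self):
        big = pep("W" * 60)  # ~11.2 kDa
        kept, rejected = filter_candidates([big])
        assert rejected[0][1] == "max_mw"

    def test_too_many_variable_ptms_rejected(self):
        p = pep("MYSTKW", [Ptm("oxidation", position=1),
                           Ptm("sulfation", position=2),
                           Ptm("phosphorylation", position=3),
                           Ptm("acetylation", position=5)])
        kept, rejected = filter_candidates([p])
        assert rejected[0][1] == "max_var_ptms"

    def test_three_ptms_pass_with_disulfide_counted_once(self):
        p = pep("CMCYSK", [Ptm("disulfide", position=1, partner=3),
                           Ptm("oxidation", position=2),
                           Ptm("sulfation", position=4)])
        kept, rejected = filter_candidates([p])
        assert kept == [p]

    def test_total_function_keeps_everything_reasonable(self):
        ok = pep("AYSFG")
        kept, rejected = filter_candidates([ok])
        assert kept == [ok] and rejected == []


class TestFdr:
    def test_ratio_definition(self):
        """200 targets and 2 decoys above a score give FDR 1% there."""
        targets = np.linspace(10, 20, 200)
        decoys = np.array([15.0, 18.0])  # both above targets.min()
        res = estimate_fdr(targets, decoys, fdr_threshold=0.05)
        # at s = 15.05.., 99 targets and 1 decoy above -> threshold below that
        s = targets.min()
        n_d = (decoys >= s).sum()
        n_t = (targets >= s).sum()
        assert n_d / n_t == pytest.approx(0.01)
        assert res.qvalues.min() <= 0.01

    def test_zero_decoys_gives_zero_fdr_everywhere(self):
        res = estimate_fdr([1.0, 2.0, 3.0], [], fdr_threshold=0.01)
        assert res.threshold == 1.0
        assert np.all(res.qvalues == 0.0)

    def test_empty_targets_rejected(self):
        with pytest.raises(MatchingError):
            estimate_fdr([], [1.0])

    def test_qvalues_non_increasing_in_score(self):
        rng = np.random.default_rng(7)
        targets = np.concatenate([rng.normal(3, 1, 300),
                                  rng.normal(0, 1, 100)])
        decoys = rng.normal(0, 1, 100)
        res = estimate_fdr(targets, decoys)
        order = np.argsort(targets)
        q_sorted = res.qvalues[order]
        assert np.all(np.diff(q_sorted) <= 1e-12)

    def test_threshold_achieves_target_when_possible(self):
        rng = np.random.default_rng(8)
        targets = np.concatenate([rng.normal(4, 1, 500),
                                  rng.normal(0, 1, 50)])
        decoys = rng.normal(0, 1, 50)
        res = estimate_fdr(targets, decoys, fdr_threshold=0.01)
        assert res.threshold is not None
        assert res.fdr_at_threshold < 0.01
        # the estimate at the chosen threshold is the smallest qualifying one
        below = targets[targets < res.threshold]
        if below.size:
            s = below.max()
            fdr_s = (decoys >= s).sum() / max(1, (targets >= s).sum())
            assert fdr_s >= 0.01

    def test_no_threshold_when_unachievable(self):
        res = estimate_fdr([1.0, 2.0], [3.0, 4.0], fdr_threshold=0.01)
        assert res.threshold is None


def test_reverse_decoy_is_full_reversal():
    assert reverse_decoy("MKLAVRYLPT") == "TPLYRVALKM"


def test_read_peaklist_accepts_whitespace_and_commas(tmp_path):
    f = tmp_path / "peaks.txt"
    f.write_text("# mz intensity snr\n649.38 120 5.2\n1279.52,300,12\n"
                 "1909.08\t80\t4.0\n")
    pl = read_peaklist(f, source_id="CC")
    assert [round(p.mz, 2) for p in pl.peaks] == [649.38, 1279.52, 1909.08]
    assert pl.peaks[0].snr == pytest.approx(5.2)


def test_peaklist_rejects_out_of_range_peaks():
    with pytest.raises(MatchingError):
        PeakList(source_id="x", peaks=[Peak(mz=100.0, intensity=1.0)],
                 mass_range=(600.0, 10000.0))
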