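"""Ground-truthed synthetic precursors and peak lists.

The generator emulates the data regime the analysis assumes: multi-copy
prepropeptides (signal peptide, mature peptides flanked by dibasic KR
sites, Gly amidation donors, pyroGlu-prone N termini, spacer precursor
peptides) and MALDI-style peak lists (relative mass error, uniform noise
peaks, missing peaks, Na/K adducts, lognormal signal-to-noise). It does
not attempt isotope envelopes, detector saturation or matrix clusters.

Planted peptides are built so that the default dibasic rules recover them
exactly: interiors avoid K/R (no internal convertase motifs) and C (no
disulfide variant explosion), leading residues avoid P (proline block) and
Q/E except when a pyroGlu-prone terminus is drawn, and trailing residues
avoid G except as an explicit amidation donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import PrecursorRecord, write_catalog
from .masses import Ptm, peptide_mass, ionize
from .matching import Peak, PeakList, MaldiTolerance, match_peaks
from .processing import RuleConfig, process_precursor

__all__ = [
    "SimConfig",
    "generate_precursors",
    "simulate_peaklists",
    "simulate_psm_scores",
    "end_to_end_recovery",
    "write_bundle",
]

# interiors: 20 residues minus K/R (internal cleavage) and C (variant bloat)
_INTERIOR = np.array(list("ADEFGHILMNPQSTVWY"))
_FIRST = np.array(list("ADFGHILMNSTVWY"))  # no P (proline block), no Q/E
_LAST = np.array(list("ADEFHILMNPQSTVWY"))  # no G (amidation donor)
_SIGNAL = np.array(list("AVLIMFWPGST"))  # hydrophobic-biased draw


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator; the seed is mandatory."""

    seed: int
    n_precursors: int = 15
    peptides_per_precursor: Tuple[int, int] = (1, 5)
    peptide_length: Tuple[int, int] = (5, 45)
    spacer_length: Tuple[int, int] = (4, 20)
    p_amidation: float = 0.6
    p_pyroglu: float = 0.15
    signal_len: Tuple[int, int] = (18, 25)
    mass_error_sd: float = 20.0  # ppm
    noise_peaks_per_spectrum: int = 50
    p_peak_missing: float = 0.10
    p_na_adduct: float = 0.05
    p_k_adduct: float = 0.05
    snr_mu: float = 3.5  # lognormal log-mean of true-peak S/N
    snr_sigma: float = 1.0
    mass_range: Tuple[float, float] = (600.0, 10000.0)

    def __post_init__(self):
        if self.n_precursors < 1:
            raise ValueError("n_precursors must be at least 1")
        for name in ("p_amidation", "p_pyroglu", "p_peak_missing",
                     "p_na_adduct", "p_k_adduct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("peptides_per_precursor", "peptide_length",
                     "spacer_length", "signal_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if self.peptide_length[0] < 2:
            raise ValueError("peptides shorter than 2 residues are not simulated")


def _draw_word(rng, length: int) -> str:
    if length == 1:
        return str(rng.choice(_FIRST))
    core = "".join(rng.choice(_INTERIOR, size=max(0, length - 2)))
    return str(rng.choice(_FIRST)) + core + str(rng.choice(_LAST))


def truth_key(precursor_id: str, start: int, end: int, ptm_label: str) -> str:
    return f"{precursor_id}:{start}-{end}:{ptm_label}"


def generate_precursors(cfg: SimConfig):
    """Build seeded precursors and the truth table of every planted product.

    Returns ``(records, truth)`` where ``truth`` has one row per expected
    derived peptide variant (pyroGlu-prone peptides contribute both the
    unmodified and the cyclized form, mirroring what processing emits).
    """
    rng = np.random.default_rng(cfg.seed)
    records: List[PrecursorRecord] = []
    rows = []
    for k in range(cfg.n_precursors):
        pid = f"SYN{k + 1:03d}"
        signal = "".join(rng.choice(_SIGNAL,
                                    size=rng.integers(*cfg.signal_len,
                                                      endpoint=True)))
        parts = [signal]
        pos = len(signal)
        n_pep = int(rng.integers(*cfg.peptides_per_precursor, endpoint=True))
        for j in range(n_pep):
            plen = int(rng.integers(*cfg.peptide_length, endpoint=True))
            pep = _draw_word(rng, plen)
            pyro = rng.random() < cfg.p_pyroglu
            if pyro:
                pep = "Q" + pep[1:]
            amid = rng.random() < cfg.p_amidation
            start, end = pos + 1, pos + plen
            variants = [[]]
            if pyro:
                variants.append([Ptm("pyroglu_Q")])
            if amid:
                variants = [v + [Ptm("amidation")] for v in variants]
            role = ("bioactive_candidate" if (amid or pyro)
                    else "precursor_peptide")
            for v in variants:
                label = "+".join(sorted(str(p) for p in v)) or "none"
                rows.append(dict(
                    precursor_id=pid, name=f"{pid}-{j + 1}", start=start,
                    end=end, sequence=pep, ptms=label, role=role,
                    key=truth_key(pid, start, end, label)))
            parts.append(pep)
            pos += plen
            if amid:
                parts.append("G")
                pos += 1
            parts.append("KR")
            pos += 2
            # spacer (a precursor peptide) after every flank but the last
            if j < n_pep - 1:
                slen = int(rng.integers(*cfg.spacer_length, endpoint=True))
                spacer = _draw_word(rng, slen)
                # spacers must not look PTM-prone, or truth bookkeeping drifts
                if spacer[0] in "QE":
                    spacer = "A" + spacer[1:]
                sstart, send = pos + 1, pos + slen
                rows.append(dict(
                    precursor_id=pid, name=f"{pid}-pp{j + 1}", start=sstart,
                    end=send, sequence=spacer, ptms="none",
                    role="precursor_peptide",
                    key=truth_key(pid, sstart, send, "none")))
                parts.append(spacer)
                pos += slen
                parts.append("KR")
                pos += 2
        records.append(PrecursorRecord(
            id=pid, name=f"synthetic precursor {k + 1}",
            sequence="".join(parts), signal_end=len(signal),
            class_label="neuropeptide", complete=True))
    truth = pd.DataFrame(rows)
    return records, truth


def _truth_ptms(label: str, sequence: str) -> tuple:
    if label == "none":
        return ()
    out = []
    for tag in label.split("+"):
        if tag == "amidation":
            out.append(Ptm("amidation"))
        elif tag == "pyroglu_Q":
            out.append(Ptm("pyroglu_Q"))
        elif tag == "pyroglu_E":
            out.append(Ptm("pyroglu_E"))
        else:
            raise ValueError(f"unexpected truth PTM tag {tag!r}")
    return tuple(out)


def simulate_peaklists(truth: pd.DataFrame, cfg: SimConfig,
                       source_id: str = "sim"):
    """Turn the truth table into one observed spectrum plus peak truth.

    observed m/z = true m/z * (1 + eps), eps ~ N(0, mass_error_sd ppm);
    each planted variant is dropped with ``p_peak_missing``; the adduct is
    sampled per variant (H by default, Na/K with the configured
    probabilities); uniform random noise peaks are added over the mass
    range; S/N is drawn from the configured lognormal.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    peaks: List[Peak] = []
    truth_rows = []
    lo, hi = cfg.mass_range
    for row in truth.itertuples(index=False):
        ptms = _truth_ptms(row.ptms, row.sequence)
        neutral = peptide_mass(row.sequence, ptms)
        u = rng.random()
        if u < cfg.p_na_adduct:
            adduct = "M+Na"
        elif u < cfg.p_na_adduct + cfg.p_k_adduct:
            adduct = "M+K"
        else:
            adduct = "M+H"
        ion = ionize(neutral, adduct, 1)
        if rng.random() < cfg.p_peak_missing:
            truth_rows.append(dict(key=row.key, adduct=adduct,
                                   true_mz=ion.mz, observed_mz=np.nan,
                                   dropped=True))
            continue
        eps = rng.normal(0.0, cfg.mass_error_sd * 1e-6)
        mz = ion.mz * (1.0 + eps)
        snr = float(np.exp(rng.normal(cfg.snr_mu, cfg.snr_sigma)))
        peaks.append(Peak(mz=mz, intensity=snr * 100.0, snr=snr))
        truth_rows.append(dict(key=row.key, adduct=adduct, true_mz=ion.mz,
                               observed_mz=mz, dropped=False))
        lo = min(lo, mz - 1.0)
        hi = max(hi, mz + 1.0)
    noise_mz = rng.uniform(lo, hi, size=cfg.noise_peaks_per_spectrum)
    for mz in np.sort(noise_mz):
        snr = float(np.exp(rng.normal(cfg.snr_mu, cfg.snr_sigma)))
        peaks.append(Peak(mz=float(mz), intensity=snr * 100.0, snr=snr))
        truth_rows.append(dict(key="noise", adduct="", true_mz=np.nan,
                               observed_mz=float(mz), dropped=False))
    peaklist = PeakList(source_id=source_id, peaks=peaks, mass_range=(lo, hi))
    return peaklist, pd.DataFrame(truth_rows)


def simulate_psm_scores(seed: int, n_true: int = 1500, n_false: int = 500,
                        n_decoys: int = 500, true_mu: float = 3.0,
                        true_sigma: float = 1.0):
    """Labelled peptide-spectrum-match scores for FDR calibration studies.

    True matches score around ``true_mu``; false matches and decoys are
    drawn from the same standard-normal null, one decoy per false target,
    which is the regime the reversed-sequence decoy search emulates.

    Returns ``(target_scores, is_true, decoy_scores)``.
    """
    rng = np.random.default_rng(seed)
    true_scores = rng.normal(true_mu, true_sigma, size=n_true)
    false_scores = rng.normal(0.0, 1.0, size=n_false)
    targets = np.concatenate([true_scores, false_scores])
    labels = np.concatenate([np.ones(n_true, bool), np.zeros(n_false, bool)])
    perm = rng.permutation(targets.size)
    decoys = rng.normal(0.0, 1.0, size=n_decoys)
    return targets[perm], labels[perm], decoys


def end_to_end_recovery(cfg: SimConfig, rules: RuleConfig = RuleConfig(),
                        tol=MaldiTolerance(), snr_min: float = 3.0) -> dict:
    """Run the whole pipeline on one simulated data set and score it.

    Precision counts match records whose peak was generated by the matched
    peptide variant with the matched adduct; recall counts planted variants
    (dropped peaks included) witnessed by at least one correct match. The
    signal-to-noise gate shapes evidence tiers, not detection, so records
    flagged below the gate still count here.
    """
    records, truth = generate_precursors(cfg)
    peaklist, peak_truth = simulate_peaklists(truth, cfg)

    ions = []
    for rec in records:
        for pep in process_precursor(rec, rules):
            key = truth_key(pep.precursor_id, pep.start, pep.end,
                            pep.ptm_label())
            neutral = peptide_mass(pep.sequence, pep.ptms)
            for adduct in ("M+H", "M+Na", "M+K"):
                ions.append(ionize(neutral, adduct, 1, parent_ref=key,
                                   variant=pep.ptm_label()))

    matches = match_peaks(ions, peaklist, tol, snr_min)
    origin = {
        round(row.observed_mz, 9): (row.key, row.adduct)
        for row in peak_truth.itertuples(index=False) if not row.dropped
    }
    hits = set()
    n_records = 0
    n_correct = 0
    for m in matches:
        n_records += 1
        key, adduct = origin[round(m.observed_mz, 9)]
        if key == m.peptide_ref and adduct == m.adduct:
            n_correct += 1
            hits.add(key)
    n_planted = len(truth)
    return {
        "recall": len(hits) / n_planted if n_planted else float("nan"),
        "precision": n_correct / n_records if n_records else float("nan"),
        "n_planted": n_planted,
        "n_match_records": n_records,
    }


def write_bundle(cfg: SimConfig, outdir) -> dict:
    """Write a ready-to-run demo directory: FASTA + annotations + truth TSV
    + peak-list text file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_precursors(cfg)
    peaklist, peak_truth = simulate_peaklists(truth, cfg)
    paths = {
        "fasta": outdir / "precursors.fasta",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
        "peaks": outdir / "peaks.txt",
        "peak_truth": outdir / "peak_truth.tsv",
    }
    write_catalog(records, paths["fasta"], paths["annotations"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["peaks"], "w") as fh:
        fh.write("# mz intensity snr\n")
        for p in peaklist.peaks:
            fh.write(f"{p.mz:.6f}\t{p.intensity:.2f}\t{p.snr:.3f}\n")
    peak_truth.to_csv(paths["peak_truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
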