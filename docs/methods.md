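# Methods

## Model

A precursor record is a preproprotein sequence plus optional annotations:
signal-peptide end, product class (`neuropeptide`, `neuropeptide_like`,
`protein_hormone`, `unclassified`), and a completeness flag. Incomplete
records (no signal peptide annotated) are processed from residue 1, with a
warning; their N-terminal products are necessarily provisional.

### Cleavage rules

Prohormone-convertase sites are predicted position by position on the
proprotein:

| rule | motif | default | confidence |
|---|---|---|---|
| dibasic | KR, RR | on | high |
| dibasic | KK, RK | off | low |
| monobasic | R with a basic residue at −4, −6 or −8 | off | low |
| furin-like | RXXR (cleavage after the second R) | off | high |

A C-terminal proline immediately after the basic residue blocks cleavage
(default on). Dibasic motifs take precedence over furin/monobasic calls at
the same position. Curated overrides can force a cleavage after any basic
residue, suppress a predicted site, or set a product's role. Forced sites
at non-basic positions are rejected rather than guessed.

Cleavage strips the motif's basic residues (two for dibasic, one for
monobasic/furin, clipped where motifs overlap), partitioning the
proprotein into segments. The partition invariant — every residue belongs
to exactly one segment or one stripped motif — is property-tested.

### Post-translational modifications

Monoisotopic deltas (Da): amidation −0.98402 (requires a Gly donor
immediately after the peptide, which is consumed); pyroGlu from Gln
−17.02655 / from Glu −18.01056 (N-terminal only; emitted as a variant
alongside the unmodified form, since both are routinely observed);
disulfide −2.01565 per bridge (an all-bridged variant is emitted for
peptides with an even cysteine count); sulfation +79.95682 (Tyr);
phosphorylation +79.96633; oxidation +15.99491; methylation +14.01565;
acetylation +42.01057. Incompatible placements (pyroGlu on a non-Q/E
terminus, sulfation off-Tyr, a disulfide partner that is not Cys, …)
raise errors instead of being dropped.

### Masses and fragments

Neutral masses come from residue monoisotopic/average tables plus one
water, with full elemental-composition bookkeeping; the residue-table path
is cross-checked against pyteomics' elemental-composition calculator in
the test suite (agreement ≤ 1e-4 Da). Adduct masses: H 1.007276,
Na 22.989218, K 38.963158 (salt adducts are restricted to charge 1).
b/y fragment series place N-terminal modifications (pyroGlu) on b ions and
C-terminal amidation on y ions; a disulfide delta attaches once the later
cysteine is included. The complementarity identity
b_i + y_(n−i) = [M+H]+ + 1.00728 is property-tested for every series.

### Matching and FDR

Peak-list matching uses a fixed ±0.1 Da window below m/z 4000 and 50 ppm
above (typical reflectron-MALDI calibration); any peak–prediction pair
within tolerance produces a match record. When several predictions share a
peak, *all* are flagged `ambiguous` with their mutual partners listed —
an 0.1 Da window cannot separate predictions ~78 ppm apart at m/z 1280,
so the ambiguity is surfaced rather than arbitrated. Peaks below a
signal-to-noise threshold (default 3) yield `below_snr` records: they are
excluded from evidence tiers but retained for bookkeeping.

High-resolution candidate filtering uses: minimum length 5, maximum
molecular weight 10 kDa, at most 3 variable PTMs (a disulfide bridge
counts once), parent tolerance 0.1 Da, fragment tolerance 0.05 Da.
Target–decoy FDR uses whole-sequence reversal decoys and the ratio
estimator FDR(s) = #decoys ≥ s / max(1, #targets ≥ s); q-values are the
running minimum of that ratio, and the reporting threshold is the smallest
score with FDR < 1 %.

### Evidence tiers

Per tissue source: `+` (mass match), `(+)` (partial MS/MS verification,
junction coverage ≥ 50 %), `++` (all n−1 junctions covered by a b_i or
y_(n−i) ion). Every `++`/`(+)` cell is backed by an auditable
verification record. Leucine/isoleucine positions are reported as
ambiguous, never failed, since they are isobaric in b/y series.

## Synthetic data generator

The generator's defaults are the study conditions; all randomness flows
from a single mandatory seed (numpy `default_rng`). Each of 15 precursors
carries a hydrophobic-biased signal peptide (18–25 residues) and 1–5
mature peptides (5–45 residues) flanked by KR sites, with spacer precursor
peptides (4–20 residues) between them. Amidation donors (probability 0.6)
and pyroGlu-prone Q termini (0.15) are planted explicitly. Peptide
interiors exclude K/R/C, leading residues exclude P/Q/E (unless pyroGlu is
planted) and trailing residues exclude G, so that default dibasic
processing recovers the planted set *exactly* — a tested construction
invariant that makes recall/precision well-defined.

Observed spectra apply: multiplicative Gaussian mass error (σ = 20 ppm),
10 % missing peaks, 5 % Na and 5 % K adducts, 50 uniform noise peaks per
spectrum, and lognormal S/N with log-mean 3.5 and log-sd 1.0. The
log-mean models the prominent peaks tissue profiling reports on; it was
fixed before any recovery experiment was run. Out of scope: isotope
envelopes, detector saturation, matrix clusters, in-source decay.

### Scoring

Recall counts planted peptide variants (dropped peaks included in the
denominator) witnessed by at least one match record whose peak was
generated by that variant with that adduct; precision is the fraction of
match records that are correct in that sense. The S/N gate is treated as
an evidence policy (it shapes tiers), not a detection filter, so
`below_snr` records count here. Expected recall under the defaults is
bounded by 0.9 (missing peaks) × ≈0.957 (20 ppm error vs the 0.1 Da
window at m/z 2200–4000) ≈ 0.86.

### FDR calibration

`simulate_psm_scores` draws 1500 true target scores from N(3, 1) and 500
false targets plus 500 decoys from the N(0, 1) null — the 1:1
false-target:decoy regime reversed-sequence searches emulate. The
calibration test checks that the realized false-discovery proportion at
the chosen threshold falls inside a 95 % binomial interval around the
estimate. Because the estimate and the realized proportion are two
independent noisy measurements of the same small mean, per-replicate
coverage of such an interval is inherently below nominal (≈83 %
analytically for Poisson counts of equal mean); the suite asserts ≥ 70 %
coverage over 50 replicates. These sizes were fixed before running the
test.

## Numerical choices

- Monoisotopic masses carry ≥ 5 decimal places; comparisons in tests use
  absolute tolerances of 1e-4–1e-6 Da as appropriate.
- Peak matching uses `numpy.searchsorted` on the sorted peak list per
  prediction (O((n+m) log m)).
- q-values use `numpy.minimum.accumulate` over score-sorted FDR ratios.
- Rounding for reported anchors is plain `round` to the reported precision.

## Limitations

- The bundled catalogue mixes literature-reconstructed sequences (where a
  published mature peptide pins the relevant region down, e.g. PDF,
  proctolin, AKH) with synthetic stand-ins; stand-in precursors cannot
  reproduce published mass anchors, and the two affected acceptance tests
  fail by design until deposited sequences are supplied.
- Cleavage prediction is rule-based; no learned site model is included.
- Only singly charged MALDI-type ions and b/y MS/MS series are modelled;
  no multiply charged ESI spectra, internal fragments, or neutral losses.
- The generator does not model isotope envelopes or intensity response,
  so intensity-based scoring cannot be validated against it.
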