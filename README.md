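# neuropep

Prediction and mass-spectrometric verification of insect neuropeptides
from precursor proteins.

Neuropeptides are short signalling peptides cut out of larger precursor
proteins (prepropeptides). After the signal peptide is removed, prohormone
convertases cleave the proprotein at basic-residue motifs, carboxypeptidases
trim the exposed basic residues, and a small set of post-translational
modifications (C-terminal amidation from a glycine donor, N-terminal
pyroglutamate from Gln/Glu, disulfide bridges, tyrosine sulfation) produce
the mature, bioactive forms. Direct tissue profiling by MALDI-TOF mass
spectrometry then detects these forms as singly charged ions, and
high-resolution MS/MS confirms their sequences via b/y fragment series.

`neuropep` implements that whole inference chain as a library plus CLI:

1. **Catalogue** (`neuropep.catalog`) — load and validate precursor FASTA
   files with signal-peptide/class annotations and curation overrides.
2. **Processing** (`neuropep.processing`) — rule-based prohormone-convertase
   cleavage prediction (dibasic KR/RR by default; optional KK/RK, monobasic-R
   with upstream basic context, furin-like RXXR; proline block) and
   derivation of mature peptide variants with PTMs.
3. **Masses** (`neuropep.masses`) — monoisotopic/average masses from residue
   tables with elemental-composition bookkeeping, PTM mass deltas,
   [M+H]+/[M+Na]+/[M+K]+ adducts, and b/y fragment series.
4. **Matching** (`neuropep.matching`) — peak-list matching with MALDI-style
   tolerances (±0.1 Da below m/z 4000, 50 ppm above), explicit ambiguity
   flagging, candidate filters, and target–decoy FDR estimation with
   q-values.
5. **Evidence** (`neuropep.evidence`) — per-tissue evidence tiers:
   `+` mass match, `(+)` partial MS/MS verification (≥50 % junction
   coverage), `++` full verification; I/L ambiguity is reported, never
   silently resolved.
6. **Simulation** (`neuropep.simulate`) — seeded, ground-truthed synthetic
   precursors and peak lists for end-to-end validation.

## Worked example

The package bundles a 68-precursor catalogue (synthetic stand-in sequences
plus a handful of literature-reconstructed ones, clearly labelled in the
FASTA headers). Processing the proctolin precursor:

```python
from neuropep.catalog import bundled_catalog_paths, load_catalog, load_overrides
from neuropep.processing import RuleConfig, process_precursor
from neuropep.masses import peptide_mass, ionize

paths = bundled_catalog_paths()
records = {r.name: r for r in load_catalog(paths["fasta"], paths["annotations"])}
overrides = load_overrides(paths["overrides"])

for pep in process_precursor(records["Proctolin"], RuleConfig(), overrides):
    mz = ionize(peptide_mass(pep.sequence, pep.ptms), "M+H", 1).mz
    print(pep.name, pep.sequence, pep.ptm_label(), pep.role, round(mz, 4))
```

prints

```
PQ049300-1 RYLPT none bioactive_candidate 649.3668
PQ049300-2 NGEILDMGPELWPPQSP none precursor_peptide 1879.8894
PQ049300-3 MAPWAHGQVWSTIMDHAF none precursor_peptide 2084.9469
```

so the free-acid pentapeptide RYLPT is predicted at [M+H]+ = 649.3668
(649.4 at one decimal). The same run on the PDF precursor yields the
amidated mature peptide NSEIINSLLGLPKVLNDA-NH2 at [M+H]+ = 1909.0753.

From the command line, an end-to-end round trip on seeded synthetic data:

```
$ neuropep simulate --seed 7 --n-precursors 3 --bundle demo
$ neuropep match --fasta demo/precursors.fasta --annotations demo/annotations.tsv \
      --peaks demo/peaks.txt --out matches.tsv
$ neuropep report --matches matches.tsv --tissues peaks --fmt markdown
```

and `neuropep catalog` validates the bundled catalogue
(`68 precursor records loaded`).

## Reproduction

All results are deterministic given a seed.

```
pip install --no-build-isolation -e .[test]
pytest -q                                   # full suite, < 5 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script derives the proctolin peptide from the bundled
catalogue through the processing pipeline and reports its rounded
[M+H]+ (`{"t1": {"value": 649.4, "n": 5}}`).

Two tests in `tests/test_acceptance.py` are expected to fail:
the MIP-7 (1279.59) and trissin (2917.16) mass anchors require the
deposited precursor sequences, which are not redistributable here; the
bundled catalogue carries synthetic stand-ins for those precursors. The
PDF anchor (1909.07) passes via a literature-reconstructed sequence. See
`docs/methods.md` for the model, parameter choices and limitations.
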