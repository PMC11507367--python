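# spoilmark

Marker-peptide discovery for raw-milk spoilage from LC-MS feature tables.

Raw milk spoils within days: endogenous proteases (plasmin, cathepsins,
elastase) and a growing microbial flora degrade the caseins continuously, so
the peptide profile of a stored sample encodes its age far more directly
than a printed best-before date. `spoilmark` implements the desk half of a
bottom-up proteomics workflow that exploits this: given feature tables from
an LC-MS analysis of a storage time-course (one row per detected feature
with m/z, retention time, charge and per-sample intensities), it selects
the features whose intensity tracks storage time, links the in-solution and
in-gel (SDS-PAGE band) experiments, and proposes peptide identities for the
selected features by mass.

## What it computes

**Chemometric selection.** For a study with days *d = 1..10* and five
replicates per day, the samples × features intensity matrix *X* is analysed
with three standard tools: PCA (2 components, min-max scaled) for an
exploratory look; PLS-DA of the two use-by classes (days 1–4 = fresh vs
5–10 = past the 96 h raw-milk limit) after a VIP > 1.5 pre-filter, with an
80/20 validation split and confusion matrix; and PLSR of *X* against the
day after a univariate-F top-*k* (k = 1000) pre-selection. Features are
ranked by their variable importance in projection in the A-component PLSR,

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),

where SSY_a = q_a²‖t_a‖² is the response sum of squares explained by
component *a*; the top 50 are reported with their trend direction
(I/D = intensity increases/decreases with day).

**Feature bookkeeping.** Near-duplicate features are merged within absolute
tolerances (0.01 Th, 2 s); features also present in blank runs are
eliminated at the same tolerances; selections are cross-matched to the
per-band in-gel tables within (0.01 Th, 5 s).

**Identification.** Each selected feature's neutral mass,
M = (m/z − m_H⁺)·z, is matched at 0.002 % relative tolerance against an
in-silico digest of the seven major milk proteins (α-lactalbumin,
β-lactoglobulin, BSA, α-s1/α-s2/β/κ-casein): tryptic cleavage with up to
two missed cleavages, plus endogenous-protease cleavage adjacent to
A/V/L/I/P/M/F/W/G/Q/T, with ten variable modifications (acetylation …
phosphorylation, lactosylation) at their canonical monoisotopic deltas.

**Synthetic studies.** `spoilmark.synthetic` generates complete storage
studies with planted monotone markers, replicate noise, m/z–RT jitter,
blank-only contaminants and per-band in-gel subsets — optionally planting
real theoretical peptide masses so the whole loop (selection →
cross-match → identification) can be validated against ground truth.

## Worked example

Matching the three published marker features of a ten-day raw-milk study
against the bundled milk-protein sequences (`examples/03_identify_peptides.py`):

```
theoretical database: 258,751 peptide variants from 7 proteins

FT 128885 (m/z 415.2385, z=1):
  PLW                P02662 212-214  unmodified            +10.9 ppm
  PWI                P02663 207-209  unmodified            +10.9 ppm

FT 62883 (m/z 857.3572, z=2):
  PESERMPCTEDYLS     P02769 464-477  carbamidomethylation   -1.4 ppm
  GTRCCTKPESERMPC    P02769 457-471  hydroxylation          -6.1 ppm
  ...
```

FT 128885 is the α-s1-casein C-terminal peptide PLW (precursor positions
212–214, +10.9 ppm); FT 62883 and FT 298105 both carry the singly
phosphorylated α-s1-casein peptide FSDIPNPIGSENSEK (194–208) within the
20 ppm window at charges 2 and 3. The extra rows are isobaric candidates
reported nearest-first — a reminder that mass alone cannot finalise an
identification. Related arithmetic: the two co-eluting band-8 features
(m/z 399.6896 and 376.1899, both z = 2) differ by

    (399.6896 − 376.1899) · 2 = 46.9994 Da

in neutral mass, consistent with a shared peptide origin differing by one
small chemical group.

`examples/02_select_markers.py` runs the selection workflow on a synthetic
study (50 features selected, PLS-DA held-out accuracy 1.00, all 10 planted
markers recovered); `examples/04_full_workflow.py` closes the loop through
cross-matching and identification (10/10 planted peptides re-identified).

A thin CLI wraps the same functions:

```
spoilmark simulate --seed 1 --out data/
spoilmark all --table data/insolution.csv --samples data/insolution.samples.csv \
    --band 2=data/band_2.csv:data/band_2.samples.csv --out report/
```

## Layout

- `spoilmark.features` — feature tables, CSV I/O, merge / blank-subtract /
  cross-match, neutral-mass arithmetic
- `spoilmark.chemometrics` — scaling, PCA, PLS, VIP, F-selection, splits,
  PLS-DA
- `spoilmark.digestion` — FASTA parsing, combined-rule digestion, variable
  modifications, mass matching
- `spoilmark.synthetic` — storage-study generator with ground truth
- `spoilmark.pipeline` / `spoilmark.cli` — the orchestrated workflows
- `spoilmark.reference` — published feature tables and the bundled
  milk-protein sequences
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices and limitations
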