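# Methods

This note records the models, defaults and numerical choices behind
`spoilmark`, and what the synthetic validation does and does not show.

## The measurement model

A *feature* is a consolidated LC-MS signal — (m/z, retention time, charge)
plus one intensity per sample — and is not presumed to be a peptide until
identified. The package consumes feature tables produced by any centroiding
/ feature-finding front end (an mzML-based detector, vendor software, or
the bundled simulator); re-implementing feature detection is explicitly out
of scope.

Coordinates follow one convention throughout: retention time in seconds,
monoisotopic m/z in Th, charge ≥ 0 with 0 meaning "undetermined". Features
with charge 0 participate in the chemometric stages (intensity carries
information regardless) but are excluded from any neutral-mass computation,
with a logged warning.

## Feature bookkeeping

**Merging** (defaults 0.01 Th, 2 s absolute). The clustering order is not
uniquely determined by the tolerances alone, so the implementation fixes
it: features are visited by descending total intensity; each unabsorbed
seed collects every remaining feature within both tolerances *of the seed's
coordinates* (coordinates frozen during absorption, which prevents
chain-merging past the tolerance). Merged intensity is the per-sample sum;
merged coordinates are intensity-weighted means; the charge is the seed's
(members that disagree are logged). The pass repeats until it is a fixed
point, which makes the operation idempotent and guarantees no two survivors
lie within both tolerances — the property the downstream stages rely on.

**Blank elimination** removes every feature with a blank-run feature within
the merge tolerances; it is a pure subset operation and therefore
idempotent by construction.

**Cross-matching** (defaults 0.01 Th, 5 s) pairs each query feature with at
most one partner: the nearest candidate by the scaled distance
max(|Δmz|/tol_mz, |Δrt|/tol_rt), ties broken by smaller |Δmz| and then by
partner id, so results are deterministic.

**Neutral mass** uses M = (m/z − 1.007276)·z with the proton mass fixed at
1.007276 Da. The arithmetic identity theoretical_mz(neutral_mass(x, z), z)
= x holds to machine precision.

## Chemometrics

Min-max scaling maps each feature onto [0, 1]; constant features map to 0
(their scaled value is arbitrary, and 0 removes them from the PCA
variance). PCA runs on the scaled, mean-centred matrix and is exploratory
only — nothing downstream consumes it.

PLS is NIPALS PLS1 (single response, X-deflation, unit-norm weights) via
scikit-learn's `PLSRegression`. Two input conventions are exposed:

- *centred, unscaled* (library default) — the textbook NIPALS contract,
  under which the documented identities hold exactly (first weight vector
  ∝ Xᵀy; A = rank(X) reproduces ordinary least squares);
- *autoscaled* (`scale=True`; the pipeline default via
  `PipelineConfig.scale_pls`) — predictors and response standardised before
  the fit. Feature base intensities in real tables span orders of
  magnitude, and on merely centred data the covariance criterion is owned
  by high-intensity noise features; autoscaling is also what the standard
  implementation this workflow was built on does by default. Under the
  default synthetic conditions the choice moves planted-marker recovery
  from ~80 % to ~98 % and PLS-DA hold-out accuracy from 0.8 to 1.0.

VIP scores use VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = q_a²‖t_a‖²; the mean of squared VIPs is identically 1, making the
1.5 cut-off scale-free. The univariate pre-selection uses the regression F
statistic F_j = r_j²/(1 − r_j²)·(n − 2) (the storage day is a numeric
target, so the regression variant is the appropriate one); constant
features score 0, numerically saturated correlations rank first, remaining
ties resolve by column order.

Validation uses a single seeded 80/20 shuffle split (train size
⌈0.8·n⌉). The split is deterministic given the seed but is not claimed to
replicate any particular external partition — the contract is
reproducibility, not bit-compatibility with other ecosystems. The PLSR
component count is chosen by held-out R² over A = 1..A_max (ties to the
smaller A); PLS-DA binarises the two classes, thresholds predictions at
0.5 and reports the held-out confusion matrix. The per-band in-gel PLSR
uses exactly two components and no split: a per-band table has ten samples,
and splitting it would cost more day coverage than the validation is worth.

The fresh / past-use-by boundary is day 4, from the 96-hour use-by limit
for raw milk.

## Digestion and identification

The theoretical peptide database combines two cleavage regimes:

- **Tryptic**: cleavage C-terminal to K/R, suppressed before proline by
  default, with ≤ 2 missed cleavages. Fully tryptic peptides have no upper
  length cap.
- **Endogenous-protease**: raw milk contains active proteases whose
  collective specificity is approximated by extra cleavage *adjacent to*
  the hydrophobic/small residues A, V, L, I, P, M, F, W, G, Q, T. Two
  design choices matter here and are both configurable on
  `CleavageRules`:
  1. a terminus may fall on either side of a listed residue
     (`extended_before=True`). Cathepsin-D/pepsin-type specificity is
     described by both the P1 and the P1′ position, and the workflow's own
     reference identifications require an N-terminal-side cut (the
     phosphopeptide FSDIPNPIGSENSEK starts at F194 of α-s1-casein, whose
     preceding residue S193 is not a cleavage site on any C-terminal
     reading);
  2. the missed-cleavage budget counts *tryptic* sites only. The in-vitro
     trypsin digest is exhaustive enough for missed cleavages to be
     meaningful; endogenous cleavage in a spoiling sample is sporadic, so
     uncut extended sites are not penalised. Without this, any peptide
     longer than a few residues would exceed the budget and the observed
     long peptides could never be generated. Enumeration is bounded
     instead by a 30-residue length cap (and a 3-residue floor) on
     extended-site peptides.

Peptide masses are sums of standard monoisotopic residue masses plus water
(18.010565 Da), cross-checked in the tests against pyteomics. Ten variable
modifications are supported with canonical monoisotopic deltas
(acetylation +42.010565 on K; carbamidomethylation +57.021464 on C;
carboxyethylation +72.021129 and carboxymethylation +58.005479 on K;
hexosylation +162.052824 and lactosylation +324.105647 on K — Maillard
chemistry on lysine is prominent in milk; hydroxylation +15.994915 on P;
methylation +14.015650 on K/R; oxidation +15.994915 on M/W;
phosphorylation +79.966331 on S/T/Y). One modification per peptide by
default: every reference identification carries at most one, and the
variant count grows combinatorially otherwise. Acetylation defaults to
lysine only; an `"nterm"` pseudo-site is available for N-terminal
chemistry but is off by default because it would add a variant of every
single peptide.

Matching applies the 0.002 % (20 ppm) tolerance to *neutral masses*
(applying it to m/z instead differs only at the sub-ppm level and is a
config choice). All candidates inside the window are reported,
nearest-first — the package deliberately does not pick a single winner,
because mass alone cannot separate isobaric candidates (Leu/Ile trivially;
hydroxylation vs oxidation exactly; and distinct sequences within ppm).

The seven milk-protein sequences are bundled for offline use
(`spoilmark.reference.load_milk_proteins`); the α-s1-casein entry is pinned
by its published peptide coordinates, the other six act as search-space
background and should be refreshed from UniProt when exactness matters
beyond that role.

## The synthetic-data generator

The generator emulates the study design the analysis assumes — 10 days × 5
replicates in-solution, per-band in-gel tables with one lane per day, and
blank runs — with the following model:

- **Trend**: an up-marker's expected intensity at day *d* is
  base·(1 + s·(d − 1)); a down-marker's is base·max(0.01, 1 − s·(d − 1)).
  Linear-in-day is the simplest shape consistent with the monotone
  intensity profiles the workflow is designed to find. Default trend
  strength s = 0.10/day: strong enough to be a plausible marker, and it
  keeps the day-10 down-marker mean (0.1·base) above the 0.01 floor so
  that monotonicity is strict over the whole study.
- **Noise**: multiplicative log-normal with unit mean and CV 0.2 —
  a typical replicate CV for label-free feature intensities.
- **Base intensities**: log-uniform over 1e4–1e6, so the analysis must
  cope with features whose scales differ by two orders of magnitude.
- **Dropout**: with probability 0.05 an intensity is set to 0, the
  feature-finder's encoding of "not detected".
- **Coordinates**: m/z uniform on 150–1200 Th, RT uniform on 60–900 s,
  charges from {1, 2, 3}; each table draws fresh Gaussian jitter
  (SD 0.002 Th / 0.5 s) around the true coordinates, within the merge and
  cross-match tolerances.
- **Counts**: 500 features, 5 up + 5 down markers, 25 blank-only
  contaminants, three bands of 80 features with overlap fraction 0.3. The
  real studies do not report per-run feature counts, so the absolute scale
  is a free parameter chosen to keep a full run under a second while
  leaving markers a 2 % minority.
- **Planting**: marker features can take the exact theoretical m/z of a
  randomly drawn digest-variant peptide at charge 1–3. Planted peptides
  are restricted to m/z ≥ 400 Th: below that the 20 ppm identification
  window shrinks under ~2 SD of the default m/z jitter and re-identification
  becomes a coin flip; at 400 Th the window is ≥ 4 SD at every charge, so
  the closed loop is deterministic by construction (and sub-400 Th
  precursors are atypical for tryptic peptides anyway).
- **Bands**: shared band features keep their day-trend means at half the
  in-solution base (in-gel workups recover less material); the planted
  markers are preferentially among the shared features, mirroring the fact
  that casein-derived markers sit in casein bands. Blank contaminants
  appear in every band table and in the blank tables that allow removing
  them.

Everything is driven by one integer seed through independent
`numpy.random.Generator` streams; identical configs give byte-identical
tables.

**What passing the synthetic tests shows — and does not.** They show the
pipeline's machinery is correct: monotone minority features are found,
directions are read correctly, blanks are removed exactly, planted masses
are re-identified. They do not show field performance on real spoilage
data, where trends are nonlinear and saturating, noise is structured
(batch, carry-over, ionisation competition), the feature count is two to
three orders of magnitude larger, and co-eluting isobars inflate the
candidate lists. In particular the synthetic PLSR R² is *not* comparable
to values reported for real studies: with only ~2 % informative features
and standardised noise the held-out R² is modest even when every marker is
recovered, whereas real spoilage proteomes contain many correlated trend
features.

## Numerical conventions

- Proton 1.007276 Da, water 18.010565 Da, residue masses at six decimals.
- Ranking ties (VIP, F) resolve by column order / feature id; all sorts are
  stable, so reports are reproducible across runs.
- Degenerate inputs fail loudly: constant response (PLS, F-selection),
  single-class targets (PLS-DA), component counts above rank, charge-0
  features in mass arithmetic, empty matrices.
- Problem sizes used by the shipped validation: 500-feature synthetic
  studies (five seeds) for recovery statistics, ≤ 40-residue random
  proteins for the digest-vs-enumeration equivalence, and the full
  ~260 k-variant milk database for the reference identifications.

## Known limitations

- No fragment-level (MS²) scoring, decoy search or FDR control: matches
  are mass-only candidate lists, as in the workflow modelled.
- Two-class PLS-DA only; no multi-class extension, no cross-validation
  beyond the single seeded split, no sparse/orthogonal PLS variants.
- The merge updates coordinates to member means; pipelines that keep the
  first occurrence will differ at the sub-tolerance level.
- Ion mobility, isotope patterns and raw spectra are outside the model;
  the package starts at the feature table.
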