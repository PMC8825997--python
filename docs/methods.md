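# Methods

This note records the models, defaults and numerical choices behind
`derep-ms`, and what the synthetic-data experiments do and do not show.

## Scope and data model

The pipeline begins at finished peak lists: per-sample, per-polarity
tables of (m/z, retention time, intensity) as exported by any
peak-picking tool. Chromatographic peak detection from raw profile
spectra is deliberately not re-implemented; the optional mzML reader
ingests already-centroided MS1 spectra only. All interchange formats
are plain text (CSV/TSV/JSON/Newick/YAML).

## Adduct model and neutral masses

Only the singly charged proton adducts are registered by default —
[M+H]+ and [M−H]− — because these are the species relevant to the
electrospray data the package targets; the registry is an ordinary
mapping and is extensible. The proton mass shift is **1.00728 Da**
(electron-corrected). This constant reproduces the molecular-weight
annotations of the bundled library at 4-decimal rounding; across the 40
records the residual |m/z·|z| − Δ − MW| is at most 2.2×10⁻⁴ Da, except
for record 39, whose printed positive-mode m/z is inconsistent with its
own MW under any proton arithmetic (it duplicates record 10's
negative-mode values). That record is kept verbatim and flagged rather
than silently corrected.

Alignment across samples is greedy centroid clustering in ascending
m/z: a peak joins a cluster while it stays within the ppm tolerance of
the cluster's intensity-weighted mean m/z and within the RT tolerance
of its weighted mean RT. Cross-polarity merging converts both modes to
neutral masses first, then pairs features best-first by smaller |Δppm|
(ties: earlier RT), each feature pairing at most once; merged features
sum intensities (total intensity is conserved) and average masses with
intensity weights. Defaults: **5 ppm** mass tolerance and **0.1 min**
RT tolerance, typical Orbitrap-class practice; both configurable.

## Formula enumeration

Monoisotopic masses use IUPAC atomic masses (C 12 exactly,
H 1.0078250319, N 14.0030740052, O 15.9949146221, P 30.97376151,
S 31.97207069). Candidate formulas for a neutral mass are enumerated
exhaustively over an integer element box (default C 0–60, H 0–100,
N 0–10, O 0–25, P 0–3, S 0–3 — wide enough for all bundled compounds,
including a C59 glycoside and two phosphorus-bearing records) by
depth-first recursion over the heavy elements with mass-window pruning;
hydrogen is resolved analytically at the leaf, so no combination can be
skipped. Enumeration refuses boxes implying more than 10⁸ naive
combinations. Candidates are filtered by RDBE ∈ [0, 40] (RDBE =
C − H/2 + (N+P)/2 + 1), annotated with the nitrogen rule (RDBE
integrality), and sorted by |ppm error|, then fewer atoms, then Hill
string. Nitrogen-rule *filtering* is off by default — the rule is
annotated, not enforced, to avoid discarding valid candidates. Default
tolerance 5 ppm. The test suite checks the enumerator against both a
literal nested-loop oracle (small boxes) and a vectorized brute force
over the full default box.

## Dereplication

Matching is on neutral monoisotopic mass only. Retention time is
carried through all reports for human inspection but never compared:
it is not transferable across chromatographic systems, and the
library's RT annotations come from a different gradient than any user
data will. All compounds within tolerance are reported — exact mass
cannot distinguish isobars (the bundled library itself contains several
groups sharing one formula), so forced unique assignment would
manufacture certainty. A source-organism text filter stands in for
taxon-restricted secondary database screens. The hit tolerance (5 ppm
by default) is deliberately surfaced in every interface because no
universally correct value exists.

## Chemometrics

- **Pareto scaling**: per feature, subtract the mean and divide by the
  square root of the sample standard deviation (ddof 1). Zero-variance
  features map to all-zero columns and are flagged. For log-normal
  intensity data the package's analyses apply log10 before Pareto
  scaling — the standard transform-then-scale sequence in metabolomics
  practice; without it, feature weights in projection methods are
  dominated by high-baseline features regardless of group structure.
- **PCA** is computed by SVD of the centered matrix. R² is the
  cumulative explained-variance fraction. Q² is leave-one-out: each
  sample is withheld, the PCA is refit, the held-out (training-mean-
  centered) sample is predicted by projection onto the refit loadings,
  and Q²ₐ = 1 − PRESSₐ/TSS. The conventional significance threshold for
  Q² is 0.5. Component signs follow a deterministic convention: the
  largest-|loading| entry of each component is made positive.
- **PLS-DA** is NIPALS PLS2 on the centered one-hot class matrix, with
  deflation of both blocks. Sparsity (the "sPLS-DA" variant) truncates
  each X-weight vector to its largest-|w| entries before forming
  scores; the default keeps all features (plain PLS-DA), since no
  keep-per-component value is canonical. The natural component count
  for k groups is k − 1 (the dimension of the class space); the
  recovery analyses use 4 components for the 5-group design.
- **VIP**: VIPⱼ = √(p·Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ) with unit-norm weight
  vectors and SSYₐ the class variance explained by component a; mean
  VIP² = 1 holds identically.
- **HCA** defaults to Euclidean distance with Ward linkage (the common
  default pairing in metabolomics servers); average/complete/single are
  available. Dendrograms export as Newick with merge heights as branch
  lengths.
- **Feature selection** for heatmaps is per-feature one-way ANOVA,
  sorted by p (ties by F); with two groups F = t² exactly. When any
  group has fewer than two samples the F statistic is undefined and the
  ranking falls back to between-sample variance with a warning —
  relevant for one-profile-per-extract designs. Fisher's LSD pairwise
  comparisons are reported post hoc but never used for selection.
  Heatmap values are z-scored per feature and both axes are ordered by
  HCA.
- Missing intensities are imputed as half the minimum positive value
  (left-censoring convention) by `impute_missing`; the simulators never
  emit missing values, so this is off the default path.

## Dose-response analysis

Viability of a treated well is
100·(well − blank)/(control − blank), with every absorbance corrected
as A570 − A690 and control/blank averaged over the plate; negative
values are clipped to 0 and flagged. Survival curves are fitted with a
descending four-parameter logistic,
v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill), by bounded least
squares on log-scale concentration. The top is constrained to ≤120%
and the bottom to ≥−5% to stabilize fits on the minimal 5-dose design
(100, 25, 6.3, 1.6, 0.4 µg/ml); when the optimizer cannot converge the
estimator falls back to log-linear interpolation between the doses
bracketing 50% and records the method used. Curves that never cross
50% are flagged extrapolated. With replicate curves, the IC50 is
reported as mean ± s.d. over per-replicate fits; recovery analyses fit
the replicate-mean curve, which is markedly more stable than any
single-replicate fit. IC50 recovery is reliable (≲10% error at 3%
measurement noise) for true IC50s well inside the dose range; values
near either end of the 5-dose ladder are intrinsically less
identifiable.

Group comparisons (cancer vs normal cell line) use the unpaired
pooled-variance Student's t-test, two-sided, with significance tiers
\* p<0.05, ** p<0.01, *** p<0.001. When both groups are constant and
equal the statistic is undefined; the comparison reports "ns" with a
flag rather than NaN.

## Synthetic data

The generators define the study conditions; everything is a pure
function of (design, seed).

- **Extract profiles**: 5 extracts by default, both polarities. The
  bundled library is split into a shared core (10 compounds present in
  every extract) and 6 unique compounds per extract; each planted
  compound emits both the protonated and deprotonated ion at its
  formula's monoisotopic mass (a literature-MW planting mode exists for
  arithmetic checks), with Gaussian mass error of **2 ppm s.d.** per
  observation (Orbitrap-class), RT jitter 0.02 min s.d. around a
  compound-level RT, and log-normal intensities (log-mean 13, log-s.d.
  1, per-observation factor 0.3). 160 decoy features are drawn
  uniformly in 150–900 Da, rejected until ≥20 ppm from every library
  mass (formula and literature MW alike), each present in a random
  subset of extracts. With these defaults the closed loop
  simulate → align → merge → dereplicate recovers the planted
  feature→compound map with precision = recall = 1 at 5 ppm.
- **Intensity matrices**: 5 groups × 3 replicates (triplicates being
  the assay convention), 200 features, log-normal baselines (log-s.d.
  1) with residual log-s.d. 0.5. Ten discriminatory features are
  assigned round-robin to groups and shifted by 3 residual-s.d. in log
  space. An optional outlier group receives ±4 s.d. shifts on 40
  additional features — one deliberately distinct extract, as real
  crude-extract panels show; on such data the outlier separates in the
  PC1/PC2 score plane and is the last join of the Ward dendrogram.
- **MTT plates**: viabilities from a known 4PL curve are converted to
  absorbance via control/blank anchors (corrected control 1.0, blank
  0.1, background 0.05) with multiplicative Gaussian noise of given CV
  on each treated well's corrected absorbance.

What the synthetic data does *not* emulate: isotope envelopes, in-source
fragments and multiply charged species; correlated (chromatographic)
mass/RT drift; heavy-tailed intensity error; matrix effects between
co-eluting compounds; plate edge effects. Passing the closed-loop tests
therefore demonstrates the correctness of the arithmetic, matching,
projection and fitting machinery under the stated error model — not
robustness to every artefact of real instruments.

## Problem sizes and determinism

The default analyses are small by design: 5–15 samples, ~200–430
features, 40-compound library, 5-dose curves — matching the emulated
study's scale, where a full run (tests plus the acceptance script)
completes in about a minute. All fitting is deterministic given the
inputs; only the simulators consume seeds, and every script takes the
seed explicitly.

## Known limitations

- Dereplication by exact mass alone cannot separate isobaric
  compounds; MS/MS spectral matching is out of scope.
- The leave-one-out Q² estimator is one of several in use; absolute Q²
  values from other software will differ slightly, though the
  structure-vs-noise contrast (≥0.99 for noiseless rank-1, ≤0.5 for
  white noise) is stable.
- PLS-DA explained-variance percentages are on the feature block and
  are not comparable across software that reports them on the class
  block.
- The 4PL bottom/top constraints encode the assumption that viability
  is expressed in percent of an untreated control; assays normalized
  differently need the bounds adjusted.
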