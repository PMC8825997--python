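# derep-ms

Dereplication- and metabolomics-guided chemical profiling of bacterial
crude extracts from LC-HRMS peak data.

When a crude extract of a cultured *Streptomyces* isolate shows
antimicrobial or anti-cancer activity, the first question is whether its
metabolites are already-known natural products or candidates for
isolation. `derep-ms` implements the computational side of that
workflow for untargeted LC-HRMS data:

- **Adduct-aware neutral-mass annotation** — observed ions are converted
  to neutral monoisotopic masses (`M = m/z·|z| − Δ_adduct`, with the
  proton shift Δ = ±1.00728 Da), peak lists are aligned across samples
  by m/z (ppm) and retention time, and positive- and negative-mode
  features are merged into cross-polarity neutral features.
- **Molecular-formula enumeration** — exhaustive search of candidate
  CHNOPS compositions for a neutral mass within a ppm tolerance, with
  RDBE bounds (`RDBE = C − H/2 + (N+P)/2 + 1`) and nitrogen-rule
  annotation, ranked by |ppm error|.
- **Library dereplication** — features are matched by neutral
  monoisotopic mass against a compound library; a bundled mini-library
  of 40 *Streptomyces* secondary metabolites (name, formula, literature
  m/z / adduct / RT / MW, source organism) ships with the package, and
  user libraries are plain TSV.
- **Chemometrics** — Pareto scaling, PCA with cumulative explained
  variance R² and leave-one-out Q², (sparse) PLS-DA with VIP scores
  (VIPⱼ = √(p·Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ), so mean VIP² = 1), hierarchical
  cluster analysis, and ANOVA-selected heatmap matrices. Estimators
  follow the scikit-learn `fit`/`transform` API.
- **Cytotoxicity summarization** — MTT viability from 570/690 nm plate
  absorbances, survival-curve IC50 by a four-parameter logistic fit
  (log-linear interpolation fallback), and unpaired Student's *t*
  comparison of cancer- vs normal-cell-line IC50s with the usual
  significance stars.
- **A synthetic-data generator** that produces dual-polarity peak
  tables with planted library compounds and decoys, grouped intensity
  matrices with known discriminants, and MTT plates from known IC50s —
  so the whole pipeline is testable end-to-end with known ground truth.

## Worked example

Simulate a five-extract, dual-polarity experiment and dereplicate it
against the bundled library:

```bash
$ derep-ms simulate --seed 11 --out demo
$ derep-ms dereplicate --peaks demo/peaks_positive.csv \
      --peaks demo/peaks_negative.csv --ppm-tol 5 --out demo/report.tsv
215 features: 41 hit, 174 no hit
```

The 215 aligned neutral features include the planted library compounds
(41 features hit; the planted compounds appear in both ionization modes
and merge into `both_modes` features) and 174 decoy features with no
library match — mirroring the real situation where most crude-extract
metabolites have no database hit. The report lists each feature with
its neutral mass, RT, provenance and matches:

```
feature_id       neutral_mass  rt    provenance  status  compound                      formula   ppm_error
B126.0681T1.72   126.0681      1.72  both_modes  hit     1-Cyclohexenecarboxylic acid  C7H10O2    0.15
B161.1050T1.80   161.1050      1.80  both_modes  hit     Deoxyvalidamine               C7H15NO3  -0.97
B210.1256T9.04   210.1256      9.04  both_modes  hit     Violapyrone A                 C12H18O3   0.02
```

The same steps from Python, for a single ion — the deprotonated species
of a tetracycline-class antibiotic observed at m/z 459.14032:

```python
>>> from derep_ms import neutral_mass_from_ion, DEPROTONATED, enumerate_formulas
>>> round(neutral_mass_from_ion(459.14032, DEPROTONATED), 4)
460.1476
>>> cands = enumerate_formulas(460.1476, tol_ppm=5.0,
...     element_ranges={"C": (0, 40), "H": (0, 80), "N": (0, 6), "O": (0, 15)})
>>> cands[0].formula.hill(), round(cands[0].ppm_error, 2)
('C22H24N2O9', -1.26)
```

The top candidate is the composition of oxytetracycline, 1.26 ppm below
the observed neutral mass — a dereplication hit at any sensible Orbitrap
tolerance.

Chemometrics on a grouped intensity matrix with known discriminants:

```python
>>> import numpy as np
>>> from derep_ms import (IntensityDesign, simulate_intensity_matrix,
...                       pareto_scale, fit_plsda, vip_scores)
>>> matrix, labels, truth = simulate_intensity_matrix(IntensityDesign(seed=0))
>>> scaled = pareto_scale(np.log10(matrix))
>>> model = fit_plsda(scaled, labels, n_components=4)
>>> top10 = vip_scores(model).sort_values(ascending=False).index[:10]
>>> len(set(top10) & set(truth.discriminatory_features))
10
```

## Layout

```
src/derep_ms/
  peaks.py         peak-list / library / report I/O, core record types
  adducts.py       adduct registry, neutral-mass arithmetic, alignment, merging
  formula.py       Hill parsing, monoisotopic mass, RDBE, formula enumeration
  derep.py         library matching and dereplication reports
  chemometrics.py  Pareto scaling, PCA/Q2, PLS-DA/VIP, HCA, ANOVA heatmap
  bioactivity.py   MTT viability, 4PL IC50, unpaired t comparison
  simulate.py      synthetic peak tables, intensity matrices, MTT plates
  pipeline.py      end-to-end orchestration with config + run manifest
  cli.py           the `derep-ms` command-line interface
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
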