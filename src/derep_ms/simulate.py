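"""Synthetic LC-HRMS, intensity-matrix and dose-response data with ground truth.

Every stage of the pipeline is exercised end-to-end on data whose truth is
known: dual-polarity peak tables with library compounds planted at their
literature-observed masses (ppm-scale Gaussian mass error, RT jitter,
log-normal intensities) among decoy masses kept >=20 ppm from every
library mass; grouped intensity matrices with designated discriminatory
features; and MTT plates generated from a known 4PL survival curve.  All
generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adducts import DEPROTONATED, PROTONATED, Adduct, ion_mz_from_neutral
from .bioactivity import DEFAULT_DOSES, four_param_logistic
from .peaks import CompoundRecord, IonFeature, bundled_library

__all__ = [
    "SimulationDesign",
    "IntensityDesign",
    "GroundTruth",
    "simulate_extract_profiles",
    "write_extract_profiles",
    "simulate_intensity_matrix",
    "simulate_dose_response",
]


@dataclass
class SimulationDesign:
    """Study design for the synthetic five-extract, dual-polarity experiment.

    Defaults mirror the emulated study: 5 crude extracts profiled in both
    ionization modes, a core of metabolites shared by all extracts plus
    per-extract unique metabolites, ~200 features per extract once decoys
    are added, 2 ppm mass-error s.d. (Orbitrap-class accuracy) and 0.02 min
    RT jitter.  Planted compounds default to the bundled library split into
    a shared core and per-extract unique subsets.
    """

    n_extracts: int = 5
    n_shared_compounds: int = 10
    n_unique_per_extract: int = 6
    n_decoy_features: int = 160
    mass_error_ppm_sd: float = 2.0
    rt_jitter_sd: float = 0.02
    intensity_log_mu: float = 13.0
    intensity_log_sd: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0
    library: Sequence[CompoundRecord] | None = None
    planted_compounds: dict[str, list[str]] | None = None  # extract -> names
    #: neutral mass each compound is planted at: the formula's monoisotopic
    #: mass ("formula", the compound's true mass) or the literature-observed
    #: molecular weight carried by the library record ("library_mw", which
    #: itself sits up to ~3 ppm from the formula mass and so emulates a
    #: previously observed instrument value).
    plant_at: str = "formula"

    def extract_ids(self) -> list[str]:
        return [f"ext{i + 1}" for i in range(self.n_extracts)]


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed for later scoring."""

    compound_extracts: dict[str, list[str]] = field(default_factory=dict)
    compound_neutral_mass: dict[str, float] = field(default_factory=dict)
    compound_rt: dict[str, float] = field(default_factory=dict)
    decoy_masses: list[float] = field(default_factory=list)
    discriminatory_features: list[str] = field(default_factory=list)
    group_labels: dict[str, str] = field(default_factory=dict)
    true_ic50: float | None = None
    true_params: dict[str, float] = field(default_factory=dict)


def _planted_map(design: SimulationDesign, library: Sequence[CompoundRecord]
                 ) -> dict[str, list[str]]:
    """Shared-core + unique-per-extract planting scheme over the library."""
    if design.planted_compounds is not None:
        return design.planted_compounds
    names = [c.name for c in library]
    need = design.n_shared_compounds + design.n_unique_per_extract * design.n_extracts
    if need > len(names):
        raise ValueError(
            f"design plants {need} compounds but library has only {len(names)}"
        )
    shared = names[: design.n_shared_compounds]
    plan: dict[str, list[str]] = {}
    cursor = design.n_shared_compounds
    for ext in design.extract_ids():
        unique = names[cursor: cursor + design.n_unique_per_extract]
        cursor += design.n_unique_per_extract
        plan[ext] = shared + unique
    return plan


def simulate_extract_profiles(
    design: SimulationDesign,
) -> tuple[list[IonFeature], list[IonFeature], GroundTruth]:
    """Generate positive- and negative-mode peak lists for all extracts.

    Each planted compound is observed at its neutral mass (see
    ``SimulationDesign.plant_at``) as both the protonated and deprotonated
    species, with per-observation Gaussian
    mass error in ppm and RT jitter around a compound-level retention
    time.  Decoy features are drawn at random masses rejected until at
    least 20 ppm from every library mass.  Fully reproducible from the
    design seed.
    """
    rng = np.random.default_rng(design.seed)
    library = list(design.library) if design.library is not None else bundled_library()
    by_name = {c.name: c for c in library}
    plan = _planted_map(design, library)
    truth = GroundTruth()

    all_names = sorted({n for names in plan.values() for n in names})
    for name in all_names:
        if name not in by_name:
            raise ValueError(f"planted compound {name!r} not in library")
    # compound-level draws (RT, base intensity) made once, in sorted order,
    # so the output is independent of dict iteration order
    base_rt = {n: rng.uniform(0.5, 10.0) for n in all_names}
    base_log_int = {
        n: rng.normal(design.intensity_log_mu, design.intensity_log_sd)
        for n in all_names
    }

    pos: list[IonFeature] = []
    neg: list[IonFeature] = []
    if design.plant_at not in ("formula", "library_mw"):
        raise ValueError(f"unknown plant_at mode {design.plant_at!r}")
    for name in all_names:
        compound = by_name[name]
        if design.plant_at == "library_mw" and compound.library_mw:
            neutral = compound.library_mw
        else:
            neutral = compound.monoisotopic_mass
        truth.compound_neutral_mass[name] = neutral
        truth.compound_rt[name] = base_rt[name]
        planted_in = [e for e in design.extract_ids() if name in plan[e]]
        truth.compound_extracts[name] = []
        for ext in planted_in:
            if design.dropout_rate > 0 and rng.random() < design.dropout_rate:
                continue
            truth.compound_extracts[name].append(ext)
            for adduct, sink, polarity in (
                (PROTONATED, pos, "positive"),
                (DEPROTONATED, neg, "negative"),
            ):
                mz_exact = ion_mz_from_neutral(neutral, adduct)
                ppm = rng.normal(0.0, design.mass_error_ppm_sd)
                rt = max(0.0, base_rt[name] + rng.normal(0.0, design.rt_jitter_sd))
                intensity = float(np.exp(base_log_int[name] + rng.normal(0.0, 0.3)))
                sink.append(
                    IonFeature(
                        mz=mz_exact * (1.0 + ppm * 1e-6),
                        rt=rt,
                        intensity=intensity,
                        polarity=polarity,
                        sample_id=ext,
                    )
                )

    # decoys: masses kept >= 20 ppm away from every library mass
    lib_masses = np.array(
        sorted({c.monoisotopic_mass for c in library}
               | {c.library_mw for c in library if c.library_mw})
    )
    n_decoys = 0
    while n_decoys < design.n_decoy_features:
        mass = rng.uniform(150.0, 900.0)
        if np.min(np.abs(lib_masses - mass)) / mass * 1e6 < 20.0:
            continue
        n_decoys += 1
        truth.decoy_masses.append(mass)
        rt0 = rng.uniform(0.5, 10.0)
        log_int = rng.normal(design.intensity_log_mu, design.intensity_log_sd)
        adduct, sink, polarity = (
            (PROTONATED, pos, "positive") if rng.random() < 0.5
            else (DEPROTONATED, neg, "negative")
        )
        for ext in design.extract_ids():
            if rng.random() < 0.4:  # decoys present in a subset of extracts
                continue
            ppm = rng.normal(0.0, design.mass_error_ppm_sd)
            sink.append(
                IonFeature(
                    mz=ion_mz_from_neutral(mass, adduct) * (1.0 + ppm * 1e-6),
                    rt=max(0.0, rt0 + rng.normal(0.0, design.rt_jitter_sd)),
                    intensity=float(np.exp(log_int + rng.normal(0.0, 0.3))),
                    polarity=polarity,
                    sample_id=ext,
                )
            )
    return pos, neg, truth


def _features_to_frame(features: Sequence[IonFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mz": f"{f.mz:.6f}", "rt": f"{f.rt:.3f}", "intensity": f"{f.intensity:.1f}",
             "polarity": f.polarity, "sample": f.sample_id}
            for f in features
        ],
        columns=["mz", "rt", "intensity", "polarity", "sample"],
    )


def write_extract_profiles(design: SimulationDesign, out_dir: str | Path
                           ) -> tuple[Path, Path, GroundTruth]:
    """Run :func:`simulate_extract_profiles` and write pos/neg CSVs.

    Numeric fields are formatted with fixed precision so identical designs
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos, neg, truth = simulate_extract_profiles(design)
    pos_path = out_dir / "peaks_positive.csv"
    neg_path = out_dir / "peaks_negative.csv"
    _features_to_frame(pos).to_csv(pos_path, index=False)
    _features_to_frame(neg).to_csv(neg_path, index=False)
    return pos_path, neg_path, truth


@dataclass
class IntensityDesign:
    """Design for the grouped sample x feature intensity simulation."""

    n_groups: int = 5
    replicates_per_group: int = 3
    n_features: int = 200
    n_discriminatory: int = 10
    effect_size: float = 3.0  # in units of the residual log-s.d.
    baseline_log_mu: float = 13.0
    baseline_log_sd: float = 1.0
    residual_log_sd: float = 0.5
    outlier_group: int | None = None
    n_outlier_features: int = 40
    outlier_effect: float = 4.0
    seed: int = 0


def simulate_intensity_matrix(
    design: IntensityDesign,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Grouped log-normal intensity matrix with planted discriminants.

    Discriminatory features are assigned round-robin to groups and shifted
    upward by ``effect_size`` residual log-s.d. units in their group.  When
    ``outlier_group`` is set, that group additionally receives a broad
    profile shift over ``n_outlier_features`` features — one deliberately
    distinct extract, as seen in real crude-extract panels.
    """
    if design.effect_size < 0:
        raise ValueError("effect size must be non-negative")
    if design.n_groups < 2:
        raise ValueError("need >=2 groups for discriminant planting")
    rng = np.random.default_rng(design.seed)
    n = design.n_groups * design.replicates_per_group
    p = design.n_features
    baseline = rng.normal(design.baseline_log_mu, design.baseline_log_sd, size=p)
    log_x = baseline + rng.normal(0.0, design.residual_log_sd, size=(n, p))

    groups = np.repeat([f"group{g + 1}" for g in range(design.n_groups)],
                       design.replicates_per_group)
    feature_ids = [f"F{j + 1:04d}" for j in range(p)]
    truth = GroundTruth()

    shift = design.effect_size * design.residual_log_sd
    for d in range(design.n_discriminatory):
        j = d  # the first n_discriminatory features are the planted ones
        g = d % design.n_groups
        log_x[groups == f"group{g + 1}", j] += shift
        truth.discriminatory_features.append(feature_ids[j])

    if design.outlier_group is not None:
        g = design.outlier_group
        cols = rng.choice(
            np.arange(design.n_discriminatory, p),
            size=min(design.n_outlier_features, p - design.n_discriminatory),
            replace=False,
        )
        signs = rng.choice([-1.0, 1.0], size=cols.size)
        mask = groups == f"group{g + 1}"
        log_x[np.ix_(mask, cols)] += signs * design.outlier_effect * design.residual_log_sd

    sample_ids = [f"{g}_r{r + 1}" for g in [f"group{i + 1}" for i in range(design.n_groups)]
                  for r in range(design.replicates_per_group)]
    matrix = pd.DataFrame(np.exp(log_x), index=sample_ids, columns=feature_ids)
    labels = pd.Series(groups, index=sample_ids, name="group")
    truth.group_labels = dict(zip(sample_ids, groups))
    return matrix, labels, truth


def simulate_dose_response(
    true_ic50: float,
    hill: float = 1.2,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd: float = 0.0,
    replicates: int = 3,
    doses: Sequence[float] = DEFAULT_DOSES,
    seed: int = 0,
    control_corr: float = 1.0,
    blank_corr: float = 0.1,
    background: float = 0.05,
) -> tuple[pd.DataFrame, GroundTruth]:
    """MTT plate table generated from a known 4PL survival curve.

    Viabilities (percent of control) at the dose series are converted to
    570/690 nm absorbance pairs via the control/blank anchors; Gaussian
    measurement noise with a coefficient of variation of ``noise_sd``
    percent (the usual plate-reader error model, proportional to signal)
    is applied to each treated well's corrected absorbance.  Returns the
    plate as a tidy DataFrame with columns well, role, dose, a570, a690,
    replicate, plus the ground truth.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be positive")
    rng = np.random.default_rng(seed)
    doses = np.asarray(list(doses), dtype=float)
    rows = []
    span = control_corr - blank_corr
    well = 0
    for rep in range(1, replicates + 1):
        for dose in doses:
            v = float(four_param_logistic(dose, true_ic50, hill, top, bottom))
            corr = blank_corr + v / 100.0 * span
            if noise_sd > 0:
                corr *= 1.0 + rng.normal(0.0, noise_sd / 100.0)
            rows.append({"well": f"W{well:03d}", "role": "treated", "dose": dose,
                         "a570": corr + background, "a690": background,
                         "replicate": rep})
            well += 1
        rows.append({"well": f"W{well:03d}", "role": "control", "dose": 0.0,
                     "a570": control_corr + background, "a690": background,
                     "replicate": rep})
        well += 1
        rows.append({"well": f"W{well:03d}", "role": "blank", "dose": 0.0,
                     "a570": blank_corr + background, "a690": background,
                     "replicate": rep})
        well += 1
    truth = GroundTruth(
        true_ic50=true_ic50,
        true_params={"hill": hill, "top": top, "bottom": bottom,
                     "noise_sd": noise_sd},
    )
    return pd.DataFrame(rows), truth
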