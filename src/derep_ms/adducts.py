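"""Adduct arithmetic, cross-sample feature alignment and polarity merging.

An electrospray source observes a neutral molecule M as charged adduct
species; in this workflow, as the protonated [M+H]+ ion in positive mode
and the deprotonated [M-H]- ion in negative mode.  Converting measured m/z
back to the neutral monoisotopic mass (the "MW" of a dereplication table)
and combining the two ionization modes into one neutral feature list are
the two steps this module implements, together with greedy m/z + RT
alignment of peak lists across samples.

The proton mass constant used is 1.00728 Da (electron-corrected), which
reproduces literature MW columns at 4-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .peaks import FeatureMatrix, IonFeature

__all__ = [
    "PROTON_MASS",
    "Adduct",
    "ADDUCT_REGISTRY",
    "NeutralFeature",
    "neutral_mass_from_ion",
    "ion_mz_from_neutral",
    "align_features",
    "matrix_to_neutral_features",
    "merge_polarities",
]

#: Electron-corrected proton mass shift (Da) for +/-1 protonation.
PROTON_MASS = 1.00728

Provenance = Literal["positive_only", "negative_only", "both_modes"]


@dataclass(frozen=True)
class Adduct:
    """An ionized species: label, signed mass shift (Da) and charge."""

    label: str
    mass_shift: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


PROTONATED = Adduct("[M+H]+", +PROTON_MASS, +1)
DEPROTONATED = Adduct("[M-H]-", -PROTON_MASS, -1)

#: Default registry: the two singly-charged proton adducts.  Extensible —
#: additional species (e.g. sodiated) can be registered via config.
ADDUCT_REGISTRY: dict[str, Adduct] = {
    PROTONATED.label: PROTONATED,
    DEPROTONATED.label: DEPROTONATED,
    # common alternative spellings
    "[M+H]": PROTONATED,
    "[M-H]": DEPROTONATED,
}


def get_adduct(label_or_polarity: str) -> Adduct:
    """Resolve an adduct by registry label or by polarity name."""
    key = label_or_polarity.strip()
    if key in ADDUCT_REGISTRY:
        return ADDUCT_REGISTRY[key]
    norm = key.replace(" ", "").replace("−", "-").replace("^", "")
    for cand, adduct in ADDUCT_REGISTRY.items():
        if norm.startswith(cand):
            return adduct
    if key.lower() in ("positive", "pos"):
        return PROTONATED
    if key.lower() in ("negative", "neg"):
        return DEPROTONATED
    raise KeyError(f"unknown adduct {label_or_polarity!r}")


def neutral_mass_from_ion(mz: float, adduct: Adduct) -> float:
    """Neutral monoisotopic mass implied by an observed m/z under an adduct.

    neutral = mz * |charge| - mass_shift.  Report at 4 decimals for tables;
    the unrounded value is returned (and retained) for computation.
    """
    neutral = mz * abs(adduct.charge) - adduct.mass_shift
    if neutral <= 0:
        raise ValueError(
            f"m/z {mz} under adduct {adduct.label} implies non-positive neutral mass"
        )
    return neutral


def ion_mz_from_neutral(neutral: float, adduct: Adduct) -> float:
    """Exact inverse of :func:`neutral_mass_from_ion` (unrounded)."""
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral + adduct.mass_shift) / abs(adduct.charge)


@dataclass
class NeutralFeature:
    """A (possibly cross-polarity) feature on the neutral-mass scale."""

    neutral_mass: float
    rt: float
    per_sample_intensity: dict[str, float]
    supporting_ions: list[IonFeature] = field(default_factory=list)
    provenance: Provenance = "positive_only"
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if not self.feature_id:
            self.feature_id = f"M{self.neutral_mass:.4f}T{self.rt:.2f}"

    @property
    def total_intensity(self) -> float:
        return float(sum(self.per_sample_intensity.values()))


def align_features(
    per_sample_features: Iterable[IonFeature] | Sequence[Sequence[IonFeature]],
    ppm_tol: float = 5.0,
    rt_tol: float = 0.1,
) -> FeatureMatrix:
    """Align single-polarity peak lists across samples into a FeatureMatrix.

    Greedy clustering: peaks are processed in ascending m/z; a peak joins
    the current cluster while it stays within ``ppm_tol`` of the cluster's
    intensity-weighted mean m/z and within ``rt_tol`` of its weighted mean
    RT, otherwise it opens a new cluster.  Column m/z and RT are the
    intensity-weighted means; a sample absent from a cluster gets 0.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    feats: list[IonFeature] = []
    for item in per_sample_features:
        if isinstance(item, IonFeature):
            feats.append(item)
        else:
            feats.extend(item)
    polarities = {f.polarity for f in feats}
    if len(polarities) > 1:
        raise ValueError(f"align_features requires a single polarity, got {polarities}")
    polarity = polarities.pop() if polarities else "positive"

    feats.sort(key=lambda f: (f.mz, f.rt))
    clusters: list[list[IonFeature]] = []
    for f in feats:
        placed = False
        # scan open clusters from the most recent; m/z ordering means only
        # nearby clusters can still be within tolerance
        for cluster in reversed(clusters):
            cmz, crt = _weighted_center(cluster)
            if 1e6 * (f.mz - cmz) / cmz > ppm_tol:
                break
            if abs(1e6 * (f.mz - cmz) / cmz) <= ppm_tol and abs(f.rt - crt) <= rt_tol:
                cluster.append(f)
                placed = True
                break
        if not placed:
            clusters.append([f])

    sample_ids = sorted({f.sample_id for f in feats})
    columns, meta_rows = {}, []
    for cluster in sorted(clusters, key=lambda c: _weighted_center(c)[0]):
        cmz, crt = _weighted_center(cluster)
        fid = f"{'P' if polarity == 'positive' else 'N'}{cmz:.4f}T{crt:.2f}"
        if fid in columns:  # same centroid twice (RT-split isobars)
            k = 2
            while f"{fid}_{k}" in columns:
                k += 1
            fid = f"{fid}_{k}"
        col = dict.fromkeys(sample_ids, 0.0)
        for f in cluster:
            col[f.sample_id] += f.intensity
        columns[fid] = col
        meta_rows.append({"feature_id": fid, "mz": cmz, "rt": crt,
                          "polarity": polarity, "n_peaks": len(cluster)})
    values = pd.DataFrame(columns, index=sample_ids, dtype=float)
    meta = pd.DataFrame(meta_rows).set_index("feature_id") if meta_rows else pd.DataFrame()
    return FeatureMatrix(values=values, feature_meta=meta)


def _weighted_center(cluster: Sequence[IonFeature]) -> tuple[float, float]:
    w = np.array([max(f.intensity, 1e-30) for f in cluster])
    mz = np.array([f.mz for f in cluster])
    rt = np.array([f.rt for f in cluster])
    return float(np.average(mz, weights=w)), float(np.average(rt, weights=w))


def matrix_to_neutral_features(matrix: FeatureMatrix, adduct: Adduct) -> list[NeutralFeature]:
    """Convert an aligned single-polarity matrix to neutral features."""
    provenance: Provenance = (
        "positive_only" if adduct.mass_shift > 0 else "negative_only"
    )
    out = []
    for fid in matrix.feature_ids:
        mz = float(matrix.feature_meta.loc[fid, "mz"])
        rt = float(matrix.feature_meta.loc[fid, "rt"])
        intensities = {
            s: float(v) for s, v in matrix.values[fid].items() if v > 0
        }
        out.append(
            NeutralFeature(
                neutral_mass=neutral_mass_from_ion(mz, adduct),
                rt=rt,
                per_sample_intensity=intensities,
                provenance=provenance,
                feature_id=fid,
            )
        )
    return out


def merge_polarities(
    pos: Sequence[NeutralFeature],
    neg: Sequence[NeutralFeature],
    ppm_tol: float = 5.0,
    rt_tol: float = 0.1,
) -> list[NeutralFeature]:
    """Merge positive- and negative-mode neutral features.

    Candidate pairs agreeing within both tolerances are merged best-first
    by smaller \\|delta ppm\\| (ties: earlier RT); each feature merges at
    most once.  A merged feature has provenance ``both_modes``, per-sample
    intensities summed, and neutral mass equal to the total-intensity-
    weighted mean of the pair.  Unpaired features pass through.  Total
    intensity is conserved.
    """
    candidates = []
    for i, p in enumerate(pos):
        for j, n in enumerate(neg):
            dppm = 1e6 * (p.neutral_mass - n.neutral_mass) / n.neutral_mass
            if abs(dppm) <= ppm_tol and abs(p.rt - n.rt) <= rt_tol:
                candidates.append((abs(dppm), min(p.rt, n.rt), i, j))
    candidates.sort()
    used_p, used_n = set(), set()
    merged: list[NeutralFeature] = []
    for _, _, i, j in candidates:
        if i in used_p or j in used_n:
            continue
        used_p.add(i)
        used_n.add(j)
        p, n = pos[i], neg[j]
        wp, wn = max(p.total_intensity, 1e-30), max(n.total_intensity, 1e-30)
        mass = (p.neutral_mass * wp + n.neutral_mass * wn) / (wp + wn)
        rt = (p.rt * wp + n.rt * wn) / (wp + wn)
        intensities = dict(p.per_sample_intensity)
        for s, v in n.per_sample_intensity.items():
            intensities[s] = intensities.get(s, 0.0) + v
        merged.append(
            NeutralFeature(
                neutral_mass=mass,
                rt=rt,
                per_sample_intensity=intensities,
                supporting_ions=list(p.supporting_ions) + list(n.supporting_ions),
                provenance="both_modes",
                feature_id=f"B{mass:.4f}T{rt:.2f}",
            )
        )
    merged.extend(p for i, p in enumerate(pos) if i not in used_p)
    merged.extend(n for j, n in enumerate(neg) if j not in used_n)
    merged.sort(key=lambda f: (f.neutral_mass, f.rt))
    return merged
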