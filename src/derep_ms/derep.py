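"""Library matching of neutral features: the dereplication step.

Dereplication screens detected metabolite features against a library of
known natural products so that already-described compounds are recognized
before any isolation effort.  Matching is on neutral monoisotopic mass
only, within a ppm tolerance; retention time is carried through reports
for human inspection but never compared (it is not transferable across
chromatographic setups).  All compounds within tolerance are reported —
mass alone cannot distinguish isobars, and a feature legitimately
dereplicates to several candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .adducts import NeutralFeature
from .peaks import CompoundRecord

__all__ = [
    "DereplicationHit",
    "DereplicationReport",
    "ppm_error",
    "match_feature",
    "dereplicate_table",
    "filter_hits_by_source",
]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class DereplicationHit:
    """One feature <-> library compound match within tolerance."""

    feature: NeutralFeature
    compound: CompoundRecord
    ppm_error: float
    adduct_context: str = ""


@dataclass
class DereplicationReport:
    """Per-feature dereplication outcome over a feature list."""

    features: list[NeutralFeature]
    hits: dict[str, list[DereplicationHit]]  # feature_id -> hits (|ppm| asc)
    tol_ppm: float

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_hit(self) -> int:
        return sum(1 for f in self.features if self.hits.get(f.feature_id))

    @property
    def n_no_hit(self) -> int:
        return self.n_features - self.n_hit

    def status(self, feature_id: str) -> str:
        return "hit" if self.hits.get(feature_id) else "no_hit"

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per (feature, hit) — or per feature if no hit."""
        rows = []
        for f in self.features:
            fhits = self.hits.get(f.feature_id, [])
            base = {
                "feature_id": f.feature_id,
                "neutral_mass": round(f.neutral_mass, 4),
                "rt": round(f.rt, 2),
                "provenance": f.provenance,
                "status": "hit" if fhits else "no_hit",
            }
            if not fhits:
                rows.append({**base, "compound": "", "formula": "", "ppm_error": "",
                             "source_organism": "", "reference": ""})
            for h in fhits:
                rows.append({**base,
                             "compound": h.compound.name,
                             "formula": h.compound.formula.hill(),
                             "ppm_error": round(h.ppm_error, 2),
                             "source_organism": h.compound.source_organism,
                             "reference": h.compound.reference_tag})
        return pd.DataFrame(rows)

    def summary(self) -> dict[str, int]:
        return {"n_features": self.n_features, "n_hit": self.n_hit,
                "n_no_hit": self.n_no_hit}


def match_feature(
    feature: NeutralFeature,
    library: Sequence[CompoundRecord],
    tol_ppm: float = 5.0,
) -> list[DereplicationHit]:
    """All library compounds within ``tol_ppm`` of the feature's neutral mass.

    Sorted by \\|ppm error\\| ascending, ties alphabetical by compound name.
    An empty list means no hit.
    """
    hits = []
    for compound in library:
        err = ppm_error(feature.neutral_mass, compound.monoisotopic_mass)
        if abs(err) <= tol_ppm:
            hits.append(
                DereplicationHit(
                    feature=feature,
                    compound=compound,
                    ppm_error=err,
                    adduct_context=feature.provenance,
                )
            )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.compound.name))
    return hits


def dereplicate_table(
    features: Sequence[NeutralFeature],
    library: Sequence[CompoundRecord],
    tol_ppm: float = 5.0,
) -> DereplicationReport:
    """Apply :func:`match_feature` to every feature and tally hit status."""
    hits = {f.feature_id: match_feature(f, library, tol_ppm) for f in features}
    return DereplicationReport(features=list(features), hits=hits, tol_ppm=tol_ppm)


def filter_hits_by_source(
    hits: Sequence[DereplicationHit], keyword: str = "Streptomyces"
) -> list[DereplicationHit]:
    """Source-organism text screen (e.g. keep only actinobacterial hits).

    Stands in for the secondary taxon-restricted database lookup of the
    original workflow; a plain case-insensitive substring match.
    """
    kw = keyword.lower()
    return [h for h in hits if kw in h.compound.source_organism.lower()]
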