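"""Peak-list, feature-matrix and compound-library I/O plus core record types.

The ingestion boundary of the pipeline is the *peak list*: per-sample,
per-polarity tables of (m/z, retention time, intensity) as produced by any
peak-picking tool.  Chromatographic peak detection from raw profile data is
deliberately out of scope; optional mzML support reads already-centroided
spectra.  All text I/O is UTF-8 with the delimiter inferred from the file
extension (.csv / .tsv) and "." as the decimal mark.
"""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .formula import MolecularFormula, parse_formula

__all__ = [
    "IonFeature",
    "CompoundRecord",
    "FeatureMatrix",
    "PeakListFormatError",
    "read_peak_list",
    "read_mzml_peaks",
    "read_compound_library",
    "bundled_library",
    "bundled_library_table",
    "write_report",
    "read_report",
]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

Polarity = Literal["positive", "negative"]


class PeakListFormatError(ValueError):
    """Malformed peak list / library table (missing columns, bad values)."""


@dataclass(frozen=True)
class IonFeature:
    """One detected ion peak in one sample and one ionization mode."""

    mz: float
    rt: float
    intensity: float
    polarity: Polarity
    sample_id: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be non-negative, got {self.rt}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A reference library entry: named compound with a molecular formula.

    ``monoisotopic_mass`` is always derived from the formula; the optional
    literature annotations (adduct, m/z, RT, printed MW) are carried for
    reporting and for validating library provenance, never for matching.
    """

    name: str
    formula: MolecularFormula
    source_organism: str = ""
    reference_tag: str = ""
    activity_note: str = ""
    library_mz: float | None = None
    library_adduct: str | None = None
    library_rt: float | None = None
    library_mw: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")

    @property
    def monoisotopic_mass(self) -> float:
        return self.formula.monoisotopic_mass


@dataclass
class FeatureMatrix:
    """Samples x features intensity matrix with per-feature metadata.

    ``values`` is a DataFrame indexed by sample id with feature ids as
    columns; ``feature_meta`` is indexed by feature id and carries at least
    a representative mass column (``mz`` or ``neutral_mass``) and ``rt``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    group_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensity matrix must be non-negative")
        if not self.feature_meta.empty and not self.feature_meta.index.equals(
            self.values.columns
        ):
            raise ValueError("feature_meta index must match value columns")
        if self.group_labels is not None:
            self.group_labels = pd.Series(self.group_labels, index=self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


_COLUMN_ALIASES = {
    "csv_simple": {"mz": ["mz", "m/z"], "rt": ["rt", "rt_min", "retention_time"],
                   "intensity": ["intensity", "area", "height"],
                   "polarity": ["polarity", "mode"], "sample": ["sample", "sample_id"]},
    "mzmine_export": {"mz": ["row m/z", "mz", "m/z"],
                      "rt": ["row retention time", "rt"],
                      "intensity": ["peak area", "peak height", "intensity"],
                      "polarity": ["polarity", "mode"], "sample": ["sample", "sample_id"]},
}


def _resolve(header: Sequence[str], aliases: Sequence[str]) -> str | None:
    lower = {h.strip().lower(): h for h in header}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def read_peak_list(
    path: str | Path,
    dialect: Literal["csv_simple", "mzmine_export"] = "csv_simple",
    polarity: Polarity | None = None,
    sample_id: str | None = None,
) -> list[IonFeature]:
    """Read a delimited peak list into :class:`IonFeature` records.

    ``polarity`` and ``sample_id`` may be given per file; otherwise they
    must be resolvable from columns.  Row order is preserved.  Malformed
    rows raise :class:`PeakListFormatError` naming the 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    aliases = _COLUMN_ALIASES[dialect]
    features: list[IonFeature] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter_for(path))
        if reader.fieldnames is None:
            raise PeakListFormatError(f"{path}: empty file, no header")
        header = reader.fieldnames
        cols: dict[str, str | None] = {k: _resolve(header, v) for k, v in aliases.items()}
        for required in ("mz", "rt", "intensity"):
            if cols[required] is None:
                raise PeakListFormatError(
                    f"{path}: missing required column for {required!r} "
                    f"(accepted names: {aliases[required]})"
                )
        if polarity is None and cols["polarity"] is None:
            raise PeakListFormatError(
                f"{path}: polarity not given and no polarity column present"
            )
        for i, row in enumerate(reader, start=1):
            try:
                pol = polarity if polarity is not None else _norm_polarity(row[cols["polarity"]])
                sid = (
                    sample_id
                    if sample_id is not None
                    else (row.get(cols["sample"], "") if cols["sample"] else path.stem)
                ) or path.stem
                features.append(
                    IonFeature(
                        mz=float(row[cols["mz"]]),
                        rt=float(row[cols["rt"]]),
                        intensity=float(row[cols["intensity"]]),
                        polarity=pol,
                        sample_id=str(sid),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise PeakListFormatError(f"{path}: invalid row {i}: {exc}") from exc
    if not features:
        log.warning("%s: peak list contains a header but no rows", path)
    return features


def _norm_polarity(raw: str) -> Polarity:
    s = str(raw).strip().lower()
    if s in ("positive", "pos", "+", "1"):
        return "positive"
    if s in ("negative", "neg", "-", "-1"):
        return "negative"
    raise ValueError(f"unrecognized polarity {raw!r}")


def read_mzml_peaks(
    path: str | Path, polarity: Polarity, sample_id: str | None = None,
    min_intensity: float = 0.0,
) -> list[IonFeature]:
    """Read centroided MS1 spectra from an mzML file into IonFeatures.

    Every centroid of every MS1 spectrum of the requested polarity becomes
    one feature at the spectrum's scan start time (minutes; seconds are
    converted).  Supports 32/64-bit float arrays, uncompressed or
    zlib-compressed.  A minimal reader for already-centroided data only —
    profile-mode processing is out of scope.
    """
    import base64
    import zlib

    from lxml import etree

    path = Path(path)
    sid = sample_id or path.stem
    wanted = "MS:1000130" if polarity == "positive" else "MS:1000129"
    ns = {"m": "http://psi.hupo.org/ms/mzml"}

    def _params(el) -> dict[str, str]:
        return {
            cv.get("accession"): cv.get("value", "")
            for cv in el.findall("m:cvParam", ns)
        } | {
            cv.get("accession"): cv.get("value", "")
            for cv in el.findall("cvParam")  # tolerate missing default ns
        }

    def _decode(bda) -> np.ndarray:
        p = _params(bda)
        binary = bda.find("m:binary", ns)
        if binary is None:
            binary = bda.find("binary")
        raw = base64.b64decode((binary.text or "").strip())
        if "MS:1000574" in p:  # zlib compression
            raw = zlib.decompress(raw)
        dtype = "<f4" if "MS:1000521" in p else "<f8"
        return np.frombuffer(raw, dtype=dtype).astype(float)

    out: list[IonFeature] = []
    tree = etree.parse(str(path))
    root = tree.getroot()
    spectra = root.findall(".//m:spectrum", ns) or root.findall(".//spectrum")
    for spec in spectra:
        p = _params(spec)
        if p.get("MS:1000511", "1") != "1" or wanted not in p:
            continue
        rt = 0.0
        for scan in spec.findall(".//m:scan", ns) or spec.findall(".//scan"):
            sp = _params(scan)
            if "MS:1000016" in sp:
                rt = float(sp["MS:1000016"])
                cv_elems = scan.findall("m:cvParam", ns) or scan.findall("cvParam")
                unit = next(
                    (c.get("unitName", "") for c in cv_elems
                     if c.get("accession") == "MS:1000016"),
                    "minute",
                )
                if unit.lower().startswith("second"):
                    rt /= 60.0
        mz_arr = inten_arr = None
        bdas = spec.findall(".//m:binaryDataArray", ns) or spec.findall(
            ".//binaryDataArray"
        )
        for bda in bdas:
            bp = _params(bda)
            if "MS:1000514" in bp:
                mz_arr = _decode(bda)
            elif "MS:1000515" in bp:
                inten_arr = _decode(bda)
        if mz_arr is None or inten_arr is None:
            continue
        for mz, inten in zip(mz_arr, inten_arr):
            if inten >= min_intensity and mz > 0:
                out.append(IonFeature(float(mz), rt, float(inten), polarity, sid))
    return out


def read_compound_library(path: str | Path) -> list[CompoundRecord]:
    """Read a compound library table (TSV/CSV) into CompoundRecords.

    Requires ``name`` and ``formula`` columns; ``source`` / ``source_organism``,
    ``reference`` / ``reference_tag``, ``note``, and the optional literature
    annotation columns (``mz``, ``adduct``, ``rt_min``, ``mw``) are picked up
    when present.  Duplicate names are allowed but warned about.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str, encoding="utf-8")
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("name", "formula"):
        if required not in df.columns:
            raise PeakListFormatError(f"{path}: missing required column {required!r}")
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        name = str(row["name"]).strip()
        try:
            formula = parse_formula(str(row["formula"]))
        except Exception as exc:
            raise PeakListFormatError(
                f"{path}: record {name!r}: bad formula {row['formula']!r}: {exc}"
            ) from exc
        records.append(
            CompoundRecord(
                name=name,
                formula=formula,
                source_organism=_opt_str(row, "source_organism") or _opt_str(row, "source") or "",
                reference_tag=_opt_str(row, "reference_tag") or _opt_str(row, "reference") or "",
                activity_note=_opt_str(row, "note") or "",
                library_mz=_opt_float(row, "mz"),
                library_adduct=_opt_str(row, "adduct") or _opt_str(row, "ionization"),
                library_rt=_opt_float(row, "rt_min") or _opt_float(row, "rt"),
                library_mw=_opt_float(row, "mw"),
            )
        )
    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        warnings.warn(f"{path}: duplicate compound names: {sorted(dupes)}", stacklevel=2)
    return records


def _opt_str(row: pd.Series, col: str) -> str | None:
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return str(v).strip() or None


def _opt_float(row: pd.Series, col: str) -> float | None:
    s = _opt_str(row, col)
    return float(s) if s is not None else None


def bundled_library() -> list[CompoundRecord]:
    """The bundled 40-record mini-library of Streptomyces secondary metabolites.

    Each record carries the literature m/z, adduct, retention time and
    molecular weight alongside the formula.  Record 39 of the source table
    is internally inconsistent (its printed positive-mode m/z does not match
    the printed MW under proton-adduct arithmetic and duplicates record 10's
    negative-mode values); it is kept verbatim rather than silently corrected.
    """
    with importlib.resources.as_file(
        importlib.resources.files("derep_ms.data") / "actinomycete_library.tsv"
    ) as p:
        return read_compound_library(p)


def bundled_library_table() -> pd.DataFrame:
    """The bundled library as a raw DataFrame (one row per record)."""
    with importlib.resources.as_file(
        importlib.resources.files("derep_ms.data") / "actinomycete_library.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# generic report I/O


def write_report(
    records: Iterable[dict] | pd.DataFrame,
    path: str | Path,
    fmt: Literal["tsv", "json"] | None = None,
) -> None:
    """Write a tabular report (list of flat dicts or DataFrame) to TSV or JSON.

    JSON output wraps the records in ``{"schema_version": ..., "records": [...]}``.
    Round-trips through :func:`read_report`.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")
    elif fmt == "json":
        doc = {"schema_version": REPORT_SCHEMA_VERSION,
               "records": df.to_dict(orient="records")}
        path.write_text(json.dumps(doc, indent=2, default=_json_default), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _json_default(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        return pd.DataFrame(doc["records"])
    return pd.read_csv(path, sep="\t", encoding="utf-8")
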