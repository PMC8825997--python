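"""End-to-end run orchestration: simulate/ingest -> annotate -> dereplicate
-> chemometrics -> bioassay, with a YAML config and a run manifest.

All interchange between stages happens through files in the run directory
(no hidden state), so each stage's inputs and outputs can be audited.
Re-running with the same config and seed is bit-identical in every
TSV/JSON output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .adducts import (
    DEPROTONATED,
    PROTONATED,
    align_features,
    matrix_to_neutral_features,
    merge_polarities,
)
from .bioactivity import fit_ic50, viability_from_plate
from .chemometrics import (
    fit_pca,
    fit_plsda,
    hca,
    heatmap_data,
    pareto_scale,
    q2_crossval,
    vip_scores,
)
from .derep import dereplicate_table
from .peaks import bundled_library, read_compound_library, read_peak_list, write_report
from .simulate import SimulationDesign, write_extract_profiles

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one of ``peaks`` (paths to existing positive/negative peak
    lists) or ``simulate`` (a simulation design) must be given.
    """

    out_dir: Path
    seed: int = 0
    peaks_positive: Path | None = None
    peaks_negative: Path | None = None
    simulate: dict[str, Any] | None = None
    library: Path | None = None
    ppm_tol: float = 5.0
    rt_tol: float = 0.1
    ncomp: int = 2
    top_n: int = 50
    linkage: str = "ward"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        has_paths = self.peaks_positive is not None or self.peaks_negative is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError(
                "config must give exactly one of input peak paths or a "
                "simulation design"
            )
        if self.ppm_tol <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {k: doc[k] for k in doc if k in cls.__dataclass_fields__}
        unknown = set(doc) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("peaks_positive", "peaks_negative", "library"):
            if known.get(key) is not None:
                known[key] = Path(known[key])
        return cls(**known)


@dataclass
class RunManifest:
    """Record counts, checksums and the config echo of a finished run."""

    config: dict[str, Any]
    version: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str),
                        encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and write the manifest last.

    Any stage failure raises :class:`PipelineError` naming the stage;
    partial outputs are retained but no manifest is written.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={k: str(v) for k, v in config.__dict__.items()},
        version=__version__,
    )

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", name, manifest.timings_s[name])
        return result

    # -- stage 1: obtain peak lists ----------------------------------------
    def _ingest():
        if config.simulate is not None:
            design = SimulationDesign(**{**config.simulate, "seed": config.seed})
            pos_path, neg_path, truth = write_extract_profiles(design, out)
            (out / "ground_truth.json").write_text(
                json.dumps(truth.__dict__, indent=2, default=str), encoding="utf-8"
            )
        else:
            pos_path, neg_path = config.peaks_positive, config.peaks_negative
        pos = read_peak_list(pos_path, polarity="positive") if pos_path else []
        neg = read_peak_list(neg_path, polarity="negative") if neg_path else []
        return pos, neg

    pos, neg = run_stage("ingest", _ingest)
    manifest.stage_counts["peaks_positive"] = len(pos)
    manifest.stage_counts["peaks_negative"] = len(neg)

    # -- stage 2: align + neutralize + merge polarities --------------------
    def _annotate():
        merged_inputs = []
        matrices = {}
        for feats, adduct, tag in ((pos, PROTONATED, "positive"),
                                   (neg, DEPROTONATED, "negative")):
            if not feats:
                continue
            fm = align_features(feats, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol)
            matrices[tag] = fm
            merged_inputs.append(matrix_to_neutral_features(fm, adduct))
        while len(merged_inputs) < 2:
            merged_inputs.append([])
        features = merge_polarities(
            merged_inputs[0], merged_inputs[1],
            ppm_tol=config.ppm_tol, rt_tol=config.rt_tol,
        )
        return features, matrices

    features, matrices = run_stage("annotate", _annotate)
    manifest.stage_counts["neutral_features"] = len(features)

    # -- stage 3: dereplicate ----------------------------------------------
    def _dereplicate():
        library = (read_compound_library(config.library)
                   if config.library else bundled_library())
        report = dereplicate_table(features, library, tol_ppm=config.ppm_tol)
        write_report(report.to_frame(), out / "dereplication.tsv")
        return report

    report = run_stage("dereplicate", _dereplicate)
    manifest.stage_counts["features_in"] = report.n_features
    manifest.stage_counts["features_hit"] = report.n_hit
    manifest.stage_counts["features_no_hit"] = report.n_no_hit

    # -- stage 4: chemometrics ---------------------------------------------
    def _chemometrics():
        samples = sorted({s for f in features for s in f.per_sample_intensity})
        values = pd.DataFrame(
            {f.feature_id: [f.per_sample_intensity.get(s, 0.0) for s in samples]
             for f in features},
            index=samples,
        )
        if values.shape[0] < 3:
            log.warning("fewer than 3 samples; skipping chemometrics")
            return None
        scaled = pareto_scale(values)
        ncomp = min(config.ncomp, values.shape[0] - 1, values.shape[1])
        pca = fit_pca(scaled, ncomp)
        scores = pd.DataFrame(pca.scores_, index=samples,
                              columns=[f"PC{i+1}" for i in range(ncomp)])
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            pca.loadings_, index=values.columns,
            columns=[f"PC{i+1}" for i in range(ncomp)],
        ).to_csv(out / "pca_loadings.tsv", sep="\t")
        diag = {
            "explained_variance_pct": pca.explained_variance_pct_.tolist(),
            "r2_cum": pca.r2_cum_.tolist(),
        }
        q2_comp = min(ncomp, values.shape[0] - 2)
        if q2_comp >= 1:
            diag["q2_cum"] = q2_crossval(scaled, q2_comp).tolist()
        (out / "pca_diagnostics.json").write_text(
            json.dumps(diag, indent=2), encoding="utf-8"
        )
        # one sample per extract: each extract is its own class
        labels = pd.Series(samples, index=samples)
        unique_labels = labels.nunique()
        if unique_labels >= 2:
            plsda = fit_plsda(scaled, labels, n_components=min(ncomp, len(samples) - 1))
            vip_scores(plsda).sort_values(ascending=False).to_csv(
                out / "vip.tsv", sep="\t", header=True
            )
        tree = hca(scaled, linkage=config.linkage)
        (out / "hca.newick").write_text(tree.to_newick(), encoding="utf-8")
        hm = heatmap_data(values, labels, n_top=config.top_n, linkage=config.linkage)
        hm.values.to_csv(out / "heatmap.tsv", sep="\t")
        return diag

    run_stage("chemometrics", _chemometrics)
    return _finalize(manifest, out)


def _finalize(manifest: RunManifest, out: Path) -> RunManifest:
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest


def run_bioassay(plate_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    """Fit per-replicate IC50s from a tidy plate CSV and write a report."""
    plate = pd.read_csv(plate_path)
    doses, via = viability_from_plate(plate)
    est = fit_ic50(doses, via)
    df = pd.DataFrame(
        [{"ic50": est.ic50, "sd": est.sd, "method": est.method,
          "extrapolated": est.extrapolated, "hill": est.hill,
          "top": est.top, "bottom": est.bottom,
          "replicates": len(est.replicate_ic50s)}]
    )
    write_report(df, out_path)
    return df
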