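"""End-to-end analysis pipeline.

Stages: feature extraction from curves and chromatograms, quality
classification by clustering the microbaking volumes, Spearman
screening of features against both volumes, construction of the
scoring configuration from the medium cluster, and scoring with an
accuracy report against the cluster classes.  Every intermediate is
materialised as CSV so a user can inject an externally measured
feature table at the feature stage and re-run only the later stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregation import AggregationCurve, extract_aggregation_features
from .classify import SampleRecord, cluster_quality, records_from_frame
from .correlate import correlation_table, select_scored_parameters, spearman
from .extension import ExtensionCurve, extract_extension_features
from .protein import Chromatogram, compose, integrate_windows
from .scoring import (ScoringConfig, medium_quantile_ranges, score_panel)
from .synthetic import PanelConfig, SyntheticPanel, generate_panel

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_pipeline",
           "extract_features"]

log = logging.getLogger("vitalgluten")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending sample."""

    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        sid = f" (sample {sample_id})" if sample_id else ""
        super().__init__(f"stage {stage!r}{sid}: {cause}")
        self.stage = stage
        self.sample_id = sample_id


@dataclass
class RunConfig:
    mode: str = "synthetic"                   # 'synthetic' or 'files'
    panel: PanelConfig = field(default_factory=PanelConfig)
    samples_csv: str | None = None            # files mode inputs
    aggregation_manifest: str | None = None
    extension_manifest: str | None = None
    chromatogram_manifest: str | None = None
    feature_table: str | None = None          # skip extraction entirely
    linkage_method: str = "ward"
    selection_rule: str = "both"
    alpha: float = 0.05
    include_cce: bool = True                  # fit CCE / score its parameters
    cce_source: str = "fit"                   # 'fit' or 'truth' (synthetic only)
    threshold_mode: str = "relative"          # 'absolute' needs published-scale weights
    outdir: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.cce_source not in ("fit", "truth"):
            raise ValueError("cce_source must be 'fit' or 'truth'")
        if self.mode == "files":
            if self.samples_csv is None:
                raise ValueError("files mode requires samples_csv")
            for p in (self.samples_csv, self.aggregation_manifest,
                      self.extension_manifest, self.chromatogram_manifest,
                      self.feature_table):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        if self.cce_source == "truth" and self.mode != "synthetic":
            raise ValueError("cce_source='truth' only applies to synthetic mode")


@dataclass
class PipelineResult:
    records: list[SampleRecord]
    features: pd.DataFrame | None
    cluster_counts: dict[str, int]
    correlations: pd.DataFrame | None
    weights: pd.DataFrame | None
    scoring_config: ScoringConfig | None
    scores: pd.DataFrame | None
    summary: dict


_CCE_COLUMNS = ("y0", "xc1", "a", "w", "k2", "xc2", "b", "k3", "xc3")


def extract_features(aggregation_curves: dict[str, AggregationCurve],
                     extension_curves: dict[str, ExtensionCurve],
                     chromatograms: dict[str, tuple[Chromatogram, Chromatogram]],
                     *, fit_cce: bool = True) -> pd.DataFrame:
    """Per-sample feature table from raw measurement data."""
    ids = (set(aggregation_curves) | set(extension_curves) | set(chromatograms))
    rows = []
    for sid in sorted(ids):
        row: dict[str, float] = {"sample_id": sid}
        try:
            if sid in aggregation_curves:
                af = extract_aggregation_features(aggregation_curves[sid],
                                                  fit=fit_cce)
                row.update(bem=af.bem, pmt=af.pmt, peak30=af.peak30,
                           peak180=af.peak180, ratio30_180=af.ratio30_180)
                if af.cce is not None:
                    row.update(y0=af.cce.y0, xc1=af.cce.xc1, a=af.cce.A,
                               w=af.cce.w, k2=af.cce.k2, xc2=af.cce.xc2,
                               b=af.cce.B, k3=af.cce.k3, xc3=af.cce.xc3,
                               cce_r_squared=af.r_squared)
            if sid in extension_curves:
                ef = extract_extension_features(extension_curves[sid])
                row.update(r_max=ef.r_max, e_rmax=ef.e_rmax, a_rmax=ef.a_rmax,
                           e_max=ef.e_max, a_max=ef.a_max,
                           ratio_ermax_rmax=ef.ratio_ermax_rmax,
                           ratio_emax_rmax=ef.ratio_emax_rmax)
            if sid in chromatograms:
                glia, glut = chromatograms[sid]
                comp = compose(integrate_windows(glia), integrate_windows(glut))
                row.update(comp.as_dict())
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError("feature-extraction", sid, exc) from exc
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _features_with_truth_cce(features: pd.DataFrame,
                             panel: SyntheticPanel) -> pd.DataFrame:
    out = features.copy()
    for col in _CCE_COLUMNS:
        out[col] = panel.truth[col]
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and return (and optionally write) the artifacts."""
    config.validate()
    log.setLevel(config.log_level.upper())
    log.info("vitalgluten %s, mode=%s, seed=%s", __version__, config.mode,
             config.panel.rng_seed if config.mode == "synthetic" else "n/a")

    panel = None
    features = None
    if config.mode == "synthetic":
        panel = generate_panel(config.panel)
        records = panel.records
        features = extract_features(
            panel.aggregation_curves, panel.extension_curves,
            panel.chromatograms,
            fit_cce=config.include_cce and config.cce_source == "fit")
        if config.include_cce and config.cce_source == "truth":
            features = _features_with_truth_cce(features, panel)
    else:
        frame = pd.read_csv(config.samples_csv)
        records = records_from_frame(frame)
        if config.feature_table is not None:
            features = pd.read_csv(config.feature_table).set_index("sample_id")
        else:
            base = Path(config.samples_csv).parent
            agg = _read_curves(config.aggregation_manifest, base, "aggregation")
            ext = _read_curves(config.extension_manifest, base, "extension")
            chrom = _read_chromatograms(config.chromatogram_manifest, base)
            if agg or ext or chrom:
                features = extract_features(agg, ext, chrom,
                                            fit_cce=config.include_cce)

    # classification
    try:
        cluster = cluster_quality(records, k=3, method=config.linkage_method)
    except Exception as exc:
        raise PipelineError("classification", None, exc) from exc
    volumes = pd.DataFrame(
        {"volume_A_ml_per_g": [r.specific_volume_a for r in records],
         "volume_B_ml_per_g": [r.specific_volume_b for r in records]},
        index=pd.Index([r.sample_id for r in records], name="sample_id"))
    labels = pd.Series(cluster.labels, index=volumes.index, name="quality_class")
    r_vol, p_vol = spearman(volumes["volume_A_ml_per_g"],
                            volumes["volume_B_ml_per_g"])
    summary = {
        "n_samples": len(records),
        "cluster_counts": cluster.counts,
        "volume_spearman_r": round(r_vol, 4),
        "volume_spearman_p": float(f"{p_vol:.3e}"),
    }

    correlations = weights = scoring_config = scores = None
    if features is not None:
        try:
            scorable = features.drop(columns=["cce_r_squared"], errors="ignore")
            if not config.include_cce:
                scorable = scorable.drop(columns=list(_CCE_COLUMNS),
                                         errors="ignore")
            correlations = correlation_table(scorable, volumes,
                                             alpha=config.alpha)
            weights = select_scored_parameters(correlations,
                                               alpha=config.alpha,
                                               rule=config.selection_rule)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("correlation", None, exc) from exc
        if len(weights) > 0:
            try:
                directions = dict(zip(weights["parameter"],
                                      weights["direction"]))
                ranges = medium_quantile_ranges(
                    scorable, labels.loc[scorable.index].to_numpy(),
                    list(weights["parameter"]), directions)
                scoring_config = ScoringConfig(
                    ranges=ranges,
                    weights=dict(zip(weights["parameter"], weights["weight"])),
                    threshold_mode=config.threshold_mode)
                report = score_panel(scorable[list(weights["parameter"])],
                                     scoring_config, reference=labels)
                scores = report.scores
                summary["scored_parameters"] = sorted(weights["parameter"])
                summary["max_total_score"] = round(scoring_config.max_total, 2)
                summary["accuracy_percent"] = report.accuracy_percent
            except Exception as exc:
                raise PipelineError("scoring", None, exc) from exc

    result = PipelineResult(records=records, features=features,
                            cluster_counts=cluster.counts,
                            correlations=correlations, weights=weights,
                            scoring_config=scoring_config, scores=scores,
                            summary=summary)
    if config.outdir is not None:
        _write_artifacts(result, labels, volumes, config)
    return result


def _read_curves(manifest, base: Path, kind: str):
    curves = {}
    if manifest is None:
        return curves
    man = pd.read_csv(manifest)
    for _, row in man.iterrows():
        sid = str(row["sample_id"])
        df = pd.read_csv(base / row["path"])
        try:
            if kind == "aggregation":
                curves[sid] = AggregationCurve(time=df.iloc[:, 0].to_numpy(),
                                               torque=df.iloc[:, 1].to_numpy())
            else:
                curves[sid] = ExtensionCurve(distance=df.iloc[:, 0].to_numpy(),
                                             force=df.iloc[:, 1].to_numpy())
        except Exception as exc:
            raise PipelineError(f"{kind}-input", sid, exc) from exc
    return curves


def _read_chromatograms(manifest, base: Path):
    chroms = {}
    if manifest is None:
        return chroms
    man = pd.read_csv(manifest)
    for _, row in man.iterrows():
        sid = str(row["sample_id"])
        try:
            pair = []
            for label in ("gliadin", "glutenin"):
                df = pd.read_csv(base / row[f"{label}_path"])
                pair.append(Chromatogram(retention=df.iloc[:, 0].to_numpy(),
                                         signal=df.iloc[:, 1].to_numpy(),
                                         extract_label=label))
            chroms[sid] = tuple(pair)
        except Exception as exc:
            raise PipelineError("chromatogram-input", sid, exc) from exc
    return chroms


def _write_artifacts(result: PipelineResult, labels: pd.Series,
                     volumes: pd.DataFrame, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    samples = volumes.copy()
    samples["quality_class"] = labels
    samples.to_csv(out / "samples_classified.csv")
    if result.features is not None:
        result.features.to_csv(out / "features.csv")
    if result.correlations is not None:
        result.correlations.to_csv(out / "correlations.csv", index=False)
    if result.weights is not None:
        result.weights.to_csv(out / "weights.csv", index=False)
    if result.scoring_config is not None:
        pd.DataFrame([{"parameter": p, "q25": r.q25, "q75": r.q75,
                       "direction": r.direction}
                      for p, r in result.scoring_config.ranges.items()
                      ]).to_csv(out / "ranges.csv", index=False)
    if result.scores is not None:
        result.scores.to_csv(out / "scores.csv")
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text(
        f"vitalgluten {__version__}\nmode: {config.mode}\n"
        f"seed: {config.panel.rng_seed}\nlinkage: {config.linkage_method}\n")
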