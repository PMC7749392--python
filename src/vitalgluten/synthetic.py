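"""Synthetic vital-gluten sample panels.

Real panels of this kind consist of a few dozen commercial vital gluten
samples, each characterised by two microbaking specific volumes, a
torque-time aggregation curve, force-distance extension curves and
GP-HPLC chromatograms of the two protein extracts.  The generator
emulates the statistical structure such a panel exhibits:

* every sample carries one latent quality scalar ``q`` in [0, 1] drawn
  around its class centre (good > medium > poor); all modalities derive
  from ``q``, which is what produces the cross-modal correlations the
  downstream analysis relies on;
* specific volume A is an affine function of ``q`` plus noise inside
  the observed 1.6-3.5 ml/g span; volume B is a monotone affine
  transform of A (shifted down by 0.5 ml/g) plus noise, so the
  between-recipe rank correlation is high by construction;
* aggregation curves are drawn from the Chesler--Cram peak family
  itself plus clipped Gaussian noise, which makes fit-quality checks
  meaningful and parameter recovery exact in the noise-free limit;
  good samples get early, sharp, tall peaks (low PMT, high BEM) and
  poor samples late, broad, low ones;
* extension curves rise smoothly to (E_Rmax, R_max), decline gently
  and rupture at E_max, with longer, larger curves for better samples;
* chromatograms are sums of Gaussian peaks centred inside the
  molecular-weight retention windows, scaled so window integration
  recovers the target composition; the gliadin-to-glutenin ratio
  increases with quality.

Within-class marginals are truncated Gaussians.  Fixed seeds give
bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import AggregationCurve, CCEParams, cce_eval
from .classify import SampleRecord, CLASS_NAMES
from .extension import ExtensionCurve
from .protein import Chromatogram, ProteinComposition

__all__ = [
    "PanelConfig",
    "SyntheticPanel",
    "generate_panel",
    "generate_aggregation_curve",
    "generate_extension_curve",
    "generate_chromatogram",
    "export_panel",
    "load_panel_config",
    "save_panel_config",
]

# latent class centres of the quality scalar q
_CLASS_CENTRES = {"good": 0.80, "medium": 0.50, "poor": 0.20}
# within-class standard deviation of q (truncated at +/- 2 sd)
_CLASS_SD = 0.06


@dataclass(frozen=True)
class PanelConfig:
    """Conditions of a synthetic panel.

    ``volume_noise_sd`` (ml/g) is the bake-to-bake noise on the
    specific volumes; ``aggregation_noise_sd`` (BU) and
    ``extension_noise_sd`` (N) are the measurement noise of the two
    curve families; ``class_spread`` and ``feature_scatter`` scale the
    within-class spread of the latent quality and the feature-specific
    biological scatter (1 = the default study conditions, 0 = the
    degenerate noise-free limit).
    """

    n_samples: int = 46
    class_proportions: tuple[float, float, float] = (23 / 46, 15 / 46, 8 / 46)
    volume_noise_sd: float = 0.10
    aggregation_noise_sd: float = 0.5
    extension_noise_sd: float = 0.002
    rng_seed: int = 0
    aggregation_interval_s: float = 1.0
    extension_interval_mm: float = 0.1
    aggregation_duration_s: float = 600.0
    class_spread: float = 1.0
    feature_scatter: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("panel needs at least 3 samples")
        props = np.asarray(self.class_proportions, float)
        if props.shape != (3,) or np.any(props <= 0) or np.any(props >= 1):
            raise ValueError("class proportions must be three fractions in (0, 1)")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for name in ("volume_noise_sd", "aggregation_noise_sd",
                     "extension_noise_sd", "class_spread", "feature_scatter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.aggregation_interval_s <= 0 or self.extension_interval_mm <= 0:
            raise ValueError("sampling intervals must be positive")

    def scaled_noise(self, factor: float) -> "PanelConfig":
        """Copy of the config with every noise source scaled by ``factor``."""
        d = asdict(self)
        for name in ("volume_noise_sd", "aggregation_noise_sd",
                     "extension_noise_sd", "class_spread", "feature_scatter"):
            d[name] = d[name] * factor
        d["class_proportions"] = tuple(d["class_proportions"])
        return PanelConfig(**d)


@dataclass
class SyntheticPanel:
    records: list[SampleRecord]
    aggregation_curves: dict[str, AggregationCurve]
    extension_curves: dict[str, ExtensionCurve]
    chromatograms: dict[str, tuple[Chromatogram, Chromatogram]]
    truth: pd.DataFrame = field(repr=False)
    config: PanelConfig | None = None


def generate_aggregation_curve(cce: CCEParams, noise_sd: float,
                               interval: float = 1.0, duration: float = 600.0,
                               seed: int | None = None) -> AggregationCurve:
    """A torque trace from the CCE model plus clipped Gaussian noise."""
    if duration < 600.0:
        raise ValueError("aggregation runs last at least 600 s")
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    t = np.arange(0.0, duration + interval / 2, interval)
    y = cce_eval(cce, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return AggregationCurve(time=t, torque=np.clip(y, 0.0, None))


def generate_extension_curve(rmax: float, e_rmax: float, e_max: float,
                             noise_sd: float, interval: float = 0.1,
                             seed: int | None = None) -> ExtensionCurve:
    """A smooth unimodal force-distance trace with a rupture at ``e_max``.

    The force rises as a quarter sine wave to ``(e_rmax, rmax)``,
    declines quadratically to 75 % of the peak at ``e_max`` and then
    collapses exponentially (the rupture), so the first post-peak
    sample-to-sample drop exceeding the instrument break sensitivity
    occurs within one sampling interval of ``e_max``.
    """
    if rmax <= 0:
        raise ValueError("rmax must be positive")
    if not 0 < e_rmax < e_max:
        raise ValueError("need 0 < e_rmax < e_max")
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    d = np.arange(0.0, e_max + 5.0 + interval / 2, interval)
    f = np.empty_like(d)
    rise = d <= e_rmax
    f[rise] = rmax * np.sin(0.5 * np.pi * d[rise] / e_rmax)
    fall = (d > e_rmax) & (d <= e_max)
    u = (d[fall] - e_rmax) / (e_max - e_rmax)
    f[fall] = rmax * (1.0 - 0.25 * u ** 2)
    post = d > e_max
    f[post] = 0.75 * rmax * np.exp(-(d[post] - e_max) / 0.3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=d.shape)
    return ExtensionCurve(distance=d, force=np.clip(f, 0.0, None))


# Gaussian peak positions (centre min, sd min) per extract and fraction;
# all peaks sit well inside their retention window so window integration
# recovers the generating fractions to within a fraction of a point.
_GLIADIN_PEAKS = {"hmw": (7.05, 0.28), "mmw": (8.60, 0.16), "lmw": (10.60, 0.55)}
_GLUTENIN_PEAKS = {"hmw": (6.70, 0.18), "mmw": (8.00, 0.16), "lmw": (10.30, 0.60)}


def generate_chromatogram(composition: ProteinComposition, seed: int | None = None,
                          *, interval_min: float = 0.01,
                          noise_sd: float = 0.001,
                          ) -> tuple[Chromatogram, Chromatogram]:
    """GP-HPLC traces of the two extracts for a target composition.

    Each trace is a sum of Gaussian peaks whose areas equal the target
    fraction values (identity calibration scale) plus clipped baseline
    noise.  Window integration of the pair recovers the composition to
    within a few tenths of a percentage point.
    """
    fracs = [composition.hmw_gliadins, composition.mmw_gliadins,
             composition.lmw_gliadins, composition.hmw_glutenins,
             composition.mmw_glutenins, composition.lmw_glutenins]
    if any(not 0 <= f <= 100 for f in fracs):
        raise ValueError("fractions must lie in [0, 100]")
    if abs(sum(fracs) - 100.0) > 1e-6:
        raise ValueError("fractions must sum to 100 %")
    t = np.arange(5.5, 13.5 + interval_min / 2, interval_min)
    rng = np.random.default_rng(seed)
    traces = []
    for peaks, values, label in (
            (_GLIADIN_PEAKS, fracs[:3], "gliadin"),
            (_GLUTENIN_PEAKS, fracs[3:], "glutenin")):
        y = np.zeros_like(t)
        for (mu, sd), area in zip(peaks.values(), values):
            y += area * np.exp(-0.5 * ((t - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(Chromatogram(retention=t, signal=np.clip(y, 0.0, None),
                                   extract_label=label))
    return tuple(traces)


def _truncnorm(rng, centre, sd, nsd=2.0):
    """One truncated-Gaussian draw, re-sampled into centre +/- nsd * sd."""
    if sd == 0:
        return centre
    while True:
        v = rng.normal(centre, sd)
        if abs(v - centre) <= nsd * sd:
            return v


def _class_counts(config: PanelConfig) -> dict[str, int]:
    props = np.asarray(config.class_proportions, float)
    n = config.n_samples
    counts = np.floor(props * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(props * n - counts))
    for j in order[:rem]:
        counts[j] += 1
    for name, c in zip(CLASS_NAMES, counts):
        if c == 0:
            raise ValueError(f"class proportions leave the {name!r} class empty")
    return dict(zip(CLASS_NAMES, counts))


def _sample_truth(q: float, rng, s: float) -> dict[str, float]:
    """All generating parameters of one sample as functions of quality q."""
    tn = lambda c, sd: _truncnorm(rng, c, sd * s)
    # aggregation: good = early (low xc1), tall (high BEM), sharp (low w)
    y0 = max(tn(1.8, 0.3), 0.5)
    xc1 = tn(440.0 - 210.0 * q, 12.0)
    bem = tn(24.5 + 6.5 * q, 0.7)
    xc2 = max(tn(60.0 + 60.0 * q, 8.0), 5.0)
    k2 = max(tn(0.04, 0.005), 0.01)
    xc3 = min(max(tn(560.0 - 120.0 * q, 10.0), xc1 + 40.0), 595.0)
    k3 = max(tn(0.015, 0.002), 0.005)
    b = max(tn(0.35 - 0.10 * q, 0.04), 0.05)
    w = max(tn(2100.0 - 1400.0 * q, 110.0), 200.0)
    # amplitude chosen so the curve maximum sits at the target BEM
    switch = 1.0 - 0.5 * (1.0 - np.tanh(k2 * (xc1 - xc2)))
    amp = (bem - y0) / (1.0 + b * switch)
    # extension: good = longer, larger curves; R_max quality-independent
    r_max = min(max(tn(0.95, 0.08), 0.70), 1.20)
    e_rmax = min(max(tn(37.0 + 27.0 * q, 2.0), 34.5), 66.5)
    e_max = min(max(tn(e_rmax + 7.0 + 5.0 * q, 1.0), e_rmax + 2.0), 78.1)
    # protein composition: gliadin share rises with quality
    ratio = min(max(tn(1.30 + 1.40 * q, 0.05), 1.2), 2.8)
    gliadins = 100.0 * ratio / (1.0 + ratio)
    hmw_glia = min(max(tn(11.5, 1.2), 6.5), 17.0)
    mmw_glia = min(max(tn(7.5 + 1.8 * q, 0.4), 5.3), 10.0)
    hmw_glut = max(tn(1.5, 0.25), 0.8)
    mmw_glut = max(tn(9.2 - 2.8 * q, 0.4), 5.8)
    return {
        "q": q, "y0": y0, "xc1": xc1, "a": amp, "w": w, "k2": k2,
        "xc2": xc2, "b": b, "k3": k3, "xc3": xc3, "bem_target": bem,
        "r_max": r_max, "e_rmax": e_rmax, "e_max": e_max,
        "glia_glut_ratio": ratio,
        "hmw_gliadins": hmw_glia, "mmw_gliadins": mmw_glia,
        "lmw_gliadins": gliadins - hmw_glia - mmw_glia,
        "hmw_glutenins": hmw_glut, "mmw_glutenins": mmw_glut,
        "lmw_glutenins": (100.0 - gliadins) - hmw_glut - mmw_glut,
    }


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a complete panel under the given conditions."""
    rng = np.random.default_rng(config.rng_seed)
    counts = _class_counts(config)
    records: list[SampleRecord] = []
    agg: dict[str, AggregationCurve] = {}
    ext: dict[str, ExtensionCurve] = {}
    chroms: dict[str, tuple[Chromatogram, Chromatogram]] = {}
    truth_rows = []
    i = 0
    for cls in CLASS_NAMES:
        for _ in range(counts[cls]):
            i += 1
            sid = f"S{i}"
            q = _truncnorm(rng, _CLASS_CENTRES[cls],
                           _CLASS_SD * config.class_spread)
            vol_a = 1.6 + 1.9 * q + rng.normal(0.0, config.volume_noise_sd)
            vol_a = float(np.clip(vol_a, 1.6, 3.5))
            vol_b = vol_a - 0.5 + rng.normal(0.0, config.volume_noise_sd)
            vol_b = float(np.clip(vol_b, 1.1, 3.0))
            truth = _sample_truth(q, rng, config.feature_scatter)
            cce = CCEParams(y0=truth["y0"], xc1=truth["xc1"], A=truth["a"],
                            w=truth["w"], k2=truth["k2"], xc2=truth["xc2"],
                            B=truth["b"], k3=truth["k3"], xc3=truth["xc3"])
            seeds = rng.integers(0, 2 ** 31, size=3)
            agg[sid] = generate_aggregation_curve(
                cce, config.aggregation_noise_sd,
                interval=config.aggregation_interval_s,
                duration=config.aggregation_duration_s, seed=int(seeds[0]))
            ext[sid] = generate_extension_curve(
                truth["r_max"], truth["e_rmax"], truth["e_max"],
                config.extension_noise_sd,
                interval=config.extension_interval_mm, seed=int(seeds[1]))
            comp = ProteinComposition(
                hmw_gliadins=truth["hmw_gliadins"],
                mmw_gliadins=truth["mmw_gliadins"],
                lmw_gliadins=truth["lmw_gliadins"],
                hmw_glutenins=truth["hmw_glutenins"],
                mmw_glutenins=truth["mmw_glutenins"],
                lmw_glutenins=truth["lmw_glutenins"])
            chroms[sid] = generate_chromatogram(comp, seed=int(seeds[2]))
            records.append(SampleRecord(sample_id=sid, specific_volume_a=vol_a,
                                        specific_volume_b=vol_b,
                                        quality_class=cls))
            truth_rows.append({"sample_id": sid, "true_class": cls,
                               "volume_A_ml_per_g": vol_a,
                               "volume_B_ml_per_g": vol_b, **truth})
    truth_df = pd.DataFrame(truth_rows).set_index("sample_id")
    return SyntheticPanel(records=records, aggregation_curves=agg,
                          extension_curves=ext, chromatograms=chroms,
                          truth=truth_df, config=config)


def export_panel(panel: SyntheticPanel, outdir) -> None:
    """Write a panel as the CSV layout the file-based pipeline reads."""
    out = Path(outdir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    (out / "chromatograms").mkdir(exist_ok=True)
    samples = pd.DataFrame([
        {"sample_id": r.sample_id,
         "volume_A_ml_per_g": r.specific_volume_a,
         "volume_B_ml_per_g": r.specific_volume_b,
         "true_class": r.quality_class} for r in panel.records])
    samples.to_csv(out / "samples.csv", index=False)
    panel.truth.to_csv(out / "truth.csv")
    manifests = {"aggregation": [], "extension": [], "chromatograms": []}
    for sid, curve in panel.aggregation_curves.items():
        path = f"curves/{sid}_aggregation.csv"
        pd.DataFrame({"time_s": curve.time, "torque_BU": curve.torque}
                     ).to_csv(out / path, index=False)
        manifests["aggregation"].append({"sample_id": sid, "path": path})
    for sid, curve in panel.extension_curves.items():
        path = f"curves/{sid}_extension.csv"
        pd.DataFrame({"distance_mm": curve.distance, "force_N": curve.force}
                     ).to_csv(out / path, index=False)
        manifests["extension"].append({"sample_id": sid, "path": path})
    for sid, (glia, glut) in panel.chromatograms.items():
        row = {"sample_id": sid}
        for chrom in (glia, glut):
            path = f"chromatograms/{sid}_{chrom.extract_label}.csv"
            pd.DataFrame({"retention_min": chrom.retention,
                          "signal": chrom.signal}).to_csv(out / path, index=False)
            row[f"{chrom.extract_label}_path"] = path
        manifests["chromatograms"].append(row)
    for name, rows in manifests.items():
        pd.DataFrame(rows).to_csv(out / f"{name}_manifest.csv", index=False)
    if panel.config is not None:
        save_panel_config(panel.config, out / "panel_config.yaml")


def save_panel_config(config: PanelConfig, path) -> None:
    d = asdict(config)
    d["class_proportions"] = list(d["class_proportions"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_panel_config(path) -> PanelConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["class_proportions"] = tuple(d["class_proportions"])
    return PanelConfig(**d)
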