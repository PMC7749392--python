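"""Quantile-binned, correlation-weighted quality scoring.

For every scored parameter the 25 % and 75 % quantiles of the
medium-quality cluster define a "medium band".  A sample's value earns
20 points when it falls on the good side of the band, 10 points inside
it (boundaries included), and 0 points on the poor side; which side is
"good" follows the sign of the parameter's correlation with bread
volume.  Points are multiplied by the parameter's correlation weight
and summed; totals above 80 classify a sample as good, above 50 as
medium, and 50 or below as poor.

The absolute 80/50 thresholds presuppose weights on the scale of the
published 46-sample panel (maximum attainable total about 113.5).  When
weights are re-estimated on another panel the thresholds can instead be
applied as the equivalent fractions of the maximum attainable total
(``threshold_mode='relative'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParameterRange",
    "ScoringConfig",
    "ScoreReport",
    "medium_quantile_ranges",
    "allocate_points",
    "score_sample",
    "classify_score",
    "evaluate_accuracy",
    "score_panel",
    "GOOD_THRESHOLD",
    "MEDIUM_THRESHOLD",
    "REFERENCE_MAX_TOTAL",
]

GOOD_THRESHOLD = 80.0
MEDIUM_THRESHOLD = 50.0
#: maximum attainable total on the published panel, 20 * sum of weights
REFERENCE_MAX_TOTAL = 113.51


@dataclass(frozen=True)
class ParameterRange:
    """Medium-band quantiles of one parameter and its quality direction."""

    parameter: str
    q25: float
    q75: float
    direction: int  # +1: larger is better; -1: smaller is better

    def __post_init__(self) -> None:
        if self.q25 > self.q75:
            raise ValueError(f"{self.parameter}: q25 must not exceed q75")
        if self.direction not in (-1, 1):
            raise ValueError(f"{self.parameter}: direction must be +1 or -1")


@dataclass
class ScoringConfig:
    ranges: dict[str, ParameterRange]
    weights: dict[str, float]
    thresholds: tuple[float, float] = (GOOD_THRESHOLD, MEDIUM_THRESHOLD)
    threshold_mode: str = "absolute"

    def __post_init__(self) -> None:
        missing = set(self.ranges) - set(self.weights)
        if missing:
            raise ValueError(f"no weight for scored parameters: {sorted(missing)}")
        if not self.thresholds[0] > self.thresholds[1]:
            raise ValueError("good threshold must exceed medium threshold")
        if self.threshold_mode not in ("absolute", "relative"):
            raise ValueError("threshold_mode must be 'absolute' or 'relative'")

    @property
    def max_total(self) -> float:
        return 20.0 * sum(self.weights[p] for p in self.ranges)

    def effective_thresholds(self) -> tuple[float, float]:
        """Thresholds on the total-score scale of this configuration.

        In relative mode the 80/50 reference cuts are rescaled by the
        ratio of this panel's maximum attainable total to the published
        panel's (about 113.5)."""
        if self.threshold_mode == "absolute":
            return self.thresholds
        f = self.max_total / REFERENCE_MAX_TOTAL
        return (self.thresholds[0] * f, self.thresholds[1] * f)


def medium_quantile_ranges(features: pd.DataFrame, labels, parameters,
                           directions: dict[str, int]) -> dict[str, ParameterRange]:
    """25 %/75 % quantiles of the medium-labelled samples per parameter.

    Quantiles interpolate linearly between order statistics at position
    ``h = (n - 1) p + 1``.  Requires at least three medium samples.
    """
    labels = np.asarray(labels)
    med = features.loc[labels == "medium"]
    if len(med) < 3:
        raise ValueError("need at least 3 medium-class samples for quantile ranges")
    ranges = {}
    for p in parameters:
        vals = med[p].dropna().to_numpy()
        q25, q75 = np.quantile(vals, [0.25, 0.75], method="linear")
        ranges[p] = ParameterRange(parameter=p, q25=float(q25), q75=float(q75),
                                   direction=directions[p])
    return ranges


def allocate_points(value: float, prange: ParameterRange) -> int:
    """20, 10 or 0 points for one parameter value.

    Values inside the medium band [q25, q75] (boundaries included)
    score 10; values beyond the band on the good side score 20 and on
    the poor side 0.
    """
    if not np.isfinite(value):
        raise ValueError("cannot score a non-finite value")
    if prange.q25 <= value <= prange.q75:
        return 10
    above = value > prange.q75
    good_side = above if prange.direction > 0 else not above
    return 20 if good_side else 0


def score_sample(features: dict | pd.Series,
                 config: ScoringConfig) -> tuple[float, pd.DataFrame]:
    """Weighted total score of one sample with a per-parameter breakdown."""
    rows = []
    for p, prange in config.ranges.items():
        if p not in features or not np.isfinite(features[p]):
            raise KeyError(f"sample is missing scored parameter {p!r}")
        pts = allocate_points(float(features[p]), prange)
        w = config.weights[p]
        rows.append({"parameter": p, "value": float(features[p]),
                     "points": pts, "weight": w, "contribution": pts * w})
    breakdown = pd.DataFrame(rows)
    return float(breakdown["contribution"].sum()), breakdown


def classify_score(total: float,
                   thresholds: tuple[float, float] = (GOOD_THRESHOLD,
                                                      MEDIUM_THRESHOLD)) -> str:
    """good / medium / poor from a total score.

    Totals strictly above the good threshold are good, strictly above
    the medium threshold medium, otherwise poor (boundary totals
    resolve downward).
    """
    if total < 0:
        raise ValueError("total score cannot be negative")
    good_t, med_t = thresholds
    if total > good_t:
        return "good"
    if total > med_t:
        return "medium"
    return "poor"


@dataclass
class ScoreReport:
    scores: pd.DataFrame            # per sample: total, predicted, reference
    breakdowns: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    accuracy: float = float("nan")  # fraction correct vs reference
    confusion: pd.DataFrame | None = None

    @property
    def accuracy_percent(self) -> float:
        return round(100.0 * self.accuracy, 1)


def evaluate_accuracy(predicted, reference) -> tuple[float, pd.DataFrame]:
    """Exact-match fraction and confusion matrix of two label mappings.

    Both arguments are mappings (or Series) from sample id to class;
    the ids must coincide.
    """
    pred = pd.Series(predicted)
    ref = pd.Series(reference)
    if len(pred.index.intersection(ref.index)) == 0:
        raise ValueError("no shared sample ids between predictions and reference")
    if not pred.index.sort_values().equals(ref.index.sort_values()):
        raise ValueError("prediction and reference sample ids do not match")
    ref = ref.loc[pred.index]
    frac = float((pred == ref).mean())
    confusion = pd.crosstab(ref, pred, rownames=["reference"],
                            colnames=["predicted"], dropna=False)
    return frac, confusion


def score_panel(features: pd.DataFrame, config: ScoringConfig,
                reference: pd.Series | dict | None = None) -> ScoreReport:
    """Score every sample of a feature table and, when reference classes
    are given, evaluate the prediction accuracy."""
    thresholds = config.effective_thresholds()
    rows = []
    breakdowns = {}
    for sid, feat in features.iterrows():
        total, bd = score_sample(feat, config)
        breakdowns[sid] = bd
        rows.append({"sample_id": sid, "total": total,
                     "predicted": classify_score(total, thresholds)})
    scores = pd.DataFrame(rows).set_index("sample_id")
    report = ScoreReport(scores=scores, breakdowns=breakdowns)
    if reference is not None:
        ref = pd.Series(reference)
        report.accuracy, report.confusion = evaluate_accuracy(
            scores["predicted"], ref)
        scores["reference"] = ref.loc[scores.index]
    return report
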