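"""Quality classification of gluten samples from microbaking volumes.

Each sample is baked in two recipes (A and B); the specific volume
(bread volume over dough weight, ml/g) of each bake is the quality
criterion.  Samples are grouped into three classes -- good, medium,
poor -- by agglomerative clustering of the (A, B) volume pairs with
Euclidean distance and Ward linkage, followed by one refinement pass
that re-assigns every sample to the nearest cluster mean.  Clusters are
named by descending mean combined volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .aggregation import DataQualityWarning

__all__ = [
    "SampleRecord",
    "ClusterResult",
    "CLASS_NAMES",
    "specific_volume",
    "cluster_quality",
    "load_reference_volumes",
]

CLASS_NAMES = ("good", "medium", "poor")


@dataclass
class SampleRecord:
    sample_id: str
    specific_volume_a: float
    specific_volume_b: float
    quality_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.specific_volume_a <= 0 or self.specific_volume_b <= 0:
            raise ValueError(f"{self.sample_id}: specific volumes must be positive")


def specific_volume(bread_volume_ml: float, dough_weight_g: float) -> float:
    """Specific volume (ml/g) = bread volume / dough weight."""
    if dough_weight_g <= 0:
        raise ValueError("dough weight must be positive")
    return bread_volume_ml / dough_weight_g


@dataclass
class ClusterResult:
    labels: list[str]
    means: dict[str, tuple[float, float]]
    counts: dict[str, int]
    linkage: np.ndarray = field(repr=False)
    refinement_moved: int = 0


def _name_clusters(X: np.ndarray, raw: np.ndarray,
                   names: tuple[str, ...]) -> tuple[list[str], dict, dict]:
    ids = sorted(set(raw))
    means = np.array([X[raw == c].mean(axis=0) for c in ids])
    order = np.argsort(-means.mean(axis=1))  # descending combined volume
    mapping = {ids[j]: names[rank] for rank, j in enumerate(order)}
    labels = [mapping[c] for c in raw]
    mean_d = {names[rank]: tuple(means[j]) for rank, j in enumerate(order)}
    count_d = {n: int(sum(lab == n for lab in labels)) for n in names}
    return labels, mean_d, count_d


def cluster_quality(records: list[SampleRecord], k: int = 3, *,
                    method: str = "ward", metric: str = "euclidean",
                    refine_passes: int = 1) -> ClusterResult:
    """Cluster samples on their (A, B) specific volumes into ``k`` classes.

    Agglomerative clustering (``method`` linkage on ``metric``
    distances) is cut at ``k`` clusters, then each refinement pass
    re-assigns every sample to the nearest (Euclidean) cluster mean.
    If a pass would empty a cluster, the pre-refinement labels are kept
    with a warning.  Deterministic for a given input.
    """
    if len(records) < k:
        raise ValueError(f"need at least {k} samples for {k} clusters")
    X = np.array([[r.specific_volume_a, r.specific_volume_b] for r in records])
    Z = hierarchy.linkage(pdist(X, metric), method=method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    moved = 0
    for _ in range(refine_passes):
        ids = sorted(set(raw))
        means = np.array([X[raw == c].mean(axis=0) for c in ids])
        d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        new = np.asarray(ids)[np.argmin(d2, axis=1)]
        if len(set(new)) < len(ids):
            warnings.warn("refinement would empty a cluster; keeping the "
                          "pre-refinement assignment", DataQualityWarning,
                          stacklevel=2)
            break
        moved += int(np.sum(new != raw))
        if np.array_equal(new, raw):
            break
        raw = new
    names = CLASS_NAMES if k == 3 else tuple(f"class_{i + 1}" for i in range(k))
    labels, means_d, counts = _name_clusters(X, raw, names)
    for rec, lab in zip(records, labels):
        rec.quality_class = lab
    return ClusterResult(labels=labels, means=means_d, counts=counts,
                         linkage=Z, refinement_moved=moved)


def load_reference_volumes() -> pd.DataFrame:
    """The packaged 46-sample reference panel of microbaking specific
    volumes (recipes A and B) with the published quality classes."""
    with resources.files("vitalgluten.data").joinpath(
            "table1_volumes.csv").open() as fh:
        return pd.read_csv(fh)


def records_from_frame(df: pd.DataFrame) -> list[SampleRecord]:
    """Build sample records from a volumes table (samples CSV layout)."""
    return [
        SampleRecord(sample_id=str(row["sample_id"]),
                     specific_volume_a=float(row["volume_A_ml_per_g"]),
                     specific_volume_b=float(row["volume_B_ml_per_g"]),
                     quality_class=str(row.get("quality_class", "unassigned")))
        for _, row in df.iterrows()
    ]
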