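"""Per-OTU environmental tolerance breadth and generalist/specialist labels.

An OTU's tolerance breadth (TB) measures how disparate the environments it
occupies are: in z-scored environment space, TB is the abundance-weighted
mean distance of the occupied samples to their abundance-weighted centroid.
Large TB means the OTU thrives across distinct conditions (a putative
habitat generalist); small TB means it is confined to a narrow niche (a
putative specialist). TB is the abundance-weighted analogue of multivariate
dispersion around a group centroid, and has no upper bound.

The direct computation uses Euclidean distance on standardized variables,
which is exactly equivalent to the principal-coordinate (PCoA) route for
Euclidean input; a PCoA path with the standard negative-eigenvalue
correction is provided for non-Euclidean dissimilarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, EnvTable

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedEnv",
    "ToleranceBreadths",
    "EcotypeClassification",
    "standardize_env",
    "tolerance_breadth",
    "tolerance_breadth_all",
    "classify_ecotypes",
    "group_relative_abundance",
]


@dataclass(frozen=True)
class StandardizedEnv:
    """Sample x variable coordinates in standardized environment space.

    ``standardize_env`` constructs these with ``validate=True``, enforcing
    per-variable mean 0 and sample sd 1. Direct construction (for coordinates
    prepared elsewhere, or small worked examples) skips the z-score check.
    """

    sample_ids: tuple[str, ...]
    var_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    validate: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.validate and values.shape[0] > 1:
            if np.any(np.abs(values.mean(axis=0)) > 1e-9):
                raise ValueError("standardized variables must have mean 0")
            if np.any(np.abs(values.std(axis=0, ddof=1) - 1) > 1e-9):
                raise ValueError("standardized variables must have unit sample sd")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.var_names)
        )


@dataclass(frozen=True)
class ToleranceBreadths:
    """Per-OTU tolerance breadth with occupancy and (on demand) centroids."""

    otu_ids: tuple[str, ...]
    tb: np.ndarray = field(repr=False)
    n_occupied: np.ndarray = field(repr=False)
    centroids: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tb": self.tb, "n_occupied": self.n_occupied},
            index=pd.Index(list(self.otu_ids), name="otu_id"),
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.tb, index=list(self.otu_ids), name="tb")


@dataclass(frozen=True)
class EcotypeClassification:
    """Generalist/specialist labels at a TB quantile threshold pair."""

    quantile: float
    otu_ids: tuple[str, ...]
    labels: tuple[str, ...]
    tb_threshold_upper: float
    tb_threshold_lower: float

    def to_series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.otu_ids), name="ecotype")


def standardize_env(env: EnvTable) -> StandardizedEnv:
    """z-score each variable over all samples (sample-sd, n-1 convention).

    Standardization is done over the full sample set supplied, so that every
    OTU's tolerance breadth is measured on one common environmental scale.
    """
    values = env.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [env.var_names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance variables cannot be standardized: {bad}")
    return StandardizedEnv(
        env.sample_ids, env.var_names, (values - mean) / sd, validate=True
    )


def _check_sample_match(counts: CountTable, env: StandardizedEnv) -> None:
    a, b = set(counts.sample_ids), set(env.sample_ids)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"sample ids differ between counts and environment: {diff}")
    if counts.sample_ids != env.sample_ids:
        raise ValueError("sample ids match as sets but differ in order; align first")


def tolerance_breadth(counts: CountTable, env: StandardizedEnv, otu) -> float:
    """Tolerance breadth of one OTU.

    With a_j the OTU's reads in sample j and x_j sample j's standardized
    environment vector, the weighted centroid is C = sum_j a_j x_j / sum_j a_j
    and TB = sum_j a_j ||x_j - C|| / sum_j a_j, both sums over occupied
    samples (a_j > 0). TB is invariant to rescaling the a_j, so raw counts
    and relative abundances give the same value.
    """
    _check_sample_match(counts, env)
    m = counts.otu_index(otu)
    a = counts.counts[m].astype(float)
    total = a.sum()
    if total == 0:
        raise ValueError(f"OTU {otu!r} is absent from every sample")
    w = a / total
    centroid = w @ env.values
    z = np.linalg.norm(env.values - centroid, axis=1)
    return float(w @ z)


def _tb_direct(weights: np.ndarray, coords: np.ndarray) -> np.ndarray:
    # weights: (n_otus, n_samples) rows summing to 1; coords: (n_samples, k)
    centroids = weights @ coords
    sq = (
        (coords**2).sum(axis=1)[None, :]
        - 2.0 * centroids @ coords.T
        + (centroids**2).sum(axis=1)[:, None]
    )
    dist = np.sqrt(np.clip(sq, 0.0, None))
    return (weights * dist).sum(axis=1)


def _tb_pcoa(weights: np.ndarray, dissim: np.ndarray) -> np.ndarray:
    """Tolerance breadth via principal coordinates of a dissimilarity matrix.

    Gower double-centering, eigendecomposition, then distances computed
    separately on the positive- and negative-eigenvalue axes with the
    correction z = sqrt(max(z_pos^2 - z_neg^2, 0)).
    """
    n = dissim.shape[0]
    a = -0.5 * dissim**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    pos = eigval > tol
    neg = eigval < -tol
    coords_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])

    def sq_to_centroid(coords):
        if coords.shape[1] == 0:
            return np.zeros((weights.shape[0], n))
        centroids = weights @ coords
        return (
            (coords**2).sum(axis=1)[None, :]
            - 2.0 * centroids @ coords.T
            + (centroids**2).sum(axis=1)[:, None]
        )

    sq = sq_to_centroid(coords_pos) - sq_to_centroid(coords_neg)
    dist = np.sqrt(np.clip(sq, 0.0, None))
    return (weights * dist).sum(axis=1)


def tolerance_breadth_all(
    counts: CountTable,
    env: StandardizedEnv,
    method: str = "direct",
    metric: str = "euclidean",
    keep_centroids: bool = False,
) -> ToleranceBreadths:
    """Tolerance breadth for every OTU in the table.

    ``method="direct"`` computes distances in the standardized variable space
    (Euclidean); ``method="pcoa"`` first builds the ``metric`` dissimilarity
    among samples and works in principal-coordinate space. The two agree for
    Euclidean input. OTUs occupying a single sample get TB = 0; filter with
    the ``n_occupied`` column.
    """
    _check_sample_match(counts, env)
    a = counts.counts.astype(float)
    totals = a.sum(axis=1)
    if np.any(totals == 0):
        bad = [counts.otu_ids[m] for m in np.nonzero(totals == 0)[0]]
        raise ValueError(f"OTUs absent from every sample: {bad}")
    weights = a / totals[:, None]
    if method == "direct":
        if metric != "euclidean":
            raise ValueError("direct method supports only the euclidean metric")
        tb = _tb_direct(weights, env.values)
    elif method == "pcoa":
        dissim = squareform(pdist(env.values, metric=metric))
        tb = _tb_pcoa(weights, dissim)
    else:
        raise ValueError(f"unknown method: {method!r}")
    n_occupied = (counts.counts > 0).sum(axis=1)
    tb = np.where(n_occupied == 1, 0.0, tb)
    centroids = weights @ env.values if keep_centroids else None
    return ToleranceBreadths(counts.otu_ids, tb, n_occupied, centroids)


def classify_ecotypes(tb: ToleranceBreadths, quantile: float) -> EcotypeClassification:
    """Label OTUs generalist/specialist by TB quantile thresholds.

    Generalists: TB >= the ``quantile`` empirical quantile of all TB values;
    specialists: TB <= the (1 - quantile) quantile. Quantiles use linear
    interpolation (type 7). OTUs qualifying for both labels (degenerate TB
    distributions) are resolved to "neither" and counted in a log message.
    """
    if not 0.5 < quantile < 1:
        raise ValueError(f"quantile must lie in (0.5, 1), got {quantile}")
    values = np.asarray(tb.tb, dtype=float)
    if values.size == 0:
        raise ValueError("empty tolerance-breadth table")
    upper = float(np.quantile(values, quantile))
    lower = float(np.quantile(values, 1 - quantile))
    gen = values >= upper
    spec = values <= lower
    both = gen & spec
    if both.any():
        logger.warning(
            "%d OTU(s) qualified as both generalist and specialist "
            "(degenerate TB distribution); labelled 'neither'", both.sum(),
        )
    labels = np.where(
        both, "neither", np.where(gen, "generalist", np.where(spec, "specialist", "neither"))
    )
    return EcotypeClassification(
        quantile, tb.otu_ids, tuple(labels.tolist()), upper, lower
    )


def group_relative_abundance(
    counts: CountTable, cls: EcotypeClassification
) -> pd.DataFrame:
    """Per-sample summed relative abundance of generalists and specialists."""
    missing = set(counts.otu_ids) - set(cls.otu_ids)
    if missing:
        raise ValueError(f"classification does not cover OTUs: {sorted(missing)}")
    label_of = dict(zip(cls.otu_ids, cls.labels))
    labels = np.array([label_of[o] for o in counts.otu_ids])
    colsums = counts.counts.sum(axis=0).astype(float)
    if np.any(colsums == 0):
        raise ValueError("zero-sum sample columns")
    rel = counts.counts / colsums
    return pd.DataFrame(
        {
            "generalist_share": rel[labels == "generalist"].sum(axis=0),
            "specialist_share": rel[labels == "specialist"].sum(axis=0),
        },
        index=pd.Index(list(counts.sample_ids), name="sample_id"),
    )
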