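"""Community-level indexes: CMTB, CMRA, and the resistance potential.

The community mean tolerance breadth (CMTB) of a sample is the
relative-abundance-weighted mean TB of its (selected) OTUs; the community
mean response asynchrony (CMRA) is the pairwise-weighted mean RA. OTUs enter
via one of two selection schemes designed to make the indexes comparable
across samples: the most abundant OTUs up to a cumulative relative-abundance
level (0.75/0.80/0.85/0.90), or a fixed number of OTUs drawn at random from
those present (300/500/700/900, averaged over 100 replicate draws).

Per selection variant, each index is min-max standardized onto [0, 1] across
the sample set, and the resistance potential combines the pair as the
Euclidean norm sqrt(CMTB_stand^2 + CMRA_stand^2) in [0, sqrt(2)]: communities
rich in broad-tolerance taxa AND in compensatory taxon pairs score highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd

from .asynchrony import AsynchronyMatrix, cmra_batch, spearman_matrix
from .tables import CountTable, EnvTable, to_relative_abundance
from .tolerance import (
    StandardizedEnv,
    ToleranceBreadths,
    standardize_env,
    tolerance_breadth_all,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionScheme",
    "select_cumulative",
    "select_random",
    "cmtb",
    "resistance_potential",
    "compute_indices",
    "method_independence",
]

#: cumulative-abundance and fixed-richness selection levels used by default
CUMULATIVE_LEVELS = (0.75, 0.80, 0.85, 0.90)
RANDOM_LEVELS = (300, 500, 700, 900)


@dataclass(frozen=True)
class SelectionScheme:
    """How OTUs are picked per sample before the community indexes are averaged."""

    mode: str  # "cumulative_abundance" | "random_fixed_richness"
    levels: tuple = CUMULATIVE_LEVELS
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode == "cumulative_abundance":
            if not all(0 < lv <= 1 for lv in self.levels):
                raise ValueError("cumulative levels must lie in (0, 1]")
            if self.replicates != 1:
                raise ValueError("cumulative mode uses a single deterministic replicate")
        elif self.mode == "random_fixed_richness":
            if not all(int(lv) == lv and lv > 0 for lv in self.levels):
                raise ValueError("random levels must be positive integers")
            if self.replicates < 1:
                raise ValueError("replicates must be >= 1")
        else:
            raise ValueError(f"unknown selection mode: {self.mode!r}")
        object.__setattr__(self, "levels", tuple(self.levels))

    @classmethod
    def cumulative(cls, levels=CUMULATIVE_LEVELS) -> "SelectionScheme":
        return cls("cumulative_abundance", tuple(levels), replicates=1)

    @classmethod
    def random(cls, levels=RANDOM_LEVELS, replicates: int = 100, seed: int = 0) -> "SelectionScheme":
        return cls("random_fixed_richness", tuple(levels), replicates, seed)


def select_cumulative(abund: np.ndarray, level: float) -> np.ndarray:
    """Indices of the smallest descending-abundance prefix reaching ``level``.

    Ties in abundance are broken by position (OTU id order) for determinism.
    A small tolerance guards the cumulative sum against float round-off.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    a = np.asarray(abund, dtype=float)
    if a.sum() <= 0:
        raise ValueError("empty sample: no positive abundances")
    order = np.argsort(-a, kind="stable")
    order = order[a[order] > 0]
    csum = np.cumsum(a[order])
    k = int(np.searchsorted(csum, level - 1e-12) + 1)
    k = min(k, len(order))
    return np.sort(order[:k])


def select_random(
    abund: np.ndarray, n: int, replicates: int, rng: np.random.Generator
) -> list[np.ndarray] | None:
    """``replicates`` uniform draws of ``n`` OTUs from those present (count > 0).

    Returns None when the sample's richness is below ``n`` (the sample is
    excluded from that level; this is a warning, not an error).
    """
    present = np.nonzero(np.asarray(abund) > 0)[0]
    if len(present) < n:
        return None
    return [np.sort(rng.choice(present, size=n, replace=False)) for _ in range(replicates)]


def cmtb(abund: np.ndarray | pd.Series, tb: ToleranceBreadths, selected=None) -> float:
    """Abundance-weighted mean tolerance breadth of the selected OTUs.

    Weights are the OTUs' original within-sample relative abundances; because
    the mean is a ratio, renormalizing over the selection is a no-op.
    """
    if isinstance(abund, pd.Series):
        a = abund.reindex(list(tb.otu_ids)).fillna(0.0).to_numpy(dtype=float)
    else:
        a = np.asarray(abund, dtype=float)
    if selected is not None:
        mask = np.zeros(len(tb.otu_ids), dtype=bool)
        pos = {o: k for k, o in enumerate(tb.otu_ids)}
        for o in selected:
            mask[pos[o]] = True
        a = np.where(mask, a, 0.0)
    total = a.sum()
    if total <= 0:
        raise ValueError("empty selection: no positive abundances")
    return float(a @ tb.tb / total)


def resistance_potential(cmtb_stand: float, cmra_stand: float) -> float:
    """sqrt(CMTB_stand^2 + CMRA_stand^2); both inputs must lie in [0, 1]."""
    c, r = float(cmtb_stand), float(cmra_stand)
    if not (0 <= c <= 1 and 0 <= r <= 1):
        raise ValueError("standardized indexes must lie in [0, 1]")
    return sqrt(c * c + r * r)


def _minmax(values: np.ndarray, name: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ValueError(f"degenerate min-max standardization: {name} has zero range")
    return (values - lo) / (hi - lo)


def _selection_weights(
    rel: np.ndarray, scheme: SelectionScheme, level, sample_idx: int
) -> np.ndarray | None:
    """Weight rows (replicates x n_otus) for one sample at one level."""
    a = rel[:, sample_idx]
    if scheme.mode == "cumulative_abundance":
        sel = select_cumulative(a, level)
        w = np.zeros((1, rel.shape[0]))
        w[0, sel] = a[sel]
        return w
    n = int(level)
    # per-sample, per-level substream: results independent of iteration order
    rng = np.random.default_rng([scheme.seed % (2**31), sample_idx, n])
    sels = select_random(a, n, scheme.replicates, rng)
    if sels is None:
        return None
    w = np.zeros((scheme.replicates, rel.shape[0]))
    for r, sel in enumerate(sels):
        w[r, sel] = a[sel]
    return w


def compute_indices(
    counts: CountTable,
    env: EnvTable | StandardizedEnv,
    scheme: SelectionScheme,
    tb: ToleranceBreadths | None = None,
    ra: AsynchronyMatrix | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-sample CMTB, CMRA, standardized forms, and resistance potential.

    For every sample and selection level, CMTB and CMRA are computed per
    replicate and then averaged (one replicate in cumulative mode). Each
    index is then min-max standardized across samples within the
    scheme-by-level variant, and the resistance potential combines the pair.
    Samples excluded at a level (richness below a random-selection size) are
    absent from that level's rows. TB and RA matrices are computed internally
    when not supplied.
    """
    rel_table = to_relative_abundance(counts)
    rel = rel_table.values
    if tb is None or ra is None:
        if isinstance(env, EnvTable):
            env = standardize_env(env)
        if tb is None:
            tb = tolerance_breadth_all(counts, env)
        if ra is None:
            ra = spearman_matrix(rel_table)
    richness = (counts.counts > 0).sum(axis=0)

    rows = []
    for level in scheme.levels:
        per_sample = {}
        skipped = 0
        for s, sid in enumerate(counts.sample_ids):
            w = _selection_weights(rel, scheme, level, s)
            if w is None:
                skipped += 1
                continue
            cmtb_reps = (w @ tb.tb) / w.sum(axis=1)
            cmra_reps = cmra_batch(w, ra.ra)
            per_sample[sid] = (
                s,
                float(np.mean(cmtb_reps)),
                float(np.nanmean(cmra_reps)) if np.isfinite(cmra_reps).any() else np.nan,
            )
        if skipped:
            logger.warning(
                "level %s: excluded %d sample(s) with richness below the "
                "selection size", level, skipped,
            )
        if not per_sample:
            logger.warning("level %s: no sample qualifies; level omitted", level)
            continue
        sids = list(per_sample)
        cmtb_vals = np.array([per_sample[sid][1] for sid in sids])
        cmra_vals = np.array([per_sample[sid][2] for sid in sids])
        if standardize:
            cmtb_st = _minmax(cmtb_vals, f"CMTB at level {level}")
            cmra_st = _minmax(cmra_vals, f"CMRA at level {level}")
            resist = np.sqrt(cmtb_st**2 + cmra_st**2)
        else:
            cmtb_st = cmra_st = resist = np.full(len(sids), np.nan)
        for k, sid in enumerate(sids):
            rows.append(
                {
                    "sample_id": sid,
                    "scheme": scheme.mode,
                    "level": level,
                    "richness": int(richness[per_sample[sid][0]]),
                    "cmtb": cmtb_vals[k],
                    "cmra": cmra_vals[k],
                    "cmtb_stand": cmtb_st[k],
                    "cmra_stand": cmra_st[k],
                    "resistance_potential": resist[k],
                }
            )
    return pd.DataFrame(rows)


def method_independence(indices: pd.DataFrame, index: str = "cmtb") -> pd.DataFrame:
    """Pairwise Pearson correlations of one index across scheme-by-level variants.

    ``indices`` concatenates compute_indices outputs for the variants to be
    compared. Each variant is a (scheme, level) pair; correlations use the
    samples shared by both variants of a pair (>= 3 required, otherwise the
    pair is reported missing). Returns the long-format correlation table;
    the minimum is ``result["r"].min()``.
    """
    if index not in ("cmtb", "cmra"):
        raise ValueError("index must be 'cmtb' or 'cmra'")
    variants = {
        (scheme, level): grp.set_index("sample_id")[index]
        for (scheme, level), grp in indices.groupby(["scheme", "level"])
    }
    rows = []
    for (ka, kb) in combinations(sorted(variants, key=str), 2):
        a, b = variants[ka].align(variants[kb], join="inner")
        if len(a) < 3:
            rows.append({"variant_a": ka, "variant_b": kb, "n": len(a), "r": np.nan})
            continue
        r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
        rows.append({"variant_a": ka, "variant_b": kb, "n": len(a), "r": r})
    return pd.DataFrame(rows)
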