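"""Pairwise response asynchrony and its community-level weighted mean.

Two OTUs respond asynchronously when their relative abundances move in
opposite directions across the environmental gradient. Response asynchrony
is the negated Spearman rank correlation of the two OTUs' relative-abundance
profiles across all samples: RA = -rho, so +1 is perfectly compensatory and
-1 perfectly synchronous. The community mean response asynchrony (CMRA) of a
sample averages RA over all distinct OTU pairs, each pair weighted by the
product of the two OTUs' within-sample relative abundances:

    CMRA = sum_{i<j} a_i a_j RA_ij / sum_{i<j} a_i a_j

Correlations are computed once over the full sample set (zeros included,
average ranks for ties); per-sample CMRA reuses that global matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables import RelativeAbundanceTable

logger = logging.getLogger(__name__)

__all__ = ["AsynchronyMatrix", "spearman_matrix", "cmra", "cmra_batch"]


@dataclass(frozen=True)
class AsynchronyMatrix:
    """Symmetric matrix of pairwise response asynchrony values in [-1, 1].

    Entries for OTUs with a constant profile (Spearman rho undefined) are
    NaN; the diagonal of defined OTUs is -1 (an OTU is perfectly synchronous
    with itself).
    """

    otu_ids: tuple[str, ...]
    ra: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ra, index=list(self.otu_ids), columns=list(self.otu_ids))

    def submatrix(self, otu_ids) -> "AsynchronyMatrix":
        pos = {o: k for k, o in enumerate(self.otu_ids)}
        idx = np.array([pos[o] for o in otu_ids])
        return AsynchronyMatrix(tuple(otu_ids), self.ra[np.ix_(idx, idx)])


def spearman_matrix(
    relabund: RelativeAbundanceTable,
    otus=None,
    occupied_only: bool = False,
) -> AsynchronyMatrix:
    """RA = -Spearman(rho) for every OTU pair, over all samples.

    ``occupied_only=True`` restricts each pair's correlation to samples where
    both OTUs occur (a sensitivity-analysis variant; the default correlates
    over all samples, zeros included). OTUs whose profile is constant across
    the correlated samples get NaN entries, reported in a log message; the
    caller decides exclusion.
    """
    if otus is None:
        otus = relabund.otu_ids
    pos = {o: k for k, o in enumerate(relabund.otu_ids)}
    try:
        idx = np.array([pos[o] for o in otus])
    except KeyError as exc:
        raise KeyError(f"unknown OTU id: {exc.args[0]!r}") from None
    x = relabund.values[idx]
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for rank correlations")

    if occupied_only:
        m = len(idx)
        ra = np.full((m, m), np.nan)
        for i in range(m):
            for j in range(i, m):
                mask = (x[i] > 0) & (x[j] > 0)
                if mask.sum() < 3:
                    continue
                xi, xj = x[i, mask], x[j, mask]
                if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                    continue
                ri, rj = rankdata(xi), rankdata(xj)
                ra[i, j] = ra[j, i] = -float(np.corrcoef(ri, rj)[0, 1])
        return AsynchronyMatrix(tuple(otus), ra)

    constant = np.all(x == x[:, :1], axis=1)
    if constant.any():
        logger.warning(
            "%d OTU(s) have constant relative-abundance profiles; "
            "their asynchrony entries are undefined (NaN)", constant.sum(),
        )
    ranks = rankdata(x, axis=1)  # average ranks on ties
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    ra = -rho
    # exact self-synchrony on the diagonal for defined OTUs
    d = np.where(constant, np.nan, -1.0)
    np.fill_diagonal(ra, d)
    ra[constant, :] = np.nan
    ra[:, constant] = np.nan
    return AsynchronyMatrix(tuple(otus), ra)


def cmra(abund: pd.Series | np.ndarray, ra: AsynchronyMatrix, selected=None) -> float:
    """Community mean response asynchrony for one sample.

    ``abund`` holds per-OTU relative abundances indexed like ``ra.otu_ids``
    (or a pandas Series keyed by OTU id). Only ``selected`` OTUs (default:
    all with positive abundance) enter the pairwise mean; pairs with
    undefined RA are excluded from numerator and denominator. Returns NaN
    when fewer than two usable OTUs remain.
    """
    if isinstance(abund, pd.Series):
        a = abund.reindex(list(ra.otu_ids)).fillna(0.0).to_numpy(dtype=float)
    else:
        a = np.asarray(abund, dtype=float)
        if a.shape[0] != len(ra.otu_ids):
            raise ValueError("abundance vector length does not match RA matrix")
    if selected is not None:
        sel = np.zeros(len(ra.otu_ids), dtype=bool)
        pos = {o: k for k, o in enumerate(ra.otu_ids)}
        for o in selected:
            sel[pos[o]] = True
        a = np.where(sel, a, 0.0)
    return float(cmra_batch(a[None, :], ra.ra)[0])


def cmra_batch(weight_rows: np.ndarray, ra: np.ndarray) -> np.ndarray:
    """Vectorized CMRA for many abundance-weight rows against one RA matrix.

    Each row of ``weight_rows`` is a per-OTU abundance vector (zeros for
    unselected/absent OTUs). Off-diagonal NaN entries are excluded pairwise;
    rows with no usable pair yield NaN. Exploits the symmetry
    sum_{i<j} w_i w_j M_ij = (s M s' - sum_i w_i^2 M_ii) / 2.
    """
    ra = np.asarray(ra, dtype=float)
    valid = np.isfinite(ra)
    ra0 = np.where(valid, ra, 0.0)
    v = valid.astype(float)
    w = np.asarray(weight_rows, dtype=float)
    w2 = w**2
    num = ((w @ ra0) * w).sum(axis=1) - (w2 * np.diag(ra0)).sum(axis=1)
    den = ((w @ v) * w).sum(axis=1) - (w2 * np.diag(v)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out
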