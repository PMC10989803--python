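"""Tabular containers and I/O for OTU count tables and environment tables.

The pipeline's community data is an OTU-by-sample matrix of nonnegative
integer read counts; environmental context is a sample-by-variable matrix of
real measurements. Both travel as delimited text (TSV/CSV) with id headers.
This module validates those tables and provides the count-level primitives
everything downstream consumes: rarefaction to a fixed read depth,
conversion to within-sample relative abundances, and observed richness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "EnvTable",
    "RelativeAbundanceTable",
    "read_count_table",
    "write_count_table",
    "read_env_table",
    "write_env_table",
    "rarefy",
    "to_relative_abundance",
    "richness",
]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass(frozen=True)
class CountTable:
    """OTU x sample matrix of nonnegative integer read counts.

    Rows are OTUs, columns are samples (the amplicon-community convention).
    """

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.otu_ids, "OTU ids")
        _check_unique(self.sample_ids, "sample ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.otu_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def otu_index(self, otu_id: str) -> int:
        try:
            return self.otu_ids.index(str(otu_id))
        except ValueError:
            raise KeyError(f"unknown OTU id: {otu_id!r}") from None


@dataclass(frozen=True)
class EnvTable:
    """Sample x variable matrix of environmental measurements.

    Every variable must be finite with nonzero variance across samples, so
    that z-scoring downstream is well defined.
    """

    sample_ids: tuple[str, ...]
    var_names: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "var_names", tuple(str(v) for v in self.var_names))
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.var_names, "variable names")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.var_names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.var_names)} variables"
            )
        if not np.all(np.isfinite(values)):
            bad = [
                self.var_names[j]
                for j in np.unique(np.nonzero(~np.isfinite(values))[1])
            ]
            raise ValueError(f"non-finite values in variables: {bad}")
        sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
        if np.any(sd == 0):
            bad = [self.var_names[j] for j in np.nonzero(sd == 0)[0]]
            raise ValueError(f"zero-variance variables: {bad}")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.var_names)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnvTable":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class RelativeAbundanceTable:
    """OTU x sample matrix of within-sample relative abundances (each column sums to 1)."""

    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.otu_ids, "OTU ids")
        _check_unique(self.sample_ids, "sample ids")
        values = np.asarray(self.values, dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        colsums = values.sum(axis=0)
        ok = np.isclose(colsums, 1.0, atol=1e-9) | (colsums == 0)
        if not np.all(ok):
            bad = [self.sample_ids[j] for j in np.nonzero(~ok)[0]]
            raise ValueError(f"sample columns do not sum to 1: {bad}")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.otu_ids), columns=list(self.sample_ids)
        )


def read_count_table(path, sep: str = "\t", transpose: bool = False) -> CountTable:
    """Read an OTU count table from delimited text.

    First column holds OTU ids, header row holds sample ids. Row and column
    order are preserved. Set ``transpose=True`` only if the file is written
    samples-by-OTUs; orientation is never guessed.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells in count table")
    frac = np.mod(arr, 1) != 0
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"{path}: non-integer count {arr[i, j]!r} at "
            f"OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    neg = arr < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative count {arr[i, j]!r} at "
            f"OTU {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return CountTable(tuple(df.index), tuple(df.columns), arr.astype(np.int64))


def write_count_table(table: CountTable, path, sep: str = "\t") -> None:
    df = table.to_frame()
    df.index.name = "otu_id"
    df.to_csv(path, sep=sep)


def read_env_table(path, sep: str | None = None) -> EnvTable:
    """Read a sample x variable environment table (CSV or TSV, auto-detected)."""
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return EnvTable.from_frame(df)


def write_env_table(env: EnvTable, path, sep: str = ",") -> None:
    df = env.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def rarefy(
    table: CountTable,
    depth: int,
    seed: int,
    drop_short: bool = False,
) -> CountTable:
    """Subsample each sample column to exactly ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution of
    its counts (one draw per sample). Samples with fewer than ``depth`` total
    reads raise an error, or are dropped with a warning when
    ``drop_short=True``; silent loss of samples is never allowed.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    totals = table.counts.sum(axis=0)
    short = totals < depth
    keep = np.arange(table.n_samples)
    if short.any():
        shortfall = {
            table.sample_ids[j]: int(depth - totals[j]) for j in np.nonzero(short)[0]
        }
        if not drop_short:
            raise ValueError(
                f"samples below rarefaction depth {depth} (shortfall): {shortfall}"
            )
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            short.sum(), depth, sorted(shortfall),
        )
        keep = np.nonzero(~short)[0]
    rng = np.random.default_rng(seed)
    out = np.zeros((table.n_otus, len(keep)), dtype=np.int64)
    for k, j in enumerate(keep):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, k] = col
        else:
            out[:, k] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(
        table.otu_ids, tuple(table.sample_ids[j] for j in keep), out
    )


def to_relative_abundance(table: CountTable) -> RelativeAbundanceTable:
    """Divide each column by its read total."""
    colsums = table.counts.sum(axis=0)
    if np.any(colsums == 0):
        bad = [table.sample_ids[j] for j in np.nonzero(colsums == 0)[0]]
        raise ValueError(f"zero-sum sample columns: {bad}")
    return RelativeAbundanceTable(
        table.otu_ids, table.sample_ids, table.counts / colsums
    )


def richness(table: CountTable) -> pd.Series:
    """Observed richness: number of OTUs with count > 0, per sample."""
    return pd.Series(
        (table.counts > 0).sum(axis=0), index=list(table.sample_ids), name="richness"
    )
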