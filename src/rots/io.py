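"""Reading and writing expression matrices and result tables.

The input format is a plain delimited text matrix: one row per feature, one
column per sample, with feature identifiers in the first column and sample
identifiers in the header row.  This mirrors the layout used throughout
two-group omics studies (log-scale protein abundances, normalized RNA-seq
counts, microarray intensities).  Normalization is a preprocessing concern
and is deliberately out of scope: the matrix handed to ROTS is expected to be
ready for testing.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupAssignment",
    "read_expression_matrix",
    "filter_low_total_columns",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A feature x sample numeric matrix with unique row/column identifiers.

    Parameters
    ----------
    feature_ids : list of str
        Unique feature (gene/protein/transcript) identifiers, one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (G, N)
        Finite numeric values, typically log-scale intensities or normalized
        counts.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", [str(f) for f in self.feature_ids])
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        g, n = values.shape
        if g != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {g} rows of values"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample_ids for {n} columns of values"
            )
        if len(set(self.feature_ids)) != g:
            dupes = _duplicates(self.feature_ids)
            raise ValueError(f"duplicate feature IDs: {dupes}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {dupes}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}; "
                "missing values must be handled during preprocessing"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a DataFrame whose index holds feature IDs and columns
        hold sample IDs."""
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


class GroupAssignment:
    """Maps each sample column to one of two groups.

    Accepts any label vector with exactly two distinct values; the smaller
    label (numeric or lexicographic) becomes group 1, so swapping the two
    labels swaps the groups and negates the log fold change.  Both groups
    need at least two samples for the pooled standard error to be defined.
    """

    def __init__(self, labels) -> None:
        labels = list(labels)
        distinct = list(dict.fromkeys(labels))
        try:
            distinct = sorted(distinct)
        except TypeError:
            distinct = sorted(distinct, key=str)
        if len(distinct) != 2:
            raise ValueError(
                f"exactly two distinct group labels required, got {distinct!r}"
            )
        self.labels = labels
        self.group_names = (distinct[0], distinct[1])
        self.group1 = np.flatnonzero([x == distinct[0] for x in labels])
        self.group2 = np.flatnonzero([x == distinct[1] for x in labels])
        self.n1 = int(self.group1.size)
        self.n2 = int(self.group2.size)
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                f"each group needs >= 2 samples (got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupAssignment) and self.labels == other.labels

    def __repr__(self) -> str:
        return (
            f"GroupAssignment(n1={self.n1} [{self.group_names[0]!r}], "
            f"n2={self.n2} [{self.group_names[1]!r}])"
        )


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    # limited, predictable sniffing: tab beats comma, comma otherwise
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_expression_matrix(
    path: str | os.PathLike,
    delimiter: str | None = None,
    header: bool = True,
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path : str
        File with features as rows and samples as columns.  With
        ``header=True`` the first row holds sample IDs and the first column
        feature IDs; with ``header=False`` IDs ``F1..FG`` / ``S1..SN`` are
        synthesized.
    delimiter : str, optional
        Field delimiter.  When omitted, tab and comma are auto-detected.
    header : bool
        Whether the file carries a header row and ID column.

    Raises
    ------
    ValueError
        On non-numeric cells (naming the offending feature and sample),
        duplicate feature IDs, or ragged rows.
    """
    path = os.fspath(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        raw = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            dtype=str,
            keep_default_na=False,  # "NA" must surface as a parse error
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path!r}: {exc}") from exc
    if header:
        df = raw.set_index(raw.columns[0])
        df.index = df.index.astype(str)
        df.index.name = None
    else:
        df = raw.copy()
        df.index = [f"F{i + 1}" for i in range(df.shape[0])]
        df.columns = [f"S{j + 1}" for j in range(df.shape[1])]
    df = df.replace("", np.nan)
    if df.shape[1] == 0:
        raise ValueError(f"no sample columns found in {path!r}")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value (ragged row or empty cell) at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r} in {path!r}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path!r}"
        )
    # convert from the raw strings so values round-trip exactly
    values = np.asarray(df.to_numpy(), dtype=np.float64)
    return ExpressionMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def filter_low_total_columns(
    m: ExpressionMatrix, min_total: float
) -> ExpressionMatrix:
    """Drop sample columns whose total signal falls below ``min_total``.

    Used e.g. to exclude low-coverage cells from single-cell count matrices
    (a common threshold is a total expression of 10000).  Column order is
    preserved and the feature set is unchanged.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = m.values.sum(axis=0)
    keep = np.flatnonzero(totals >= min_total)
    if keep.size == 0:
        raise ValueError(
            f"all {m.n_samples} columns have total < {min_total}; "
            "nothing left to analyse"
        )
    return ExpressionMatrix(
        feature_ids=m.feature_ids,
        sample_ids=[m.sample_ids[j] for j in keep],
        values=m.values[:, keep],
    )


_META_KEYS = ("alpha1", "alpha2", "k", "R", "Z", "B", "K", "seed")


def write_results(r, path: str | os.PathLike) -> None:
    """Write a ROTS result table as TSV.

    The table has columns ``feature_id, d, logfc, pvalue, fdr`` in the
    original feature order, preceded by ``#``-prefixed metadata lines holding
    the selected statistic parameters and run settings.
    """
    path = os.fspath(path)
    buf = _io.StringIO()
    meta = {
        "alpha1": r.alpha1,
        "alpha2": r.alpha2,
        "k": r.k,
        "R": r.R,
        "Z": r.Z,
        "B": r.B,
        "K": r.K,
        "seed": r.seed,
    }
    for key in _META_KEYS:
        val = meta[key]
        buf.write(f"# {key}={val!r}\n")
    df = pd.DataFrame(
        {
            "feature_id": r.feature_ids,
            "d": r.d,
            "logfc": r.logfc,
            "pvalue": r.pvalue,
            "fdr": r.fdr,
        }
    )
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_results(path: str | os.PathLike) -> tuple[pd.DataFrame, dict]:
    """Read a results TSV written by :func:`write_results`.

    Returns the per-feature table and the parsed metadata dict.
    """
    path = os.fspath(path)
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, raw = line[1:].strip().partition("=")
            try:
                import ast

                meta[key.strip()] = ast.literal_eval(raw)
            except (ValueError, SyntaxError):
                meta[key.strip()] = raw
            body_start = i + 1
        else:
            break
    df = pd.read_csv(
        _io.StringIO("".join(lines[body_start:])),
        sep="\t",
        dtype={"feature_id": str},
        float_precision="round_trip",
    )
    return df, meta
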