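"""Reading, validation and harmonization of expression matrices and survival tables.

The pipeline consumes already-normalized log2 expression (e.g. RMA output from
Affymetrix arrays); raw CEL processing and normalization are out of scope.  Two
on-disk formats are supported: plain TSV (first column = gene/probe id, remaining
columns = samples) and the GEO series-matrix format, from which the numeric table
between the ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers
is extracted.

In memory an expression matrix is a :class:`ExpressionMatrix` — a thin, validated
wrapper around a genes × samples :class:`pandas.DataFrame` — and survival data is
a :class:`SurvivalTable` with one row per sample (``time`` ≥ 0, ``event`` ∈ {0,1}).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "collapse_probes",
    "align_samples",
]

#: log2/RMA values essentially never exceed this; larger suggests linear scale.
_LOG2_RANGE_WARN = 25.0


@dataclass(frozen=True)
class ExpressionMatrix:
    """A validated genes × samples matrix of log2 expression values.

    Parameters
    ----------
    data
        DataFrame with gene (or probe) identifiers as the index and sample
        identifiers as columns.  All values must be finite numbers; identifiers
        must be unique and non-empty.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if any(str(g).strip() == "" for g in df.index):
            raise ValueError("empty gene identifier")
        if any(str(s).strip() == "" for s in df.columns):
            raise ValueError("empty sample identifier")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(df)
            raise ValueError(f"non-numeric expression value at {bad}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if values.size and values.max() > _LOG2_RANGE_WARN:
            logger.warning(
                "max expression value %.3g exceeds %.3g; data may be on a "
                "linear rather than log2 scale",
                values.max(),
                _LOG2_RANGE_WARN,
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes])


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time and event indicator.

    ``data`` has a unique sample-id index and columns ``time`` (non-negative,
    consistent unit, e.g. months) and ``event`` (1 = death/event, 0 = censored).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample identifiers: {dups}")
        time = df["time"].to_numpy()
        if not np.issubdtype(time.dtype, np.number) or not np.all(np.isfinite(time)):
            raise ValueError("survival times must be finite numbers")
        if (time < 0).any():
            raise ValueError("negative survival time")
        event = df["event"].to_numpy()
        if not np.isin(event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for gene, row in df.iterrows():
        for sample, val in row.items():
            try:
                float(val)
            except (TypeError, ValueError):
                return f"gene {gene!r}, sample {sample!r} (value {val!r})"
    return "unknown position"


def _parse_table(text: str, source: str) -> ExpressionMatrix:
    df = pd.read_csv(
        _io.StringIO(text), sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.index = df.index.astype(str).str.strip().str.strip('"')
    df.columns = df.columns.astype(str).str.strip().str.strip('"')
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (df != "")
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{source}: non-numeric value {df.iat[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{source}: missing value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    # cell-wise float() is correctly rounded, so TSV round trips bit-identically
    # (pandas' fast parser can be off by one ulp)
    return ExpressionMatrix(df.map(float))


def read_expression(
    path: str | Path, format: Literal["tsv", "geo_series_matrix"] = "tsv"
) -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``format="tsv"`` expects a header row of sample ids and a first column of
    gene/probe ids.  ``format="geo_series_matrix"`` extracts the block between
    the ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` markers
    of a GEO series-matrix file and parses it the same way.  Row and column
    order are preserved from the file.
    """
    path = Path(path)
    text = path.read_text()
    if format == "geo_series_matrix":
        lines = text.splitlines()
        try:
            start = next(
                i for i, l in enumerate(lines)
                if l.startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, l in enumerate(lines)
                if l.startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise ValueError(
                f"{path}: series_matrix_table_begin/end markers not found"
            ) from None
        if end <= start + 1:
            raise ValueError(f"{path}: empty series-matrix table")
        text = "\n".join(lines[start + 1 : end])
    elif format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    return _parse_table(text, str(path))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write ``m`` as TSV; round-trips bit-identically through read_expression."""
    m.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: survival TSV must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    df["sample_id"] = df["sample_id"].str.strip()
    return SurvivalTable(df.set_index("sample_id")[["time", "event"]])


def write_survival(s: SurvivalTable, path: str | Path) -> None:
    s.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def collapse_probes(
    m: ExpressionMatrix,
    probe_map: pd.DataFrame | dict[str, str],
    rule: Literal["max_mean", "median"] = "max_mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``probe_map`` maps probe id → gene symbol (dict, or DataFrame with columns
    ``probe_id``/``gene_symbol``); a probe maps to at most one symbol.  Probes
    absent from the map are dropped (counted in the log).  With
    ``rule="max_mean"`` the retained row for each gene is the probe with the
    highest mean expression across samples (the common Affymetrix convention);
    with ``rule="median"`` each cell is the per-gene median across its probes.
    """
    if isinstance(probe_map, pd.DataFrame):
        if probe_map["probe_id"].duplicated().any():
            raise ValueError("a probe maps to more than one gene symbol")
        mapping = dict(zip(probe_map["probe_id"], probe_map["gene_symbol"]))
    else:
        mapping = dict(probe_map)
    present = [p for p in m.data.index if p in mapping]
    dropped = len(m.data) - len(present)
    if not present:
        raise ValueError("no probes in the expression matrix appear in the probe map")
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    df = m.data.loc[present]
    symbols = pd.Series([mapping[p] for p in present], index=df.index, name="symbol")
    if rule == "max_mean":
        means = df.mean(axis=1)
        best = means.groupby(symbols.to_numpy(), sort=False).idxmax()
        out = df.loc[best]
        out.index = pd.Index(best.index, name=None)
    elif rule == "median":
        out = df.groupby(symbols, sort=False).median()
        out.index.name = None
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    return ExpressionMatrix(out)


def align_samples(
    m: ExpressionMatrix, s: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both inputs to their shared samples, in identical order.

    Order follows the expression matrix.  Sample-id matching is exact string
    equality after whitespace trimming.  Raises if fewer than two samples are
    shared.
    """
    expr_ids = [str(c).strip() for c in m.data.columns]
    surv_ids = {str(i).strip() for i in s.data.index}
    shared = [c for c in expr_ids if c in surv_ids]
    if not shared:
        raise ValueError("expression and survival tables share no sample ids")
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared samples between expression and survival")
    dropped_expr = len(expr_ids) - len(shared)
    dropped_surv = len(surv_ids) - len(shared)
    if dropped_expr or dropped_surv:
        logger.info(
            "align_samples: dropped %d expression-only and %d survival-only samples",
            dropped_expr,
            dropped_surv,
        )
    m2 = ExpressionMatrix(m.data.loc[:, shared])
    s2 = SurvivalTable(s.data.loc[shared])
    return m2, s2
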