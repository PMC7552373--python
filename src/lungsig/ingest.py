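"""Reading expression tables and probe-level preprocessing.

Series-matrix-like TSV input: first column gene or probe identifier,
header row of sample IDs. Probe-level matrices are collapsed to unique
gene symbols by per-sample probe medians; intensities are brought onto
the log2 scale.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix, read_sample_sheet

__all__ = ["read_expression", "collapse_probes", "log2_transform"]


def read_expression(
    path: str | Path,
    sample_sheet_path: str | Path,
    probe_map: pd.Series | None = None,
) -> ExpressionMatrix | ProbeMatrix:
    """Read an expression TSV plus its sample sheet.

    If ``probe_map`` (probe ID -> gene symbol) is given, a
    :class:`ProbeMatrix` is returned for later collapsing; otherwise the
    first column is taken to hold gene symbols. Duplicated gene rows are
    only legal at the probe level.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from None
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()].tolist()
        raise ValueError(f"duplicated sample IDs in {path}: {dup}")
    sheet = read_sample_sheet(sample_sheet_path)
    missing = values.columns.difference(sheet.index)
    if len(missing):
        raise ValueError(
            f"samples absent from sample sheet: {missing.tolist()}")
    sheet = sheet.loc[values.columns]
    if probe_map is not None:
        return ProbeMatrix(values, probe_map, sheet)
    if values.index.duplicated().any():
        # duplicated symbols: treat as probe-level with the identity map
        return ProbeMatrix(
            values.set_index(pd.Index([f"row{i}" for i in range(len(values))])),
            pd.Series(values.index, index=[f"row{i}" for i in range(len(values))]),
            sheet,
        )
    return ExpressionMatrix(values, sheet)


def collapse_probes(m: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probes to unique gene symbols by per-sample medians.

    Probes with no mapped symbol (missing/empty) are dropped.
    """
    if m.probe_to_gene is None or len(m.probe_to_gene) == 0:
        raise ValueError("empty probe-to-gene map")
    symbols = m.probe_to_gene.reindex(m.values.index)
    keep = symbols.notna() & (symbols.astype(str).str.len() > 0)
    values = m.values.loc[keep.to_numpy()]
    symbols = symbols[keep].astype(str)
    collapsed = values.groupby(symbols.to_numpy()).median()
    collapsed.index.name = "gene"
    return ExpressionMatrix(collapsed, m.samples)


def log2_transform(
    m: ExpressionMatrix, offset: float = 0.0, already_log2: bool = False
) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; identity if already on log2 scale."""
    if already_log2:
        return m
    arr = m.values.to_numpy(dtype=float) + offset
    if (arr <= 0).any():
        raise ValueError(
            "nonpositive values under log2; supply a positive offset")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr), index=m.values.index, columns=m.values.columns),
        m.samples,
    )
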