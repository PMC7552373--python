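"""Core in-memory containers shared across the pipeline.

Expression data travel as a :class:`ExpressionMatrix`: a genes × samples
log2-intensity table plus a sample sheet carrying study membership and
phenotype. Phenotypes are restricted to the three states the study design
uses: ``healthy``, ``IPF`` and ``NSCLC``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHENOTYPES = ("healthy", "IPF", "NSCLC")

SAMPLE_SHEET_COLUMNS = ("sample_id", "study_id", "phenotype")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (unique gene symbols × unique sample IDs).

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample ID.
    samples
        Sample sheet indexed by sample ID with columns ``study_id`` and
        ``phenotype``; row order matches the columns of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicated gene symbols: {dup}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise ValueError(f"duplicated sample IDs: {dup}")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples missing from sample sheet: {missing.tolist()}")
        self.samples = self.samples.loc[self.values.columns]
        bad = set(self.samples["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotypes: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_mask(self, phenotypes: str | list[str]) -> np.ndarray:
        if isinstance(phenotypes, str):
            phenotypes = [phenotypes]
        return self.samples["phenotype"].isin(phenotypes).to_numpy()

    def subset_samples(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            ids = self.values.columns[mask_or_ids]
        else:
            ids = pd.Index(mask_or_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[pd.Index(genes)], self.samples)

    # -- serialization ---------------------------------------------------------

    def to_tsv(self, expr_path: str | Path, sheet_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(expr_path, sep="\t")
        if sheet_path is not None:
            sheet = self.samples.reset_index()
            sheet.columns = list(SAMPLE_SHEET_COLUMNS)
            sheet.to_csv(sheet_path, sep="\t", index=False)


@dataclass
class ProbeMatrix:
    """Probe-level intensities with a probe → gene-symbol map.

    Probes mapping to no symbol (empty string / NaN in ``probe_to_gene``)
    are dropped at collapse time. Duplicate gene rows are legal here —
    collapsing to unique symbols happens in :func:`lungsig.ingest.collapse_probes`.
    """

    values: pd.DataFrame  # probes × samples
    probe_to_gene: pd.Series  # index: probe ID, value: gene symbol
    samples: pd.DataFrame = field(default=None)  # optional sample sheet

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe IDs must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("duplicated sample IDs")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, study_id, phenotype)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicated sample IDs in sample sheet")
    return sheet.set_index("sample_id")
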