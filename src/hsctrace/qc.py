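"""Two-tier cell-quality filtering with survivorship reporting.

Thresholds are upper bounds applied with strict inequality: a cell survives
when ``n_genes < max_genes`` and ``n_transcripts < max_transcripts`` and
``pct_mito < max_pct_mito``.  The broad tier (8,500 / 60,000 / 25%) is meant
for a first cleaning pass over the full dataset; the stringent tier
(5,000 / 15,000 / 10%) for per-lineage reanalysis.  No lower bounds are
applied by default (``min_genes``/``min_transcripts`` are available and
default to 0, i.e. inactive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Exclusive upper bounds on per-cell QC statistics."""

    max_genes: int
    max_transcripts: int
    max_pct_mito: float
    min_genes: int = 0
    min_transcripts: int = 0

    def __post_init__(self) -> None:
        if self.max_genes <= 0 or self.max_transcripts <= 0:
            raise QCError("max_genes and max_transcripts must be strictly positive")
        if not 0.0 < self.max_pct_mito <= 100.0:
            raise QCError("max_pct_mito must be in (0, 100]")


BROAD = QCThresholds(max_genes=8_500, max_transcripts=60_000, max_pct_mito=25.0)
STRINGENT = QCThresholds(max_genes=5_000, max_transcripts=15_000, max_pct_mito=10.0)
TIERS = {"broad": BROAD, "stringent": STRINGENT}


def compute_cell_qc(adata: AnnData, mito_flags: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell ``n_genes`` (genes with count > 0), ``n_transcripts`` (row
    sum) and ``pct_mito`` (percent of transcripts from mito-flagged genes,
    computed on raw counts; 0 for all-zero cells, which are flagged)."""
    if mito_flags is None:
        if "mito" not in adata.var.columns:
            raise QCError("gene metadata lacks a 'mito' flag column")
        mito_flags = adata.var["mito"].to_numpy(bool)
    mito_flags = np.asarray(mito_flags, dtype=bool)
    X = adata.X.tocsr()
    n_genes = X.getnnz(axis=1)
    n_transcripts = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_transcripts > 0, 100.0 * mito_counts / np.maximum(n_transcripts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(int),
            "n_transcripts": n_transcripts.astype(int),
            "pct_mito": pct,
            "all_zero": n_transcripts == 0,
        },
        index=adata.obs_names,
    )


def filter_cells(
    adata: AnnData, thresholds: QCThresholds, qc: pd.DataFrame | None = None
) -> tuple[AnnData, pd.DataFrame]:
    """Apply ``thresholds`` and return the filtered matrix plus a per-sample
    survivorship report (kept + removed = input, per sample and in total)."""
    if thresholds is None:
        raise QCError("thresholds are required")
    if qc is None:
        qc = compute_cell_qc(adata)
    keep = (
        (qc["n_genes"] < thresholds.max_genes)
        & (qc["n_transcripts"] < thresholds.max_transcripts)
        & (qc["pct_mito"] < thresholds.max_pct_mito)
        & (qc["n_genes"] >= thresholds.min_genes)
        & (qc["n_transcripts"] >= thresholds.min_transcripts)
    ).to_numpy()
    sample = (
        adata.obs["sample_id"]
        if "sample_id" in adata.obs.columns
        else pd.Series("all", index=adata.obs_names)
    )
    report = (
        pd.DataFrame({"sample_id": np.asarray(sample), "kept": keep})
        .groupby("sample_id", sort=True)
        .agg(n_input=("kept", "size"), n_kept=("kept", "sum"))
        .reset_index()
    )
    report["n_removed"] = report["n_input"] - report["n_kept"]
    return adata[keep].copy(), report
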