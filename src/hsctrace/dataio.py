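"""Readers and writers for every external representation the pipeline touches.

The in-memory cell-by-gene container is an :class:`anndata.AnnData` with raw
integer counts in ``X`` (CSR), per-cell metadata in ``obs`` (``sample_id``,
``patient_id``, ``timepoint``, ``lineage``, ``subtype`` and, for simulated
cohorts, ``origin_truth``) and per-gene metadata in ``var`` (``chromosome``,
``mito``).  On disk the matrix lives as 1-based Matrix Market coordinates
(cells in rows, genes in columns) next to ``cells.tsv`` / ``genes.tsv``;
immune-receptor chains use the AIRR Rearrangement TSV dialect that TRUST4
emits at barcode level.

Parsers validate eagerly and never silently drop records: anything skipped is
counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from anndata import AnnData

logger = logging.getLogger("hsctrace")

#: Default ordering of the longitudinal timepoints (graft product, day 30 and
#: day 100 post-transplant).  Free-form timepoint labels are allowed; ordering
#: comes from the sample design, not from this constant.
DEFAULT_TIMEPOINT_ORDER = ("Graft", "D30", "D100")

#: Receptor loci the chain parser understands.
KNOWN_LOCI = frozenset({"TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL"})

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n"}

AIRR_REQUIRED_COLUMNS = ("cell_id", "locus", "junction_aa", "v_call", "j_call", "productive")


class DataValidationError(ValueError):
    """Raised when an on-disk table violates a structural invariant."""


@dataclass(frozen=True)
class ChainRecord:
    """One assembled receptor chain of one cell.

    ``cdr3_aa`` must use the 20-letter amino-acid alphabet; ``*`` and ``_``
    (stop / frameshift placeholders) are tolerated only on non-productive
    chains, which are retained but flagged and excluded downstream.
    """

    cell_id: str
    locus: str
    cdr3_aa: str
    v_call: str = ""
    j_call: str = ""
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise DataValidationError(f"empty CDR3 for cell {self.cell_id!r}")
        allowed = _AA20 if self.productive else _AA20 | {"*", "_"}
        bad = set(self.cdr3_aa) - allowed
        if bad:
            raise DataValidationError(
                f"invalid CDR3 characters {sorted(bad)} in {self.cdr3_aa!r} "
                f"(cell {self.cell_id!r}, productive={self.productive})"
            )


# ---------------------------------------------------------------------------
# cell x gene count matrices
# ---------------------------------------------------------------------------

def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].tolist()[:5]
        raise DataValidationError(f"duplicate {what} ids: {dup}")


def read_counts(matrix_path: str | Path, cells_path: str | Path, genes_path: str | Path) -> AnnData:
    """Read a Matrix Market count matrix plus cell/gene TSV tables.

    Row/column order is preserved exactly as written.  Raises
    :class:`DataValidationError` on dimension mismatches, duplicate ids or
    negative / non-integer entries, naming the offending record.
    """
    coo = scipy.io.mmread(str(matrix_path))
    cells = pd.read_csv(cells_path, sep="\t", dtype=str).set_index("cell_id")
    genes = pd.read_csv(genes_path, sep="\t", dtype=str).set_index("gene_id")
    _check_unique(cells.index, "cell")
    _check_unique(genes.index, "gene")
    if coo.shape != (len(cells), len(genes)):
        raise DataValidationError(
            f"dimension mismatch: matrix is {coo.shape} but metadata lists "
            f"{len(cells)} cells x {len(genes)} genes"
        )
    data = np.asarray(coo.data)
    if data.size:
        if np.any(data < 0):
            i = int(np.argmax(data < 0))
            raise DataValidationError(
                f"negative count {data[i]} at cell {cells.index[coo.row[i]]!r}, "
                f"gene {genes.index[coo.col[i]]!r}"
            )
        if not np.all(data == np.floor(data)):
            i = int(np.argmax(data != np.floor(data)))
            raise DataValidationError(
                f"non-integer count {data[i]} at cell {cells.index[coo.row[i]]!r}, "
                f"gene {genes.index[coo.col[i]]!r}"
            )
    X = sp.csr_matrix(coo).astype(np.int64)
    if "mito" in genes.columns:
        genes = genes.assign(mito=genes["mito"].str.lower().isin(_TRUTHY))
    adata = AnnData(X=X, obs=cells, var=genes)
    logger.info("read_counts: %d cells x %d genes from %s", adata.n_obs, adata.n_vars, matrix_path)
    return adata


def write_counts(adata: AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write ``matrix.mtx`` + ``cells.tsv`` + ``genes.tsv`` so that
    :func:`read_counts` inverts the result exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    X = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(paths["matrix"]), X, field="integer")
    adata.obs.rename_axis("cell_id").to_csv(paths["cells"], sep="\t")
    adata.var.rename_axis("gene_id").to_csv(paths["genes"], sep="\t")
    return paths


def validate_cell_matrix(adata: AnnData, design: pd.DataFrame | None = None) -> None:
    """Check the CellMatrix invariants, optionally against a sample design."""
    _check_unique(adata.obs_names, "cell")
    _check_unique(adata.var_names, "gene")
    if adata.X.min() < 0:
        raise DataValidationError("negative entries in count matrix")
    if "sample_id" not in adata.obs.columns:
        raise DataValidationError("cell metadata lacks 'sample_id'")
    if design is not None:
        missing = set(adata.obs["sample_id"]) - set(design["sample_id"])
        if missing:
            raise DataValidationError(f"cells reference unknown samples: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# AIRR rearrangement tables
# ---------------------------------------------------------------------------

def _parse_bool(value: str, context: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise DataValidationError(f"cannot parse productive flag {value!r} ({context})")


def read_airr(path: str | Path) -> list[ChainRecord]:
    """Parse an AIRR Rearrangement TSV into chain records.

    Extra AIRR columns are ignored; a missing mandatory column is a hard
    error.  Rows with an unknown locus are skipped with a logged count —
    input row count always equals retained + skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"AIRR table {path} missing mandatory columns {missing}")
    records: list[ChainRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        locus = row.locus
        if locus not in KNOWN_LOCI:
            skipped += 1
            continue
        records.append(
            ChainRecord(
                cell_id=row.cell_id,
                locus=locus,
                cdr3_aa=row.junction_aa,
                v_call=row.v_call,
                j_call=row.j_call,
                productive=_parse_bool(row.productive, f"cell {row.cell_id}"),
            )
        )
    if skipped:
        logger.warning("read_airr: skipped %d rows with unknown locus (%s)", skipped, path)
    logger.info("read_airr: %d of %d rows retained from %s", len(records), len(df), path)
    return records


def write_airr(records: list[ChainRecord], path: str | Path) -> Path:
    """Write chain records as an AIRR Rearrangement TSV."""
    path = Path(path)
    chains_to_frame(records).rename(columns={"cdr3_aa": "junction_aa"}).assign(
        productive=lambda d: np.where(d.pop("productive"), "T", "F")
    ).to_csv(path, sep="\t", index=False)
    return path


def chains_to_frame(records: list[ChainRecord]) -> pd.DataFrame:
    """Chain records as a DataFrame (cell_id, locus, cdr3_aa, v_call, j_call, productive)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "locus": [r.locus for r in records],
            "cdr3_aa": [r.cdr3_aa for r in records],
            "v_call": [r.v_call for r in records],
            "j_call": [r.j_call for r in records],
            "productive": [r.productive for r in records],
        }
    )


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def validate_sample_design(design: pd.DataFrame, require_sex: bool = False) -> None:
    """Validate the sample design: unique (patient, timepoint) pairs and,
    when demultiplexing is requested, populated M/F sex fields."""
    for col in ("sample_id", "patient_id", "timepoint"):
        if col not in design.columns:
            raise DataValidationError(f"sample design lacks column {col!r}")
    dup = design.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        rows = design.loc[dup, ["patient_id", "timepoint"]].iloc[0].tolist()
        raise DataValidationError(f"duplicate (patient_id, timepoint) pair: {rows}")
    _check_unique(pd.Index(design["sample_id"]), "sample")
    if require_sex:
        for col in ("donor_sex", "recipient_sex"):
            if col not in design.columns or not design[col].isin(["M", "F"]).all():
                raise DataValidationError(f"sample design column {col!r} must be 'M' or 'F'")


def read_sample_design(
    path: str | Path, timepoint_order: tuple[str, ...] = DEFAULT_TIMEPOINT_ORDER
) -> pd.DataFrame:
    """Read the sample design TSV; ``timepoint`` becomes an ordered categorical."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    validate_sample_design(design)
    extra = [t for t in design["timepoint"].unique() if t not in timepoint_order]
    design["timepoint"] = pd.Categorical(
        design["timepoint"], categories=list(timepoint_order) + sorted(extra), ordered=True
    )
    return design


# ---------------------------------------------------------------------------
# signatures and configuration
# ---------------------------------------------------------------------------

def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Read gene signatures from a two-column TSV (signature_name, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["signature_name", "gene_id"]:
        raise DataValidationError(
            f"signature file {path} must have columns signature_name, gene_id"
        )
    return {name: sub["gene_id"].tolist() for name, sub in df.groupby("signature_name", sort=False)}


def load_config(path: str | Path) -> dict:
    """Load a nested key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataValidationError(f"config {path} must be a mapping at top level")
    return cfg
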