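"""CDR3-based clonotype definition, repertoire overlap and clone tracing.

A clonotype is the set of cells sharing a receptor-chain CDR3 amino-acid
sequence, keyed per locus (TRB for alpha/beta T cells, TRD for gamma/delta
T cells, IGH for B cells).  V/J calls are carried as annotation but are not
part of the key; a stricter (V, J, CDR3) key is available via
``strict_key=True``.  Only productive chains of QC-passed cells enter the
repertoire; a cell with several distinct productive CDR3s of one locus
contributes one member to each of those clonotypes (counted and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dataio import ChainRecord, chains_to_frame

logger = logging.getLogger("hsctrace")


class ClonotypeError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapResult:
    """Shared clonotypes between two repertoires of the same locus."""

    sample_a: str
    sample_b: str
    locus: str
    shared: frozenset
    n_a: int
    n_b: int
    n_shared: int

    def __post_init__(self) -> None:
        assert self.n_shared <= min(self.n_a, self.n_b)


def _as_frame(chains) -> pd.DataFrame:
    if isinstance(chains, pd.DataFrame):
        return chains
    return chains_to_frame(list(chains))


def build_repertoire(
    chains,
    cell_meta: pd.DataFrame,
    locus: str,
    strict_key: bool = False,
) -> pd.DataFrame:
    """One clonotype row per (sample, locus, CDR3): size, member cells and
    V/J annotation.  ``chains`` may be ChainRecords or a chain DataFrame;
    chains of cells absent from ``cell_meta`` (e.g. QC-removed) are dropped
    with a logged count."""
    df = _as_frame(chains)
    df = df[(df["locus"] == locus) & df["productive"]]
    if df.empty:
        logger.warning("build_repertoire: no productive %s chains", locus)
        return pd.DataFrame(
            columns=["sample_id", "locus", "cdr3_aa", "v_call", "j_call", "size", "cell_ids"]
        )
    known = df["cell_id"].isin(cell_meta.index)
    if not known.all():
        logger.info(
            "build_repertoire: dropped %d chains of cells not in metadata", int((~known).sum())
        )
        df = df[known]
    df = df.assign(sample_id=cell_meta.loc[df["cell_id"], "sample_id"].to_numpy())
    before = len(df)
    key = ["sample_id", "cdr3_aa", "v_call", "j_call"] if strict_key else ["sample_id", "cdr3_aa"]
    df = df.drop_duplicates(subset=key + ["cell_id"])
    multi = df.duplicated(subset=["sample_id", "cell_id"], keep=False).sum()
    if multi:
        logger.info("build_repertoire: %d chain rows from multi-chain cells (%s)", int(multi), locus)
    if before != len(df):
        logger.info("build_repertoire: deduplicated %d repeated chains", before - len(df))
    group_key = key if strict_key else ["sample_id", "cdr3_aa"]
    rep = (
        df.groupby(group_key, sort=True)
        .agg(
            size=("cell_id", "nunique"),
            cell_ids=("cell_id", lambda s: sorted(set(s))),
            v_call=("v_call", lambda s: ",".join(sorted(set(s)))),
            j_call=("j_call", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    rep["locus"] = locus
    return rep[["sample_id", "locus", "cdr3_aa", "v_call", "j_call", "size", "cell_ids"]]


def repertoire_overlap(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> OverlapResult:
    """Set intersection of the CDR3 keys of two same-locus repertoires."""
    loci_a = set(rep_a["locus"]) if len(rep_a) else set()
    loci_b = set(rep_b["locus"]) if len(rep_b) else set()
    if len(loci_a | loci_b) > 1:
        raise ClonotypeError(f"locus mismatch: {sorted(loci_a)} vs {sorted(loci_b)}")
    locus = next(iter(loci_a | loci_b), "")
    set_a = set(rep_a["cdr3_aa"]) if len(rep_a) else set()
    set_b = set(rep_b["cdr3_aa"]) if len(rep_b) else set()
    shared = frozenset(set_a & set_b)

    def _name(rep: pd.DataFrame) -> str:
        return ",".join(sorted(set(rep["sample_id"]))) if len(rep) else ""

    return OverlapResult(
        sample_a=_name(rep_a),
        sample_b=_name(rep_b),
        locus=locus,
        shared=shared,
        n_a=len(set_a),
        n_b=len(set_b),
        n_shared=len(shared),
    )


def rank_expanded(rep: pd.DataFrame, k: int = 3, pool: bool = True) -> pd.DataFrame:
    """Top-``k`` clonally expanded clonotypes.

    With ``pool=True`` (default) sizes are summed over all samples in the
    repertoire table before ranking — expansion across a patient's pooled
    post-transplant samples.  Ties are broken lexicographically on the CDR3
    so the ranking is deterministic.
    """
    if rep.empty:
        return rep.copy()
    if pool:
        pooled = (
            rep.groupby(["locus", "cdr3_aa"], sort=False)["size"].sum().reset_index()
        )
    else:
        pooled = rep[["locus", "cdr3_aa", "size"]].copy()
    pooled = pooled.sort_values(
        ["size", "cdr3_aa"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return pooled.head(k)


def trace_clones(
    clones: pd.DataFrame,
    chains,
    cell_meta: pd.DataFrame,
    timepoints: tuple[str, ...],
) -> pd.DataFrame:
    """Per-clone, per-timepoint member counts with subtype composition.

    ``clones`` needs ``locus`` and ``cdr3_aa`` columns (e.g. the output of
    :func:`rank_expanded`).  A clone absent at a timepoint yields a zero
    row, not an error; where present, subtype proportions sum to one.
    """
    df = _as_frame(chains)
    df = df[df["productive"] & df["cell_id"].isin(cell_meta.index)]
    df = df.assign(
        timepoint=cell_meta.loc[df["cell_id"], "timepoint"].astype(str).to_numpy(),
        subtype=cell_meta.loc[df["cell_id"], "subtype"].to_numpy(),
    )
    rows = []
    for clone in clones.itertuples(index=False):
        members = df[(df["locus"] == clone.locus) & (df["cdr3_aa"] == clone.cdr3_aa)]
        for tp in timepoints:
            at_tp = members[members["timepoint"] == tp].drop_duplicates("cell_id")
            total = len(at_tp)
            if total == 0:
                rows.append(
                    {
                        "locus": clone.locus, "cdr3_aa": clone.cdr3_aa, "timepoint": tp,
                        "total_cells": 0, "subtype": None, "n_cells": 0, "proportion": 0.0,
                    }
                )
                continue
            for subtype, n in at_tp.groupby("subtype", observed=True).size().sort_index().items():
                rows.append(
                    {
                        "locus": clone.locus, "cdr3_aa": clone.cdr3_aa, "timepoint": tp,
                        "total_cells": total, "subtype": subtype,
                        "n_cells": int(n), "proportion": n / total,
                    }
                )
    return pd.DataFrame(rows)
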