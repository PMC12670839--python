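"""Group-comparison statistics, the cytokine screen, pseudobulk export and
2^-ΔΔCt quantification.

Hypothesis tests delegate to scipy (paired and Welch t-tests, Mann-Whitney U
with midranks; exact U enumeration when both groups have at most
``MWU_EXACT_MAX`` untied observations).  A paired comparison whose
differences have zero variance has no defined t statistic and raises
:class:`ZeroVarianceError` — table-producing operations catch it and flag
the row untested rather than reporting a spurious p-value.

Zero fractions and zero group means are handled with a recorded pseudocount
ε = 1/(n + 1), where n is the relevant cell denominator, so log2 fold
changes stay finite and swapping the contrast negates them exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from anndata import AnnData

logger = logging.getLogger("hsctrace")

MWU_EXACT_MAX = 8


class StatsError(ValueError):
    pass


class ZeroVarianceError(StatsError):
    """The test statistic is undefined because the data have no variance."""


def percentage(count: float, total: float, ndigits: int = 1) -> float:
    """``100 * count / total`` rounded to ``ndigits`` — for worked-example
    arithmetic such as doublet ratios and gated-cell percentages."""
    if total <= 0:
        raise StatsError("total must be positive")
    return round(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def t_test(x, y, paired: bool = False) -> dict:
    """Two-tailed Student's t-test: paired (df = n - 1) or Welch for
    independent samples (Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise StatsError("paired test requires equal-length samples")
        if len(x) < 2:
            raise StatsError("paired test requires n >= 2")
        diffs = x - y
        if np.ptp(diffs) == 0:
            raise ZeroVarianceError("paired differences have zero variance")
        res = scipy.stats.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise StatsError("independent test requires n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ZeroVarianceError("both groups have zero variance")
        res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U (U reported for ``x``): exact enumeration
    when both groups are small (n <= 8) and untied, otherwise the normal
    approximation with midranks and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("Mann-Whitney U requires non-empty samples")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = len(x) <= MWU_EXACT_MAX and len(y) <= MWU_EXACT_MAX and not ties
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {"U": float(res.statistic), "p": float(res.pvalue),
            "method": "exact" if exact else "asymptotic"}


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; the family size defaults to
    the panel length and is the caller's reported family."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def subtype_proportions(cell_meta: pd.DataFrame, denominator: str = "lineage") -> pd.DataFrame:
    """Per-sample subtype proportions.

    ``denominator`` is "lineage" (fraction of the subtype's lineage in that
    sample) or "all_cells".  The full (sample x subtype) panel is emitted,
    including zero counts; rows whose denominator is zero are omitted with
    a warning.
    """
    if denominator not in ("lineage", "all_cells"):
        raise StatsError("denominator must be 'lineage' or 'all_cells'")
    meta = cell_meta[["sample_id", "lineage", "subtype"]].astype(str)
    counts = (
        meta.groupby(["sample_id", "lineage", "subtype"]).size().rename("n_cells").reset_index()
    )
    panel = counts[["lineage", "subtype"]].drop_duplicates()
    samples = pd.DataFrame({"sample_id": meta["sample_id"].unique()})
    full = samples.merge(panel, how="cross").merge(
        counts, on=["sample_id", "lineage", "subtype"], how="left"
    )
    full["n_cells"] = full["n_cells"].fillna(0).astype(int)
    if denominator == "lineage":
        denom = (
            meta.groupby(["sample_id", "lineage"]).size().rename("denominator").reset_index()
        )
        full = full.merge(denom, on=["sample_id", "lineage"], how="left")
    else:
        denom = meta.groupby("sample_id").size().rename("denominator").reset_index()
        full = full.merge(denom, on="sample_id", how="left")
    full["denominator"] = full["denominator"].fillna(0).astype(int)
    zero = full["denominator"] == 0
    if zero.any():
        logger.warning("subtype_proportions: omitting %d zero-denominator rows", int(zero.sum()))
        full = full[~zero]
    full["proportion"] = full["n_cells"] / full["denominator"]
    return full.reset_index(drop=True)


def differential_abundance(
    proportions: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subtype abundance contrast between two sample groups.

    ``contrast = (design_column, group_a, group_b)``.  The log2 fold change
    compares group mean proportions with pseudocount ε = 1/(mean denominator
    + 1) added to both means; the t-test (paired on matched patient order,
    Welch otherwise) runs on the per-sample proportions, and Bonferroni
    correction spans the subtype panel.  Degenerate rows are flagged
    ``untested``.
    """
    col, group_a, group_b = contrast
    info = design.set_index("sample_id")
    props = proportions.merge(
        info[[col, "patient_id"]], left_on="sample_id", right_index=True, how="left"
    )
    rows = []
    for (lineage, subtype), sub in props.groupby(["lineage", "subtype"], sort=True):
        a = sub[sub[col] == group_a].sort_values("patient_id")
        b = sub[sub[col] == group_b].sort_values("patient_id")
        if paired:
            shared = sorted(set(a["patient_id"]) & set(b["patient_id"]))
            a = a[a["patient_id"].isin(shared)].sort_values("patient_id")
            b = b[b["patient_id"].isin(shared)].sort_values("patient_id")
        pa, pb = a["proportion"].to_numpy(), b["proportion"].to_numpy()
        eps = 1.0 / (
            float(pd.concat([a, b])["denominator"].mean() if len(a) + len(b) else 0.0) + 1.0
        )
        mean_a, mean_b = (pa.mean() if len(pa) else 0.0), (pb.mean() if len(pb) else 0.0)
        log2fc = float(np.log2((mean_a + eps) / (mean_b + eps)))
        row = {
            "lineage": lineage, "subtype": subtype,
            "contrast": f"{group_a}_vs_{group_b}",
            "n_a": len(pa), "n_b": len(pb),
            "mean_a": mean_a, "mean_b": mean_b,
            "pseudocount": eps, "log2fc": log2fc,
            "test": "paired t" if paired else "Welch t",
            "p_value": np.nan, "untested": False,
        }
        try:
            row["p_value"] = t_test(pa, pb, paired=paired)["p"]
        except StatsError as exc:
            row["untested"] = True
            row["note"] = str(exc)
        rows.append(row)
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_adjusted"] = bonferroni(out["p_value"].to_numpy(), m=m)
    out["family_size"] = m
    out["significant"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# cytokine screen
# ---------------------------------------------------------------------------

def positive_fraction_table(
    adata: AnnData,
    gene: str,
    groupby: tuple[str, ...] = ("donor", "condition", "cell_class"),
) -> pd.DataFrame:
    """Marker-positive cell fractions per metadata group (raw UMI > 0)."""
    if gene not in adata.var_names:
        raise StatsError(f"gene {gene!r} absent from matrix")
    col = np.asarray((adata[:, gene].X > 0).todense()).ravel()
    df = adata.obs.loc[:, list(groupby)].copy()
    df["positive"] = col
    out = (
        df.groupby(list(groupby), sort=True, observed=True)
        .agg(fraction=("positive", "mean"), n_cells=("positive", "size"))
        .reset_index()
    )
    return out


def cytokine_screen(
    fractions: pd.DataFrame,
    baseline_label: str = "PBS",
    alpha: float = 0.05,
    test_on: str = "fractions",
) -> pd.DataFrame:
    """Paired within-donor marker-positivity screen.

    ``fractions`` has columns donor, condition, cell_class, fraction,
    n_cells.  Per (cytokine, class): per-donor
    log2((f_treated + ε_t) / (f_baseline + ε_b)) with ε = 1/(n_cells + 1),
    the mean log2FC, and a two-tailed paired t-test of treated versus
    baseline values across donors (``test_on`` chooses fractions, the
    default, or the per-donor log2FCs against zero).  Volcano coordinates
    are (log2fc, -log10 p); significance is uncorrected p < 0.05 as in a
    screening volcano.  Donors lacking a baseline sample are dropped with a
    warning.
    """
    if test_on not in ("fractions", "log2fc"):
        raise StatsError("test_on must be 'fractions' or 'log2fc'")
    base = fractions[fractions["condition"] == baseline_label]
    if base.empty:
        raise StatsError(f"no baseline samples labelled {baseline_label!r}")
    base = base.set_index(["donor", "cell_class"])
    treated = fractions[fractions["condition"] != baseline_label]
    missing = set(treated["donor"]) - set(base.index.get_level_values(0))
    if missing:
        logger.warning("cytokine_screen: dropping donors without baseline: %s", sorted(missing))
        treated = treated[~treated["donor"].isin(missing)]
    rows = []
    for (condition, cell_class), sub in treated.groupby(["condition", "cell_class"], sort=True, observed=True):
        sub = sub.sort_values("donor")
        keys = [(d, cell_class) for d in sub["donor"]]
        have = [k in base.index for k in keys]
        sub = sub[np.array(have, dtype=bool)]
        if sub.empty:
            continue
        b = base.loc[[(d, cell_class) for d in sub["donor"]]]
        f_t = sub["fraction"].to_numpy()
        f_b = b["fraction"].to_numpy()
        eps_t = 1.0 / (sub["n_cells"].to_numpy() + 1.0)
        eps_b = 1.0 / (b["n_cells"].to_numpy() + 1.0)
        log2fc = np.log2((f_t + eps_t) / (f_b + eps_b))
        row = {
            "cytokine": condition, "cell_class": cell_class,
            "n_donors": len(sub), "log2fc": float(log2fc.mean()),
            "p_value": np.nan, "untested": False,
        }
        try:
            if test_on == "fractions":
                row["p_value"] = t_test(f_t, f_b, paired=True)["p"]
            else:
                row["p_value"] = t_test(log2fc, np.zeros_like(log2fc), paired=True)["p"]
        except StatsError as exc:
            row["untested"] = True
            row["note"] = str(exc)
        row["neg_log10_p"] = float(-np.log10(row["p_value"])) if row["p_value"] > 0 else np.inf
        row["significant"] = bool(row["p_value"] < alpha) if not row["untested"] else False
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def aggregate_pseudobulk(
    adata: AnnData, group_keys: tuple[str, ...] = ("sample_id", "lineage")
) -> pd.DataFrame:
    """Sum raw counts per group — pseudobulk profiles for external DE
    engines.  Rows are groups (index = joined key), columns genes; integer,
    and column sums are conserved across the aggregation."""
    for key in group_keys:
        if key not in adata.obs.columns:
            raise StatsError(f"group key {key!r} absent from cell metadata")
    labels = adata.obs[list(group_keys)].astype(str).agg("|".join, axis=1)
    codes, uniques = pd.factorize(labels, sort=True)
    indicator = sp.csr_matrix(
        (np.ones(adata.n_obs), (codes, np.arange(adata.n_obs))),
        shape=(len(uniques), adata.n_obs),
    )
    sums = indicator @ sp.csr_matrix(adata.X)
    return pd.DataFrame(
        sums.toarray().astype(np.int64), index=pd.Index(uniques, name="|".join(group_keys)),
        columns=adata.var_names,
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_rows: pd.DataFrame,
    target: str = "MDGA1",
    reference_gene: str = "GAPDH",
    reference_group: str = "non-aGvHD",
) -> pd.DataFrame:
    """2^-ΔΔCt relative quantification.

    ``ct_rows`` has columns sample_id, group, gene, replicate, ct.
    Technical replicates are averaged per (sample, gene) first; then
    ΔCt = Ct_target - Ct_reference per sample, ΔΔCt subtracts the mean ΔCt
    of the reference group, and RQ = 2^-ΔΔCt.  Samples missing the
    reference gene are dropped with a warning.  By construction the
    reference group's mean ΔΔCt is zero, i.e. its geometric-mean RQ is 1.
    """
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    if not required.issubset(ct_rows.columns):
        raise StatsError(f"Ct table must have columns {sorted(required)}")
    means = (
        ct_rows.groupby(["sample_id", "group", "gene"])["ct"].mean().rename("ct_mean").reset_index()
    )
    wide = means.pivot(index=["sample_id", "group"], columns="gene", values="ct_mean")
    for gene in (target, reference_gene):
        if gene not in wide.columns:
            raise StatsError(f"gene {gene!r} absent from Ct table")
    dropped = wide[wide[reference_gene].isna() | wide[target].isna()]
    if len(dropped):
        logger.warning(
            "delta_delta_ct: dropping %d samples lacking %s or %s measurements",
            len(dropped), target, reference_gene,
        )
        wide = wide.dropna(subset=[target, reference_gene])
    wide = wide.reset_index()
    if not (wide["group"] == reference_group).any():
        raise StatsError(f"reference group {reference_group!r} has no samples")
    wide["delta_ct"] = wide[target] - wide[reference_gene]
    ref_mean = wide.loc[wide["group"] == reference_group, "delta_ct"].mean()
    wide["delta_delta_ct"] = wide["delta_ct"] - ref_mean
    wide["rq"] = 2.0 ** (-wide["delta_delta_ct"])
    out = wide.rename(columns={target: "ct_target", reference_gene: "ct_reference"})
    assert abs(out.loc[out["group"] == reference_group, "delta_delta_ct"].mean()) < 1e-9
    return out[
        ["sample_id", "group", "ct_target", "ct_reference", "delta_ct", "delta_delta_ct", "rq"]
    ]
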