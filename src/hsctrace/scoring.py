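"""Log-normalization, expression-binned gene-module scores and marker calls.

The module score of a signature in a cell is the mean log-normalized
expression over the signature genes minus the mean over a control gene set
matched on average expression: genes are ranked by dataset-mean expression,
cut into ``n_bins`` equal-size bins, and ``ctrl_size`` control genes are
sampled (without replacement, fixed seed) from the bin of each signature
gene.  Signature genes are excluded from a control pool unless that would
empty it, in which case the whole bin is used — so a signature spanning the
entire gene universe scores exactly zero.

Sex scores are two such module scores over the Y-linked gene set and the
XIST/TSIX set; the ADGRG1 cytotoxicity feature is the module score of its
printed 20-gene program.  Marker positivity is parameter-free: a cell is
positive when it has any UMI of the gene (normalized value > 0), which makes
positive fractions invariant to the normalization target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .simulate import ADGRG1_PROGRAM, X_GENES, Y_GENES

logger = logging.getLogger("hsctrace")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list; duplicates are rejected."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes) -> None:
        genes = tuple(genes)
        if not genes:
            raise ScoringError(f"signature {name!r} is empty")
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if list(genes).count(g) > 1})
            raise ScoringError(f"signature {name!r} contains duplicates: {dup}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)


Y_SIGNATURE = GeneSignature("chr_y", Y_GENES)
X_SIGNATURE = GeneSignature("chr_x", X_GENES)
ADGRG1_SIGNATURE = GeneSignature("adgrg1_program", ADGRG1_PROGRAM)


@dataclass(frozen=True)
class ScoreParams:
    """Control-gene scheme: 25 expression bins, 50 controls per signature
    gene, seed recorded so the draw is reproducible."""

    n_bins: int = 25
    ctrl_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ScoringError("n_bins must be >= 2")
        if self.ctrl_size < 1:
            raise ScoringError("ctrl_size must be >= 1")


def lognormalize(adata: AnnData, target_sum: float = 10_000.0) -> AnnData:
    """Counts-per-``target_sum`` then natural log1p.

    Returns a copy with normalized values in ``X`` (float64) and the raw
    counts retained in ``layers["counts"]``.  All-zero cells stay all-zero
    and are flagged in ``obs["all_zero"]``.
    """
    out = adata.copy()
    X = sp.csr_matrix(out.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("lognormalize: %d all-zero cells", int(zero.sum()))
    factors = np.where(zero, 0.0, target_sum / np.maximum(totals, 1e-300))
    X = sp.diags(factors) @ X
    X.data = np.log1p(X.data)
    out.layers["counts"] = out.X
    out.X = X
    out.obs["all_zero"] = zero
    out.uns["normalization"] = {"target_sum": target_sum, "log": "log1p"}
    return out


def _expression_bins(X: sp.spmatrix, n_bins: int) -> list[np.ndarray]:
    """Gene indices grouped into ``n_bins`` equal-size bins of ascending
    dataset-mean expression (stable sort, so ties keep input order)."""
    means = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(means, kind="stable")
    return np.array_split(order, n_bins)


def _control_draw(
    X: sp.spmatrix, gene_index: dict[str, int], sig_idx: list[int], params: ScoreParams
) -> np.ndarray:
    bins = _expression_bins(X, params.n_bins)
    bin_of = np.empty(X.shape[1], dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b
    sig_set = set(sig_idx)
    rng = np.random.default_rng(params.seed)
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.array([g for g in bins[bin_of[gi]] if g not in sig_set])
        if pool.size == 0:
            pool = bins[bin_of[gi]]  # signature fills the bin: fall back to it
        take = min(params.ctrl_size, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    return np.array(sorted(ctrl), dtype=int)


def module_score(
    adata: AnnData, signature: GeneSignature, params: ScoreParams = ScoreParams()
) -> pd.Series:
    """Per-cell module score of ``signature`` on a log-normalized matrix.

    Signature genes absent from the gene universe are dropped with a logged
    warning; an empty intersection is an error.  Deterministic under
    ``params.seed``.
    """
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    present = [g for g in signature.genes if g in gene_index]
    missing = [g for g in signature.genes if g not in gene_index]
    if missing:
        logger.warning(
            "module_score(%s): %d signature genes absent: %s",
            signature.name, len(missing), missing[:5],
        )
    if not present:
        raise ScoringError(f"signature {signature.name!r} absent from gene universe")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    sig_idx = [gene_index[g] for g in present]
    ctrl_idx = _control_draw(X, gene_index, sig_idx, params)
    sig_mean = np.asarray(X[:, sig_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return pd.Series(sig_mean - ctrl_mean, index=adata.obs_names, name=signature.name)


def sex_scores(
    adata: AnnData,
    y_signature: GeneSignature = Y_SIGNATURE,
    x_signature: GeneSignature = X_SIGNATURE,
    params: ScoreParams = ScoreParams(),
    per_sample: bool = False,
) -> pd.DataFrame:
    """Chr-Y and Chr-X module scores per cell.

    By default control bins are formed over the whole dataset jointly; with
    ``per_sample=True`` scoring (binning and control draw) is repeated
    within each sample.
    """
    if per_sample:
        parts = []
        for sample in pd.unique(adata.obs["sample_id"]):
            sub = adata[adata.obs["sample_id"] == sample]
            parts.append(
                pd.DataFrame(
                    {
                        "chr_y_score": module_score(sub, y_signature, params),
                        "chr_x_score": module_score(sub, x_signature, params),
                    }
                )
            )
        return pd.concat(parts).loc[adata.obs_names]
    return pd.DataFrame(
        {
            "chr_y_score": module_score(adata, y_signature, params),
            "chr_x_score": module_score(adata, x_signature, params),
        }
    )


def adgrg1_feature(
    adata: AnnData,
    signature: GeneSignature = ADGRG1_SIGNATURE,
    params: ScoreParams = ScoreParams(),
) -> pd.Series:
    """The ADGRG1 cytotoxicity feature: module score of the 20-gene program."""
    return module_score(adata, signature, params).rename("adgrg1_feature")


def positive_fraction(adata: AnnData, gene_id: str, cells=None) -> float:
    """Fraction of cells (optionally a subset) with any expression of
    ``gene_id``.  Raw count > 0 and normalized value > 0 are equivalent."""
    if gene_id not in adata.var_names:
        raise ScoringError(f"gene {gene_id!r} absent from gene universe")
    sub = adata if cells is None else adata[cells]
    if sub.n_obs == 0:
        raise ScoringError("empty cell subset")
    col = sub[:, gene_id].X
    n_pos = int((col > 0).sum())
    return n_pos / sub.n_obs
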