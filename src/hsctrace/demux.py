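"""Donor/recipient origin calls from sex-chromosome gene scores.

In a sex-mismatched transplant the residual recipient cells separate from
the donor background in the (Chr-Y score, Chr-X score) plane.  Because no
numeric thresholds exist for the qualitative "low Y, high X" gate, the gate
is calibrated on sex-matched control samples: for detecting female recipient
cells on a male-donor background, ``tau_y`` is an extreme low quantile of
the male-control Y score and ``tau_x`` an extreme high quantile of the
male-control X score (defaults 0.1% / 99.9%).  The mirrored rule (high Y,
low X, female controls) detects male recipients of female grafts.

Recipient calls inside graft samples are impossible by construction (the
graft is donor material) and are flagged as false positives; they are
excluded from the residual-cell composition but always counted, so
``recipient_total = residual_total + false_positive_total`` holds exactly.
Cells meeting exactly one of the two score conditions are called
``ambiguous`` and counted as donor in compositions (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hsctrace")


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreGate:
    """Calibrated 2-D thresholds for one recipient sex.

    For ``recipient_sex == "F"`` a recipient call requires
    ``chr_y_score <= tau_y`` and ``chr_x_score >= tau_x``; for
    ``recipient_sex == "M"`` it requires ``chr_y_score >= tau_y`` and
    ``chr_x_score <= tau_x``.
    """

    recipient_sex: str
    tau_y: float
    tau_x: float
    q_y: float
    q_x: float
    n_control: int
    control_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_y) and np.isfinite(self.tau_x)):
            raise DemuxError("gate thresholds must be finite")

    def recipient_mask(self, scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(both-conditions mask, exactly-one-condition mask)."""
        y = scores["chr_y_score"].to_numpy()
        x = scores["chr_x_score"].to_numpy()
        if self.recipient_sex == "F":
            cond_y, cond_x = y <= self.tau_y, x >= self.tau_x
        else:
            cond_y, cond_x = y >= self.tau_y, x <= self.tau_x
        return cond_y & cond_x, cond_y ^ cond_x

    def to_dict(self) -> dict:
        return {
            "recipient_sex": self.recipient_sex,
            "tau_y": self.tau_y,
            "tau_x": self.tau_x,
            "q_y": self.q_y,
            "q_x": self.q_x,
            "n_control": self.n_control,
            "control_samples": list(self.control_samples),
        }


def calibrate_gate(
    scores: pd.DataFrame,
    control_cells,
    q_y: float = 0.001,
    q_x: float = 0.999,
    recipient_sex: str = "F",
    min_control: int = 100,
    control_samples: tuple[str, ...] = (),
) -> ScoreGate:
    """Calibrate a gate from sex-matched control cells.

    ``q_y``/``q_x`` are the quantiles used for female-recipient detection on
    a male background (low-Y / high-X).  For ``recipient_sex == "M"`` the
    quantiles are mirrored internally (``1 - q``) so that the same defaults
    describe equally extreme tails of the female-control distribution.
    """
    if recipient_sex not in ("M", "F"):
        raise DemuxError(f"recipient_sex must be 'M' or 'F', got {recipient_sex!r}")
    ctrl = scores.loc[control_cells]
    if len(ctrl) < min_control:
        raise DemuxError(
            f"too few control cells for calibration: {len(ctrl)} < {min_control}"
        )
    qy, qx = (q_y, q_x) if recipient_sex == "F" else (1.0 - q_y, 1.0 - q_x)
    tau_y = float(np.quantile(ctrl["chr_y_score"].to_numpy(), qy))
    tau_x = float(np.quantile(ctrl["chr_x_score"].to_numpy(), qx))
    return ScoreGate(
        recipient_sex=recipient_sex,
        tau_y=tau_y,
        tau_x=tau_x,
        q_y=q_y,
        q_x=q_x,
        n_control=len(ctrl),
        control_samples=tuple(control_samples),
    )


def sex_matched_control_cells(cell_meta: pd.DataFrame, design: pd.DataFrame, sex: str = "M"):
    """Cells from samples whose donor and recipient share genetic sex ``sex``
    — the negative control population for gate calibration."""
    matched = design[(design["donor_sex"] == sex) & (design["recipient_sex"] == sex)]
    samples = set(matched["sample_id"])
    return cell_meta.index[cell_meta["sample_id"].isin(samples)]


def call_origin(
    scores: pd.DataFrame,
    gates: dict[str, ScoreGate] | ScoreGate,
    design: pd.DataFrame,
    cell_meta: pd.DataFrame,
    graft_timepoint: str = "Graft",
) -> pd.DataFrame:
    """Per-cell origin calls (donor / recipient / ambiguous).

    Sex-matched samples are undecidable: every cell is called donor and
    flagged.  Graft-sample recipient calls carry ``false_positive=True``.
    """
    if isinstance(gates, ScoreGate):
        gates = {gates.recipient_sex: gates}
    for col in ("donor_sex", "recipient_sex"):
        if col not in design.columns or design[col].isna().any():
            raise DemuxError(f"sample design lacks populated {col!r}")
    meta = cell_meta.loc[scores.index]
    sample_info = design.set_index("sample_id")
    calls = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy(),
            "call": "donor",
            "is_graft_sample": (meta["timepoint"].astype(str) == graft_timepoint).to_numpy(),
            "false_positive": False,
            "undecidable": False,
        },
        index=scores.index,
    )
    for sample, sub in meta.groupby("sample_id", sort=False, observed=True):
        row = sample_info.loc[sample]
        idx = sub.index
        if row["donor_sex"] == row["recipient_sex"]:
            calls.loc[idx, "undecidable"] = True
            continue
        recipient_sex = row["recipient_sex"]
        if recipient_sex not in gates:
            raise DemuxError(
                f"no gate calibrated for recipient sex {recipient_sex!r} (sample {sample})"
            )
        both, one = gates[recipient_sex].recipient_mask(scores.loc[idx])
        calls.loc[idx[both], "call"] = "recipient"
        calls.loc[idx[one], "call"] = "ambiguous"
    fp = (calls["call"] == "recipient") & calls["is_graft_sample"]
    calls.loc[fp, "false_positive"] = True
    n_fp = int(fp.sum())
    if n_fp:
        logger.info("call_origin: %d graft-derived recipient calls flagged false-positive", n_fp)
    return calls


def residual_composition(calls: pd.DataFrame, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of residual recipient cells per
    (sample, lineage, subtype).  Graft false positives are excluded;
    proportions are within-sample fractions of residual cells."""
    residual = calls[(calls["call"] == "recipient") & ~calls["false_positive"]]
    if residual.empty:
        return pd.DataFrame(
            columns=["sample_id", "lineage", "subtype", "n_cells", "proportion"]
        )
    meta = cell_meta.loc[residual.index]
    comp = (
        meta.groupby(["sample_id", "lineage", "subtype"], sort=True, observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = comp.groupby("sample_id", observed=True)["n_cells"].transform("sum")
    comp["proportion"] = comp["n_cells"] / totals
    return comp


def score_calls(calls: pd.DataFrame, cell_meta: pd.DataFrame, design: pd.DataFrame) -> dict:
    """Precision/recall of recipient calls against simulation truth,
    evaluated over sex-mismatched post-transplant samples (the only samples
    where recipient cells are identifiable)."""
    info = design.set_index("sample_id")
    mismatched = set(info.index[info["donor_sex"] != info["recipient_sex"]])
    meta = cell_meta.loc[calls.index]
    scope = meta["sample_id"].isin(mismatched).to_numpy() & ~calls["is_graft_sample"].to_numpy()
    truth = (meta["origin_truth"] == "recipient").to_numpy()[scope]
    pred = (calls["call"] == "recipient").to_numpy()[scope]
    tp = int((truth & pred).sum())
    fp = int((~truth & pred).sum())
    fn = int((truth & ~pred).sum())
    return {
        "n_cells": int(scope.sum()),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }
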