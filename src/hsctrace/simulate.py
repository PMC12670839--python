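"""Synthetic chimeric longitudinal cohorts with full ground truth.

The generator emulates the statistical structure of a sex-mismatched
allo-HSCT single-cell study: a multi-patient cohort sampled at the graft
product and two follow-up timepoints; donor- versus recipient-origin cells
under all four donor/recipient sex combinations; Y-linked and XIST/TSIX
expression tied to the genetic sex of each cell's individual of origin
(with dropout arising naturally from low negative-binomial means); clonal
TCR repertoires whose graft clones persist into follow-up samples with a
configurable probability for T cells and never for B cells; an MDGA1
positivity shift in aGvHD patients; and a depressed ADGRG1 cytotoxicity
program in relapsing patients.

Counts are negative binomial with gene-level base means, a global dispersion
and a log-normal per-cell library-size factor.  Everything is deterministic
under a fixed seed, and the emitted truth tables are sufficient to score
every downstream call (origin demultiplexing, clone persistence, screen
hits) without re-deriving them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .dataio import ChainRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Y-chromosome-linked genes expressed only by genetically male cells.
Y_GENES = (
    "UTY", "DDX3Y", "USP9Y", "RPS4Y1", "RPS4Y2", "EIF1AY", "KDM5D", "PRY",
    "PRY2", "DAZ1", "DAZ2", "DAZ4", "ZFY", "AMELY", "TBL1Y", "PCDH11Y",
)

#: X-inactivation transcripts with near-zero expression in male cells.
X_GENES = ("XIST", "TSIX")

#: The 20-gene cytotoxicity program anchored on ADGRG1 (GPR56).
ADGRG1_PROGRAM = (
    "ADGRG1", "GZMB", "FGFBP2", "CX3CR1", "GZMH", "EFHD2", "GNLY", "NKG7",
    "SPON2", "CLIC3", "PRF1", "FCGR3A", "ZEB2", "KLRD1", "TRGC2", "S1PR5",
    "CST7", "SSBP3", "TTC38", "PLEK",
)

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3",
    "MT-ATP6", "MT-ATP8", "MT-CYB", "MT-ND4", "MT-ND5",
)

LYMPHOID_LINEAGES = frozenset({"T", "gdT", "NK", "B"})
CYTOTOXIC_SUBTYPES = frozenset({"CD8 Tmem", "CD8 Temra", "gdT Vd1", "gdT Vd2", "NK CD56dim"})

#: Receptor locus simulated per lineage (alpha/beta T cells -> TRB,
#: gamma/delta T cells -> TRD, B cells -> IGH).
LINEAGE_LOCUS = {"T": "TRB", "gdT": "TRD", "B": "IGH"}

_CDR3_AFFIX = {"TRB": ("CASS", "F"), "TRD": ("CACD", "F"), "IGH": ("CAR", "W")}


class SimulationConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class PatientSpec:
    """Donor/recipient sexes and clinical groups of one simulated patient."""

    patient_id: str
    donor_sex: str
    recipient_sex: str
    agvhd_grade: str = "0-I"   # "0-I" or "II-IV"
    remission: str = "CR"      # "CR" or "REL"


def default_patients() -> tuple[PatientSpec, ...]:
    """Ten-patient cohort mirroring the study design: five female recipients
    of male grafts, four male-to-male pairs, one female-to-female pair;
    five patients with aGvHD grade II-IV and two who later relapse."""
    return (
        PatientSpec("P01", "M", "F", "II-IV", "CR"),
        PatientSpec("P02", "M", "F", "II-IV", "CR"),
        PatientSpec("P03", "M", "F", "0-I", "CR"),
        PatientSpec("P04", "M", "F", "0-I", "REL"),
        PatientSpec("P05", "M", "F", "II-IV", "CR"),
        PatientSpec("P06", "M", "M", "II-IV", "CR"),
        PatientSpec("P07", "M", "M", "0-I", "REL"),
        PatientSpec("P08", "M", "M", "0-I", "CR"),
        PatientSpec("P09", "M", "M", "II-IV", "CR"),
        PatientSpec("P10", "F", "F", "0-I", "CR"),
    )


def _default_lineage_props() -> dict[str, dict[str, float]]:
    return {
        "Graft": {"T": 0.35, "gdT": 0.05, "NK": 0.10, "B": 0.15, "Mono": 0.30, "DC": 0.05},
        "D30": {"T": 0.40, "gdT": 0.05, "NK": 0.25, "B": 0.02, "Mono": 0.23, "DC": 0.05},
        "D100": {"T": 0.45, "gdT": 0.05, "NK": 0.15, "B": 0.08, "Mono": 0.22, "DC": 0.05},
    }


def _default_subtype_props() -> dict[str, dict[str, float]]:
    return {
        "T": {
            "CD4 Tnv": 0.20, "CD4 Tmem": 0.25, "Treg": 0.10,
            "CD8 Tnv": 0.15, "CD8 Tmem": 0.20, "CD8 Temra": 0.10,
        },
        "gdT": {"gdT Vd2": 0.60, "gdT Vd1": 0.40},
        "NK": {"NK CD56dim": 0.70, "NK CD56bright": 0.30},
        "B": {"B naive": 0.70, "B memory": 0.30},
        "Mono": {"Mono CD14": 0.80, "Mono CD16": 0.20},
        "DC": {"cDC": 0.70, "pDC": 0.30},
    }


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    Sex-gene effect sizes are per-gene negative-binomial means in the
    expressing sex (zero for Y-linked genes in female cells; ``x_leak_mean``
    models the near-zero XIST/TSIX background of male cells).
    ``sex_effect_scale`` multiplies all of them at once, which is how the
    large-effect regime is expressed.  Group effects are multiplicative on
    gene means and apply to post-transplant samples only — the graft product
    is donor material and carries no recipient clinical-group effect.
    """

    patients: tuple[PatientSpec, ...] = field(default_factory=default_patients)
    timepoints: tuple[str, ...] = ("Graft", "D30", "D100")
    cells_per_sample: int = 1000
    recipient_fraction: float = 0.05
    lineage_props: dict[str, dict[str, float]] = field(default_factory=_default_lineage_props)
    subtype_props: dict[str, dict[str, float]] = field(default_factory=_default_subtype_props)
    #: e.g. {"II-IV": {"Treg": 0.5}} halves the Treg weight in post-transplant
    #: samples of aGvHD patients (weights renormalized within the lineage).
    group_subtype_multiplier: dict[str, dict[str, float]] = field(default_factory=dict)

    n_background_genes: int = 2000
    background_logmean: float = 0.0
    background_logsd: float = 1.2
    dispersion: float = 10.0
    libsize_sigma: float = 0.35
    mito_gene_mean: float = 20.0

    y_gene_mean: float = 1.5
    xist_mean: float = 4.0
    tsix_mean: float = 1.0
    x_leak_mean: float = 0.0005
    sex_effect_scale: float = 1.0

    mdga1_base_mean: float = 0.05
    mdga1_agvhd_multiplier: float = 2.0
    adgrg1_base_mean: float = 0.15
    adgrg1_cytotoxic_multiplier: float = 4.0
    adgrg1_rel_multiplier: float = 0.4

    chain_rate: float = 0.7
    nonproductive_rate: float = 0.03
    mean_clone_size: float = 3.0
    clone_alpha: float = 1.0
    t_persistence: float = 0.6
    # B-cell (IGH) clone persistence is structurally zero and not configurable.

    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.recipient_fraction <= 1.0:
            raise SimulationConfigError(
                f"recipient_fraction must be in [0, 1], got {self.recipient_fraction}"
            )
        if self.dispersion <= 0:
            raise SimulationConfigError("dispersion must be > 0")
        if not 0.0 <= self.t_persistence <= 1.0:
            raise SimulationConfigError("t_persistence must be in [0, 1]")
        if not 0.0 <= self.chain_rate <= 1.0:
            raise SimulationConfigError("chain_rate must be in [0, 1]")
        for tp, props in self.lineage_props.items():
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise SimulationConfigError(f"lineage proportions for {tp!r} do not sum to 1")
        for lin, props in self.subtype_props.items():
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise SimulationConfigError(f"subtype proportions for {lin!r} do not sum to 1")
        for p in self.patients:
            if p.donor_sex not in ("M", "F") or p.recipient_sex not in ("M", "F"):
                raise SimulationConfigError(f"invalid sexes for patient {p.patient_id}")


@dataclass
class SimResult:
    """Simulated cohort: count matrix, sample design, receptor chains and
    ground-truth tables (``cells`` and ``clones``)."""

    matrix: AnnData
    design: pd.DataFrame
    chains: list[ChainRecord]
    truth: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# gene universe and counts
# ---------------------------------------------------------------------------

def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names, chrom, mito, base = [], [], [], []

    def add(gene: str, chromosome: str, is_mito: bool, mean: float) -> None:
        names.append(gene)
        chrom.append(chromosome)
        mito.append(is_mito)
        base.append(mean)

    for g in Y_GENES:
        add(g, "Y", False, 0.0)          # set per cell from origin sex
    for g in X_GENES:
        add(g, "X", False, 0.0)
    add("MDGA1", "6", False, cfg.mdga1_base_mean)
    for g in ADGRG1_PROGRAM:
        add(g, "A", False, cfg.adgrg1_base_mean)
    for g in MITO_GENES:
        add(g, "MT", True, cfg.mito_gene_mean)
    bg_means = rng.lognormal(cfg.background_logmean, cfg.background_logsd, cfg.n_background_genes)
    for i, m in enumerate(bg_means):
        add(f"BG{i + 1:04d}", "1", False, float(m))
    return pd.DataFrame({"chromosome": chrom, "mito": mito, "base_mean": base}, index=names)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Vectorized NB(mean=mu, dispersion=r); mu=0 yields exact zeros."""
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int32)


def _sample_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, chunk: int = 8192
) -> sp.csr_matrix:
    """Draw a cells x genes NB count matrix in row chunks to bound memory."""
    blocks = []
    for start in range(0, mu.shape[0], chunk):
        blocks.append(sp.csr_matrix(_nb_draw(rng, mu[start:start + chunk], dispersion)))
    return sp.vstack(blocks, format="csr")


def _random_cdr3(rng: np.random.Generator, locus: str, seen: set[str]) -> str:
    prefix, suffix = _CDR3_AFFIX[locus]
    while True:
        n = int(rng.integers(6, 11))
        core = "".join(_AA[i] for i in rng.integers(0, len(_AA), n))
        cdr3 = prefix + core + suffix
        if cdr3 not in seen:
            seen.add(cdr3)
            return cdr3


def _clone_sizes(rng: np.random.Generator, n_cells: int, mean_size: float, alpha: float) -> np.ndarray:
    """Partition ``n_cells`` into clones with rank-power-law relative
    abundances (weight of clone i proportional to i**-alpha)."""
    n_clones = max(1, int(round(n_cells / mean_size)))
    w = np.arange(1, n_clones + 1, dtype=float) ** (-alpha)
    sizes = rng.multinomial(n_cells, w / w.sum())
    return sizes[sizes > 0]  # only observed clones exist


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate one longitudinal chimeric cohort under ``cfg``.

    Ground truth emitted per cell: true origin (donor/recipient), the origin
    individual's genetic sex, lineage and subtype.  Ground truth per clone:
    locus, CDR3, sample, size and whether it persisted from the patient's
    graft repertoire.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg, rng)
    gene_idx = {g: i for i, g in enumerate(genes.index)}
    y_idx = [gene_idx[g] for g in Y_GENES]
    xist_i, tsix_i = gene_idx["XIST"], gene_idx["TSIX"]
    mdga1_i = gene_idx["MDGA1"]
    prog_idx = [gene_idx[g] for g in ADGRG1_PROGRAM]

    obs_rows: list[dict] = []
    design_rows: list[dict] = []
    chains: list[ChainRecord] = []
    clone_truth_rows: list[dict] = []
    mu_blocks: list[np.ndarray] = []
    scale = cfg.sex_effect_scale

    # per-patient graft repertoires for persistence draws
    graft_clones: dict[tuple[str, str], list[str]] = {}
    seen_cdr3: set[str] = set()

    for patient in cfg.patients:
        for timepoint in cfg.timepoints:
            sample_id = f"{patient.patient_id}_{timepoint}"
            is_graft = timepoint == cfg.timepoints[0]
            n = cfg.cells_per_sample
            design_rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": patient.patient_id,
                    "timepoint": timepoint,
                    "donor_sex": patient.donor_sex,
                    "recipient_sex": patient.recipient_sex,
                    "agvhd_grade": patient.agvhd_grade,
                    "remission": patient.remission,
                }
            )

            # --- cell-level truth ----------------------------------------
            if is_graft:
                origin = np.full(n, "donor", dtype=object)
            else:
                origin = np.where(
                    rng.random(n) < cfg.recipient_fraction, "recipient", "donor"
                ).astype(object)
            origin_sex = np.where(origin == "donor", patient.donor_sex, patient.recipient_sex)

            lin_props = cfg.lineage_props[timepoint]
            lineages = list(lin_props)
            lin_draw = rng.choice(len(lineages), size=n, p=list(lin_props.values()))
            lineage = np.array(lineages, dtype=object)[lin_draw]

            subtype = np.empty(n, dtype=object)
            group_mult: dict[str, float] = {}
            if not is_graft:
                for key in (patient.agvhd_grade, patient.remission):
                    group_mult.update(cfg.group_subtype_multiplier.get(key, {}))
            for lin in lineages:
                mask = lineage == lin
                if not mask.any():
                    continue
                props = dict(cfg.subtype_props[lin])
                for st in props:
                    props[st] *= group_mult.get(st, 1.0)
                total = sum(props.values())
                names = list(props)
                p = np.array([props[s] / total for s in names])
                subtype[mask] = np.array(names, dtype=object)[
                    rng.choice(len(names), size=int(mask.sum()), p=p)
                ]

            # --- expression means ----------------------------------------
            lib = rng.lognormal(0.0, cfg.libsize_sigma, n)
            mu = np.tile(genes["base_mean"].to_numpy(np.float64), (n, 1))
            male = origin_sex == "M"
            female = ~male
            mu[np.ix_(male, y_idx)] = cfg.y_gene_mean * scale
            mu[female[:, None] & np.isin(np.arange(mu.shape[1]), y_idx)[None, :]] = 0.0
            mu[female, xist_i] = cfg.xist_mean * scale
            mu[female, tsix_i] = cfg.tsix_mean * scale
            mu[male, xist_i] = cfg.x_leak_mean
            mu[male, tsix_i] = cfg.x_leak_mean
            lymphoid = np.isin(lineage, list(LYMPHOID_LINEAGES))
            mu[~lymphoid, mdga1_i] = 0.0
            if not is_graft and patient.agvhd_grade == "II-IV":
                mu[lymphoid, mdga1_i] *= cfg.mdga1_agvhd_multiplier
            cytotox = np.isin(subtype, list(CYTOTOXIC_SUBTYPES))
            mu[np.ix_(cytotox, prog_idx)] *= cfg.adgrg1_cytotoxic_multiplier
            if not is_graft and patient.remission == "REL":
                mu[np.ix_(lymphoid, prog_idx)] *= cfg.adgrg1_rel_multiplier
            mu *= lib[:, None]
            mu_blocks.append(mu.astype(np.float32))

            cell_ids = [f"{sample_id}:C{i + 1:05d}" for i in range(n)]
            for i in range(n):
                obs_rows.append(
                    {
                        "cell_id": cell_ids[i],
                        "sample_id": sample_id,
                        "patient_id": patient.patient_id,
                        "timepoint": timepoint,
                        "lineage": lineage[i],
                        "subtype": subtype[i],
                        "origin_truth": origin[i],
                        "origin_sex_truth": origin_sex[i],
                    }
                )

            # --- receptor chains -----------------------------------------
            for lin, locus in LINEAGE_LOCUS.items():
                members = [i for i in range(n) if lineage[i] == lin and rng.random() < cfg.chain_rate]
                if not members:
                    continue
                sizes = _clone_sizes(rng, len(members), cfg.mean_clone_size, cfg.clone_alpha)
                persistence = cfg.t_persistence if locus in ("TRB", "TRD") else 0.0
                key = (patient.patient_id, locus)
                pool = [] if is_graft else list(graft_clones.get(key, []))
                cdr3s: list[str] = []
                for _ in range(len(sizes)):
                    persisted = (not is_graft) and pool and rng.random() < persistence
                    if persisted:
                        cdr3 = pool.pop(int(rng.integers(len(pool))))
                    else:
                        cdr3 = _random_cdr3(rng, locus, seen_cdr3)
                    cdr3s.append(cdr3)
                    clone_truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "patient_id": patient.patient_id,
                            "timepoint": timepoint,
                            "locus": locus,
                            "cdr3_aa": cdr3,
                            "size": 0,  # filled below
                            "persisted_from_graft": bool(persisted),
                        }
                    )
                if is_graft:
                    graft_clones[key] = list(cdr3s)
                assignment = np.repeat(np.arange(len(sizes)), sizes)
                for cell_pos, clone_i in zip(members, assignment):
                    clone_truth_rows[-len(sizes) + clone_i]["size"] += 1
                    chains.append(
                        ChainRecord(
                            cell_id=cell_ids[cell_pos],
                            locus=locus,
                            cdr3_aa=cdr3s[clone_i],
                            v_call=f"{locus}V1-1",
                            j_call=f"{locus}J1-1",
                            productive=True,
                        )
                    )
                    if rng.random() < cfg.nonproductive_rate:
                        chains.append(
                            ChainRecord(
                                cell_id=cell_ids[cell_pos],
                                locus=locus,
                                cdr3_aa="CA*_" + cdr3s[clone_i][4:],
                                v_call=f"{locus}V2-1",
                                j_call=f"{locus}J1-1",
                                productive=False,
                            )
                        )

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    mu_all = np.vstack(mu_blocks)
    X = _sample_counts(rng, mu_all, cfg.dispersion)
    adata = AnnData(X=X, obs=obs, var=genes.drop(columns="base_mean"))
    adata.uns["simulation"] = {"seed": cfg.seed, "dispersion": cfg.dispersion}
    design = pd.DataFrame(design_rows)
    clone_truth = pd.DataFrame(clone_truth_rows)
    clone_truth = clone_truth[clone_truth["size"] > 0].reset_index(drop=True)
    truth = {
        "cells": obs.reset_index()[
            ["cell_id", "sample_id", "origin_truth", "origin_sex_truth", "lineage", "subtype"]
        ],
        "clones": clone_truth,
    }
    return SimResult(matrix=adata, design=design, chains=chains, truth=truth)


# ---------------------------------------------------------------------------
# cytokine panel simulation
# ---------------------------------------------------------------------------

@dataclass
class PanelConfig:
    """Conditions of the cytokine stimulation panel (PBMC screen).

    One sample per (donor, condition); each donor's baseline MDGA1 mean is
    drawn once (log-normal donor effect) and shared between that donor's
    baseline and treated samples, so paired within-donor contrasts are
    exact.  ``multipliers`` maps cytokine label to the factor applied to the
    donor's MDGA1 mean (default 1.0 = null).
    """

    cytokines: tuple[str, ...] = tuple(f"CYT{i:03d}" for i in range(1, 91))
    baseline_label: str = "PBS"
    multipliers: dict[str, float] = field(default_factory=dict)
    n_donors: int = 12
    cell_classes: tuple[str, ...] = ("CD4 T", "CD8 T", "NK")
    cells_per_class: int = 2000
    mdga1_base_mean: float = 0.05
    donor_logsd: float = 0.2
    n_background_genes: int = 11
    background_logmean: float = -0.7
    background_logsd: float = 1.0
    dispersion: float = 10.0
    libsize_sigma: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_label in self.cytokines:
            raise SimulationConfigError("baseline label must not appear among cytokines")
        if not self.cytokines:
            raise SimulationConfigError("at least one cytokine is required")
        unknown = set(self.multipliers) - set(self.cytokines)
        if unknown:
            raise SimulationConfigError(f"multipliers for unknown cytokines: {sorted(unknown)}")


def simulate_cytokine_panel(cfg: PanelConfig) -> dict:
    """Simulate the cytokine panel; returns ``{"matrix", "design"}``.

    The matrix carries MDGA1 plus a small background panel — enough to
    exercise normalization and positive-fraction calls at screen scale.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    conditions = (cfg.baseline_label,) + tuple(cfg.cytokines)
    donors = [f"D{i + 1:02d}" for i in range(cfg.n_donors)]
    donor_mu = {
        d: cfg.mdga1_base_mean * rng.lognormal(0.0, cfg.donor_logsd) for d in donors
    }
    bg_means = rng.lognormal(cfg.background_logmean, cfg.background_logsd, cfg.n_background_genes)
    gene_names = ["MDGA1"] + [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]

    per_class = cfg.cells_per_class
    cells_per_sample = per_class * len(cfg.cell_classes)
    n_cond = len(conditions)
    n_samples = len(donors) * n_cond
    n_cells = n_samples * cells_per_sample

    # integer codes throughout: the panel can reach 10^7 cells
    donor_codes = np.repeat(np.arange(len(donors), dtype=np.int32), n_cond * cells_per_sample)
    cond_codes = np.tile(
        np.repeat(np.arange(n_cond, dtype=np.int32), cells_per_sample), len(donors)
    )
    class_codes = np.tile(
        np.repeat(np.arange(len(cfg.cell_classes), dtype=np.int32), per_class), n_samples
    )
    sample_codes = donor_codes * n_cond + cond_codes
    sample_names = [f"{d}_{c}" for d in donors for c in conditions]

    lib = rng.lognormal(0.0, cfg.libsize_sigma, n_cells)
    mult_by_cond = np.array([cfg.multipliers.get(c, 1.0) for c in conditions])
    base_by_donor = np.array([donor_mu[d] for d in donors])
    mu_mdga1 = base_by_donor[donor_codes] * mult_by_cond[cond_codes] * lib

    cols = [sp.csc_matrix(_nb_draw(rng, mu_mdga1, cfg.dispersion)[:, None])]
    del mu_mdga1
    for m in bg_means:
        cols.append(sp.csc_matrix(_nb_draw(rng, m * lib, cfg.dispersion)[:, None]))
    del lib
    X = sp.hstack(cols, format="csr")
    del cols

    obs = pd.DataFrame(
        {
            "sample_id": pd.Categorical.from_codes(sample_codes, sample_names),
            "donor": pd.Categorical.from_codes(donor_codes, donors),
            "condition": pd.Categorical.from_codes(cond_codes, list(conditions)),
            "cell_class": pd.Categorical.from_codes(class_codes, list(cfg.cell_classes)),
        }
    )
    var = pd.DataFrame(
        {"chromosome": ["6"] + ["1"] * cfg.n_background_genes,
         "mito": [False] * len(gene_names)},
        index=gene_names,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anndata's str-index conversion notice
        adata = AnnData(X=X, obs=obs, var=var)
    design = pd.DataFrame(
        {
            "sample_id": sample_names,
            "donor": [d for d in donors for _ in conditions],
            "condition": [c for _ in donors for c in conditions],
        }
    )
    design["patient_id"] = design["donor"]
    design["timepoint"] = "stim24h"
    return {"matrix": adata, "design": design}


def screen_replicate(multiplier: float = 1.0, seed: int = 0, **panel_kwargs) -> "pd.DataFrame":
    """One independent screen replication: simulate a single-cytokine panel
    (its own donors and baselines) and run the paired positivity screen.

    Used to measure the screen's operating characteristics — type-I error
    under ``multiplier=1`` and detection power under a planted induction —
    by repeating with different seeds; replicates are then statistically
    independent, which a single shared-baseline panel is not.
    """
    from .stats import cytokine_screen, positive_fraction_table

    cfg = PanelConfig(
        cytokines=("CYT001",), multipliers={"CYT001": multiplier}, seed=seed, **panel_kwargs
    )
    panel = simulate_cytokine_panel(cfg)
    fractions = positive_fraction_table(panel["matrix"], "MDGA1")
    return cytokine_screen(fractions)


def config_from_dict(section: dict, cls=SimConfig, path: str = "simulate"):
    """Build a config dataclass from a plain mapping, naming unknown keys."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise SimulationConfigError(f"{path}.{sorted(unknown)[0]}: unknown configuration key")
    kwargs = dict(section)
    if cls is SimConfig and "patients" in kwargs:
        kwargs["patients"] = tuple(
            PatientSpec(**p) if isinstance(p, dict) else p for p in kwargs["patients"]
        )
    return cls(**kwargs)
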