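"""Biochemical normalisation for collagen structure-function studies.

Hydroxyproline-to-collagen conversion (300 hydroxyproline residues and
300 kDa per triple helix), cross-link densities per mole of collagen and the
standard immature/mature and DHLNL/HLNL ratios, sequential-extraction
solubility fractions, and delta-delta-Ct relative gene expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

#: molar mass of free hydroxyproline (g/mol), matching assay standards
M_HYP_G_PER_MOL = 131.13
#: hydroxyproline residues per collagen triple helix
HYP_PER_HELIX = 300.0
#: molecular weight of one triple helix (g/mol)
M_COLLAGEN_G_PER_MOL = 300_000.0


def collagen_from_hydroxyproline(
    hyp_mass_ug: float, m_hyp: float = M_HYP_G_PER_MOL
) -> dict:
    """Convert a hydroxyproline mass (ug) to collagen moles and mass (ug).

    mol_hyp = mass / M_hyp; mol_collagen = mol_hyp / 300;
    mass_collagen = mol_collagen x 300 kDa.  Linear in the input.
    """
    if hyp_mass_ug < 0:
        raise ParameterError("hydroxyproline mass must be non-negative")
    mol_hyp = hyp_mass_ug * 1e-6 / m_hyp
    mol_collagen = mol_hyp / HYP_PER_HELIX
    mass_collagen_ug = mol_collagen * M_COLLAGEN_G_PER_MOL * 1e6
    return {"collagen_mol": mol_collagen, "collagen_mass_ug": mass_collagen_ug}


@dataclass
class CrosslinkPanel:
    """Cross-link amounts (mol) plus collagen (mol) for one sample.

    DHLNL/HLNL are the immature divalent, PYD/DPD the mature trivalent
    hydroxyallysine-derived cross-links.
    """

    dhlnl_mol: float
    hlnl_mol: float
    pyd_mol: float
    dpd_mol: float
    collagen_mol: float

    def __post_init__(self):
        for name in ("dhlnl_mol", "hlnl_mol", "pyd_mol", "dpd_mol", "collagen_mol"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def crosslink_densities(panel: CrosslinkPanel) -> dict:
    """Cross-link densities per mole of collagen, totals and ratios.

    Immature = DHLNL + HLNL; mature = PYD + DPD.  Ratios with a zero
    denominator are returned as NaN and listed under ``undefined``.
    """
    if panel.collagen_mol <= 0:
        raise ParameterError("collagen amount must be positive")
    c = panel.collagen_mol
    dens = {
        "dhlnl_per_collagen": panel.dhlnl_mol / c,
        "hlnl_per_collagen": panel.hlnl_mol / c,
        "pyd_per_collagen": panel.pyd_mol / c,
        "dpd_per_collagen": panel.dpd_mol / c,
    }
    immature = dens["dhlnl_per_collagen"] + dens["hlnl_per_collagen"]
    mature = dens["pyd_per_collagen"] + dens["dpd_per_collagen"]
    undefined = []
    if mature > 0:
        imm_mat = immature / mature
    else:
        imm_mat = math.nan
        undefined.append("immature_to_mature")
    if dens["hlnl_per_collagen"] > 0:
        dh_hl = dens["dhlnl_per_collagen"] / dens["hlnl_per_collagen"]
    else:
        dh_hl = math.nan
        undefined.append("dhlnl_to_hlnl")
    return {
        **dens,
        "immature_per_collagen": immature,
        "mature_per_collagen": mature,
        "immature_to_mature": imm_mat,
        "dhlnl_to_hlnl": dh_hl,
        "undefined": undefined,
    }


@dataclass
class SolubilitySeries:
    """Hydroxyproline recovered per sequential-extraction fraction."""

    tbs: float
    acetic_acid: float
    pepsin: float
    insoluble: float

    def __post_init__(self):
        for name in ("tbs", "acetic_acid", "pepsin", "insoluble"):
            if getattr(self, name) < 0:
                raise ValidationError(f"fraction {name} must be non-negative")


def solubility_fractions(series: SolubilitySeries) -> dict:
    """Percentage of total collagen in each solubility fraction (sums to 100)."""
    values = {
        "tbs": series.tbs,
        "acetic_acid": series.acetic_acid,
        "pepsin": series.pepsin,
        "insoluble": series.insoluble,
    }
    total = sum(values.values())
    if total <= 0:
        raise ParameterError("at least one fraction must be positive")
    return {k: 100.0 * v / total for k, v in values.items()}


@dataclass
class CtTable:
    """qPCR Ct values in long format with housekeeping and baseline metadata.

    ``data`` needs columns (gene, sample, ct); ``groups`` maps sample ->
    group label.  The baseline is either a named sample or a group whose mean
    delta-Ct per gene anchors the delta-delta-Ct.
    """

    data: pd.DataFrame
    housekeeping: tuple
    baseline_sample: str | None = None
    baseline_group: str | None = None
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"gene", "sample", "ct"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"CtTable needs columns {sorted(required)}")
        if not self.housekeeping:
            raise ValidationError("housekeeping gene set must be non-empty")
        if not np.all(np.isfinite(self.data["ct"])):
            raise ValidationError("Ct values must be finite")
        if self.baseline_sample is None and self.baseline_group is None:
            raise ValidationError("a baseline sample or group must be designated")


def ddct_expression(table: CtTable) -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per gene and sample, plus group summaries.

    dCt = Ct_gene - mean(Ct_housekeeping) within each sample (the arithmetic
    mean of Ct values, equivalent to a geometric mean on the expression
    scale); ddCt subtracts the baseline dCt per gene (the designated sample's,
    or the baseline group's mean).  Returns a long table with columns
    (gene, sample, group, dct, ddct, expression).  Use
    :func:`expression_group_geometric_means` for the per-group geometric
    means the study plots.
    """
    df = table.data
    hk = set(table.housekeeping)
    samples = df["sample"].unique()
    hk_mean = {}
    for s in samples:
        sub = df[(df["sample"] == s) & (df["gene"].isin(hk))]
        present = set(sub["gene"])
        if present != hk:
            missing = sorted(hk - present)
            raise ValidationError(
                f"sample {s!r} is missing housekeeping gene(s) {missing}"
            )
        hk_mean[s] = float(sub["ct"].mean())

    targets = df[~df["gene"].isin(hk)].copy()
    targets["dct"] = targets["ct"] - targets["sample"].map(hk_mean)
    targets["group"] = targets["sample"].map(table.groups).fillna("")

    baseline_dct = {}
    for gene, sub in targets.groupby("gene"):
        if table.baseline_sample is not None:
            base = sub[sub["sample"] == table.baseline_sample]
            if base.empty:
                raise ValidationError(
                    f"baseline sample {table.baseline_sample!r} lacks gene {gene!r}"
                )
            baseline_dct[gene] = float(base["dct"].mean())
        else:
            base = sub[sub["group"] == table.baseline_group]
            if base.empty:
                raise ValidationError(
                    f"baseline group {table.baseline_group!r} has no data for {gene!r}"
                )
            baseline_dct[gene] = float(base["dct"].mean())

    targets["ddct"] = targets["dct"] - targets["gene"].map(baseline_dct)
    targets["expression"] = 2.0 ** (-targets["ddct"])
    return targets[["gene", "sample", "group", "dct", "ddct", "expression"]].reset_index(
        drop=True
    )


def expression_group_geometric_means(expression: pd.DataFrame) -> pd.DataFrame:
    """Geometric mean expression per gene per group (over 2^(-ddCt) values)."""
    out = (
        expression.groupby(["gene", "group"])["expression"]
        .apply(lambda x: float(np.exp(np.mean(np.log(x)))))
        .rename("geometric_mean")
        .reset_index()
    )
    return out
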