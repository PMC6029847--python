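"""Collagen biochemistry: hydroxyproline conversion, cross-link densities,
solubility fractions and ddCt gene expression.
"""

import pandas as pd

from fibromech import (
    CrosslinkPanel,
    collagen_from_hydroxyproline,
    crosslink_densities,
    ddct_expression,
    solubility_fractions,
)
from fibromech.biochem import CtTable, SolubilitySeries

out = collagen_from_hydroxyproline(1.0)
print(f"1 ug hydroxyproline -> {out['collagen_mass_ug']:.2f} ug collagen "
      f"({out['collagen_mol']:.3g} mol; 300 residues / 300 kDa per triple helix)")

panel = CrosslinkPanel(dhlnl_mol=2e-9, hlnl_mol=1e-9, pyd_mol=1e-9, dpd_mol=5e-10,
                       collagen_mol=1e-9)
dens = crosslink_densities(panel)
print(f"immature (DHLNL+HLNL) per collagen : {dens['immature_per_collagen']:.2f}")
print(f"mature (PYD+DPD) per collagen      : {dens['mature_per_collagen']:.2f}")
print(f"immature/mature ratio              : {dens['immature_to_mature']:.2f}")

frac = solubility_fractions(SolubilitySeries(tbs=12.0, acetic_acid=7.0, pepsin=55.0, insoluble=14.0))
print("solubility fractions (%):", {k: round(v, 1) for k, v in frac.items()})
print("  (a small insoluble fraction means the cross-linked network was digestible)")

rows = [
    {"gene": "UBC", "sample": s, "ct": ct}
    for s, ct in (("ctrl", 20.0), ("ipf", 20.2))
] + [
    {"gene": "LOXL2", "sample": "ctrl", "ct": 26.0},
    {"gene": "LOXL2", "sample": "ipf", "ct": 24.0},
]
table = CtTable(pd.DataFrame(rows), housekeeping=("UBC",), baseline_sample="ctrl",
                groups={"ctrl": "control", "ipf": "case"})
expr = ddct_expression(table)
fold = expr.loc[expr["sample"] == "ipf", "expression"].iloc[0]
print(f"LOXL2 relative expression in the case sample: {fold:.2f}x the control (2^-ddCt)")
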