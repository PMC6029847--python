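"""End-to-end study orchestration on synthetic or user-supplied cohorts.

``run_cohort_analysis`` reproduces the human-cohort design: per-donor tissue
stiffness and biochemistry, two-group comparisons, and the missing-data
multivariate correlation between stiffness, collagen concentration and
cross-link densities.  ``run_invitro_analysis`` reproduces the intervention
design: enzyme-inhibition IC50 fits plus a dose-indexed repeated-measures
comparison of spheroid Young's modulus against vehicle.

Reports are tidy TSV tables plus a JSON manifest carrying inputs, seeds and
package version; with a fixed seed the emitted tables are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .stats import (
    CorrelationResult,
    MultiGroupResult,
    TestResult,
    correlation_matrix,
    fit_dose_response,
    multigroup_tests,
    pairwise_tests,
)
from .synth import CohortSpec, CohortTable, SynthProtocol, synth_cohort, synth_dose_response

_FLOAT_FMT = "%.6g"

#: cohort variables compared between groups: (column, test method, log?)
_COHORT_TESTS = [
    ("stiffness_kpa", "welch_t", True),
    ("collagen_ug_per_mg", "student_t", False),
    ("immature_per_collagen", "mann_whitney", False),
    ("mature_per_collagen", "mann_whitney", False),
    ("fibril_diameter_nm", "mann_whitney", False),
    ("swelling_ratio", "welch_t", True),
]

#: variables entering the multivariate correlation (log10 where marked)
_CORR_VARS = [
    ("stiffness_kpa", True),
    ("collagen_ug_per_mg", False),
    ("immature_per_collagen", True),
    ("mature_per_collagen", True),
]


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Either ``cohort_path`` (a donor table on disk) or ``cohort_spec`` (a
    synthetic cohort specification; requires ``seed``) feeds the cohort
    analysis.  ``out_dir`` enables report writing; in-memory bundles are
    returned either way.
    """

    seed: int = 0
    out_dir: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    cohort_path: str | Path | None = None
    alpha: float = 0.05
    # in vitro design
    doses_um: tuple = (0.0, 0.01, 0.1, 1.0, 10.0)
    n_donors: int = 3
    n_replicates: int = 2
    e_vehicle_kpa: float = 5.0
    effect_at_max: float = 0.5
    ed50_um: float = 0.5
    replicate_sd_log: float = 0.10
    donor_sd_log: float = 0.15
    ic50s_um: dict = field(default_factory=lambda: {"LOXL2": 0.005, "LOXL3": 0.016})
    control_label: str = "vehicle"


@dataclass
class CohortReport:
    donor_table: pd.DataFrame
    group_tests: list[TestResult]
    correlation: CorrelationResult
    key_pair: tuple  # (r, p, n) for stiffness vs mature cross-links
    manifest: dict


@dataclass
class InvitroReport:
    dose_table: pd.DataFrame
    ic50_fits: dict
    rm_result: MultiGroupResult
    manifest: dict


def _tests_frame(tests: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": t.comparison[0] if len(t.comparison) == 3 else "",
                "comparison": " vs ".join(map(str, t.comparison[-2:])),
                "method": t.method,
                "statistic": t.statistic,
                "df": t.df if t.df is not None else math.nan,
                "p": t.p,
                "p_adjusted": t.p_adjusted,
            }
            for t in tests
        ]
    )


def _corr_frames(corr: CorrelationResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    square = pd.DataFrame(corr.r, index=corr.variables, columns=corr.variables)
    rows = []
    for i, a in enumerate(corr.variables):
        for j in range(i + 1, len(corr.variables)):
            b = corr.variables[j]
            rows.append(
                {
                    "var_a": a,
                    "var_b": b,
                    "r": corr.r[i, j],
                    "p": corr.p[i, j],
                    "n_eff": corr.n_eff[i, j],
                }
            )
    return square, pd.DataFrame(rows)


def _write_report(out_dir, manifest: dict, tables: dict):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_cohort_analysis(config: StudyConfig) -> CohortReport:
    """Cohort study: group comparisons plus the stiffness-cross-link correlation."""
    if config.cohort_path is not None:
        from .io import read_table

        data = read_table(config.cohort_path)
        source = str(config.cohort_path)
    else:
        spec = config.cohort_spec or CohortSpec()
        cohort = synth_cohort(spec, SynthProtocol(seed=config.seed))
        data = cohort.data
        source = "synthetic"
    if len(data) == 0:
        raise ValidationError("cohort contains no donors")
    if "group" not in data.columns:
        raise ValidationError("cohort table needs a 'group' column")
    groups = data["group"].unique()
    if len(groups) != 2:
        raise ValidationError(f"cohort analysis expects 2 groups, found {len(groups)}")
    g0, g1 = sorted(groups)

    tests: list[TestResult] = []
    for column, method, log in _COHORT_TESTS:
        if column not in data.columns:
            continue
        a = data.loc[data["group"] == g0, column].dropna().to_numpy()
        b = data.loc[data["group"] == g1, column].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        t = pairwise_tests(a, b, method=method, log_transform=log, labels=(g0, g1))
        t.comparison = (column, g0, g1)
        tests.append(t)

    corr_input = pd.DataFrame(
        {
            name: np.log10(data[name]) if log else data[name]
            for name, log in _CORR_VARS
            if name in data.columns
        }
    )
    corr = correlation_matrix(corr_input, method="em_mvn")
    key = ("stiffness_kpa", "mature_per_collagen")
    if all(k in corr.variables for k in key):
        key_pair = corr.pair(*key)
    else:
        key_pair = (math.nan, math.nan, 0)

    manifest = {
        "analysis": "cohort",
        "seed": config.seed,
        "source": source,
        "n_donors": int(len(data)),
        "groups": {g0: int((data["group"] == g0).sum()), g1: int((data["group"] == g1).sum())},
        "stiffness_mature_r": key_pair[0],
        "stiffness_mature_p": key_pair[1],
        "significant": bool(key_pair[1] < config.alpha) if math.isfinite(key_pair[1]) else False,
        "version": __version__,
    }
    report = CohortReport(data, tests, corr, key_pair, manifest)
    if config.out_dir is not None:
        square, long = _corr_frames(corr)
        _write_report(
            config.out_dir,
            manifest,
            {
                "donor_table": data,
                "group_tests": _tests_frame(tests),
                "correlation_matrix": square.reset_index(names="variable"),
                "correlation_pairs": long,
            },
        )
    return report


def _simulate_invitro_moduli(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-donor, per-replicate spheroid moduli declining with inhibitor dose.

    The dose effect is a saturating (Emax-type) reduction scaled so the
    highest dose reaches ``effect_at_max``; donor and replicate variability
    are log-normal.
    """
    doses = np.asarray(config.doses_um, dtype=float)
    dmax = doses.max()
    sat_max = dmax / (dmax + config.ed50_um)
    rows = []
    for d_idx in range(config.n_donors):
        donor_factor = math.exp(rng.normal(0.0, config.donor_sd_log))
        for dose in doses:
            effect = config.effect_at_max * (dose / (dose + config.ed50_um)) / sat_max
            mean_e = config.e_vehicle_kpa * (1.0 - effect) * donor_factor
            for rep in range(config.n_replicates):
                e = mean_e * math.exp(rng.normal(0.0, config.replicate_sd_log))
                rows.append(
                    {
                        "donor": f"D{d_idx + 1}",
                        "dose_um": dose,
                        "condition": config.control_label if dose == 0 else f"{dose:g} uM",
                        "replicate": rep + 1,
                        "youngs_modulus_kpa": e,
                    }
                )
    return pd.DataFrame(rows)


def run_invitro_analysis(config: StudyConfig, modulus_table: pd.DataFrame | None = None) -> InvitroReport:
    """Intervention study: IC50 fits plus dose-dependent stiffness reduction.

    ``modulus_table`` (columns donor, condition, replicate,
    youngs_modulus_kpa) may be supplied; otherwise it is simulated from the
    config.  The repeated-measures ANOVA treats each donor as a matched block
    (replicates averaged) with Dunnett's post-test against the vehicle.
    """
    rng = np.random.default_rng(config.seed)
    ic50_fits = {}
    for i, (enzyme, ic50) in enumerate(sorted(config.ic50s_um.items())):
        table = synth_dose_response(
            ic50,
            hill=1.0,
            protocol=SynthProtocol(seed=config.seed * 1000 + i, noise_sd=2.0),
        )
        ic50_fits[enzyme] = fit_dose_response(
            table.data["dose_um"].to_numpy(), table.data["activity_pct"].to_numpy()
        )

    if modulus_table is None:
        modulus_table = _simulate_invitro_moduli(config, rng)
    required = {"donor", "condition", "youngs_modulus_kpa"}
    if not required.issubset(modulus_table.columns):
        raise ValidationError(f"modulus table needs columns {sorted(required)}")
    if config.control_label not in set(modulus_table["condition"]):
        raise ValidationError(
            f"control condition {config.control_label!r} missing from modulus table"
        )

    per_block = (
        modulus_table.groupby(["condition", "donor"])["youngs_modulus_kpa"]
        .mean()
        .reset_index()
    )
    conditions = list(dict.fromkeys(modulus_table["condition"]))
    donors = sorted(per_block["donor"].unique())
    groups = {}
    for cond in conditions:
        sub = per_block[per_block["condition"] == cond].set_index("donor")
        groups[cond] = np.log10(
            sub.loc[donors, "youngs_modulus_kpa"].to_numpy(dtype=float)
        )
    rm = multigroup_tests(groups, design="rm_anova_dunnett", control=config.control_label)

    manifest = {
        "analysis": "invitro",
        "seed": config.seed,
        "n_donors": len(donors),
        "conditions": conditions,
        "ic50_um": {k: v.ic50 for k, v in ic50_fits.items()},
        "rm_anova_p": rm.omnibus.p,
        "dunnett_p": {c.comparison[0]: c.p_adjusted for c in rm.comparisons},
        "version": __version__,
    }
    report = InvitroReport(modulus_table, ic50_fits, rm, manifest)
    if config.out_dir is not None:
        _write_report(
            config.out_dir,
            manifest,
            {
                "modulus_table": modulus_table,
                "rm_tests": _tests_frame([rm.omnibus, *rm.comparisons]),
                "ic50_fits": pd.DataFrame(
                    [
                        {"enzyme": k, "ic50_um": v.ic50, "hill": v.hill,
                         "top": v.top, "bottom": v.bottom}
                        for k, v in sorted(ic50_fits.items())
                    ]
                ),
            },
        )
    return report
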