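"""Statistical layer for the cohort and intervention analyses.

Two-group tests (Welch/Student t, exact or tie-corrected Mann-Whitney,
one-sample t), step-down Holm-Sidak adjustment, multi-group designs (one-way
ANOVA with Dunnett's post-test, repeated-measures ANOVA with Dunnett,
Kruskal-Wallis with Dunn), correlation matrices tolerating missing data via
an EM-estimated multivariate-normal covariance, and four-parameter-logistic
dose-response (IC50) fitting.

The missing-data correlation is the likelihood-based analogue of the
REML-handling used by common statistics packages: the multivariate-normal
mean and covariance are estimated by EM over missing-at-random cells and the
correlations are read off the converged covariance.  For covariance-only
estimation at these sample sizes the ML/REML distinction is negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    FitError,
    InsufficientDataError,
    NoFitError,
    ParameterError,
    ValidationError,
)


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | None
    p: float
    p_adjusted: float
    comparison: tuple
    n: tuple
    flags: list[str] = field(default_factory=list)


@dataclass
class MultiGroupResult:
    omnibus: TestResult
    comparisons: list[TestResult]


@dataclass
class CorrelationResult:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray
    n_eff: np.ndarray
    method: str
    converged: bool = True
    n_iter: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)

    def pair(self, a: str, b: str) -> tuple[float, float, int]:
        """(r, p, effective n) for one variable pair."""
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j]), float(self.p[i, j]), int(self.n_eff[i, j])


@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    residual_norm: float
    converged: bool


# --------------------------------------------------------------------------
# pairwise tests
# --------------------------------------------------------------------------

def _maybe_log(x, log_transform):
    x = np.asarray(x, dtype=float)
    if log_transform:
        if np.any(x <= 0):
            raise ParameterError("log transform requires strictly positive values")
        return np.log10(x)
    return x


def pairwise_tests(
    x,
    y,
    method: str = "welch_t",
    log_transform: bool = False,
    labels: tuple = ("group1", "group2"),
) -> TestResult:
    """Two-sided two-group (or one-sample) test.

    ``method`` is one of welch_t, student_t, mann_whitney, one_sample_t (for
    which ``y`` is the null mean).  ``log_transform`` applies a base-10 log
    first (test statistics are invariant to the base).  Mann-Whitney is exact
    for combined n <= 20 without ties, otherwise the normal approximation
    with mid-ranks and tie correction is used.
    """
    x = _maybe_log(x, log_transform)
    if method == "one_sample_t":
        if x.size < 2:
            raise InsufficientDataError("one-sample t needs n >= 2")
        popmean = math.log10(y) if log_transform else float(y)
        if np.ptp(x) == 0 and x[0] == popmean:
            stat, p = 0.0, 1.0
        else:
            res = sps.ttest_1samp(x, popmean)
            stat, p = float(res.statistic), float(res.pvalue)
        return TestResult(method, stat, float(x.size - 1), p, p, (labels[0], "null"), (x.size,))

    y = _maybe_log(y, log_transform)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    n = (int(x.size), int(y.size))

    if method in ("welch_t", "student_t"):
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            return TestResult(method, 0.0, float(sum(n) - 2), 1.0, 1.0, labels, n)
        res = sps.ttest_ind(x, y, equal_var=(method == "student_t"))
        df = float(res.df) if hasattr(res, "df") else float(sum(n) - 2)
        return TestResult(method, float(res.statistic), df, float(res.pvalue), float(res.pvalue), labels, n)

    if method == "mann_whitney":
        combined = np.concatenate([x, y])
        has_ties = np.unique(combined).size < combined.size
        if np.ptp(combined) == 0:
            return TestResult(method, n[0] * n[1] / 2.0, None, 1.0, 1.0, labels, n)
        mode = "exact" if (sum(n) <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        return TestResult(method, float(res.statistic), None, float(min(res.pvalue, 1.0)), float(min(res.pvalue, 1.0)), labels, n)

    raise ParameterError(f"unknown method {method!r}")


def adjust_holm_sidak(p_values) -> np.ndarray:
    """Step-down Sidak (Holm-Sidak) adjusted p-values, in the input order.

    Sorted p_(i) becomes 1 - (1 - p_(i))^(m-i+1) with running-maximum
    enforcement of monotonicity; never smaller than the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm-sidak")[1]


# --------------------------------------------------------------------------
# multi-group designs
# --------------------------------------------------------------------------

_DUNNETT_MC_DRAWS = 100_000
_DUNNETT_MC_SEED = 20181703  # fixed: post-hoc adjustment must be deterministic


def _rm_anova_cells(matrix: np.ndarray):
    """Two-way (blocks x conditions) cell-mean decomposition for RM-ANOVA."""
    n, k = matrix.shape
    grand = matrix.mean()
    row = matrix.mean(axis=1, keepdims=True)
    col = matrix.mean(axis=0, keepdims=True)
    resid = matrix - row - col + grand
    ss_cond = n * float(((col - grand) ** 2).sum())
    ss_res = float((resid**2).sum())
    df_cond = k - 1
    df_res = (k - 1) * (n - 1)
    return ss_cond, df_cond, ss_res, df_res


def _dunnett_maxt_pvalues(t_stats: np.ndarray, df: int) -> np.ndarray:
    """Two-sided family-wise p-values for contrasts vs a shared control.

    Uses the max-|T| distribution of equicorrelated (rho = 1/2) t statistics
    sharing one variance estimate, evaluated by seeded Monte Carlo.
    """
    m = t_stats.size
    rng = np.random.default_rng(_DUNNETT_MC_SEED)
    z0 = rng.standard_normal(_DUNNETT_MC_DRAWS)
    z = rng.standard_normal((_DUNNETT_MC_DRAWS, m))
    w = np.sqrt(rng.chisquare(df, _DUNNETT_MC_DRAWS) / df)
    tmax = np.max(np.abs((z + z0[:, None]) / math.sqrt(2.0)), axis=1) / w
    return np.array([float(np.mean(tmax >= abs(t))) for t in t_stats])


def multigroup_tests(
    groups: dict,
    design: str = "anova_dunnett",
    control: str | None = None,
) -> MultiGroupResult:
    """Omnibus test plus per-comparison-vs-control adjusted p-values.

    designs: ``anova_dunnett`` (independent one-way ANOVA, Dunnett post-test),
    ``rm_anova_dunnett`` (repeated measures over complete blocks; contrasts
    use the RM error mean square with sphericity assumed), ``kruskal_dunn``
    (Kruskal-Wallis omnibus, Dunn's rank z-tests with Bonferroni adjustment
    across the vs-control family).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    names = list(groups.keys())
    if control is None:
        control = names[0]
    if control not in groups:
        raise ValidationError(f"control group {control!r} not among groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    others = [k for k in names if k != control]

    if design == "anova_dunnett":
        values = list(data.values())
        if all(np.ptp(v) == 0 for v in values) and np.ptp(
            [v[0] for v in values]
        ) == 0:
            omnibus = TestResult(
                "anova", math.nan, None, math.nan, math.nan, tuple(names),
                tuple(v.size for v in values), flags=["zero_variance"],
            )
            comps = [
                TestResult("dunnett", 0.0, None, 1.0, 1.0, (k, control),
                           (data[k].size, data[control].size))
                for k in others
            ]
            return MultiGroupResult(omnibus, comps)
        f, p = sps.f_oneway(*values)
        omnibus = TestResult(
            "anova", float(f), float(len(values) - 1), float(p), float(p),
            tuple(names), tuple(v.size for v in values),
        )
        res = sps.dunnett(*[data[k] for k in others], control=data[control])
        df_err = float(sum(v.size for v in values) - len(values))
        if len(others) == 1:
            # one comparison: the max-|T| family collapses to a single pooled t
            pvals = 2 * sps.t.sf(np.abs(res.statistic), df_err)
        else:
            pvals = res.pvalue
        comps = [
            TestResult(
                "dunnett", float(res.statistic[i]), df_err, float(pvals[i]),
                float(pvals[i]), (k, control), (data[k].size, data[control].size),
            )
            for i, k in enumerate(others)
        ]
        return MultiGroupResult(omnibus, comps)

    if design == "rm_anova_dunnett":
        sizes = {k: v.size for k, v in data.items()}
        if len(set(sizes.values())) != 1:
            raise ValidationError("repeated-measures design requires complete blocks")
        matrix = np.column_stack([data[k] for k in names])
        if not np.all(np.isfinite(matrix)):
            raise ValidationError("missing cell in repeated-measures block")
        n, k = matrix.shape
        if n < 2:
            raise InsufficientDataError("repeated measures need >= 2 blocks")
        ss_cond, df_cond, ss_res, df_res = _rm_anova_cells(matrix)
        if ss_res == 0 and ss_cond == 0:
            omnibus = TestResult(
                "rm_anova", math.nan, None, math.nan, math.nan, tuple(names),
                (n,) * k, flags=["zero_variance"],
            )
            comps = [
                TestResult("dunnett_rm", 0.0, float(df_res), 1.0, 1.0, (g, control), (n, n))
                for g in others
            ]
            return MultiGroupResult(omnibus, comps)
        mse = ss_res / df_res
        f = (ss_cond / df_cond) / mse if mse > 0 else math.inf
        p = float(sps.f.sf(f, df_cond, df_res)) if math.isfinite(f) else 0.0
        omnibus = TestResult(
            "rm_anova", float(f), float(df_cond), p, p, tuple(names), (n,) * k
        )
        ci = names.index(control)
        means = matrix.mean(axis=0)
        t_stats = np.array(
            [(means[names.index(g)] - means[ci]) / math.sqrt(2 * mse / n) for g in others]
        )
        p_adj = _dunnett_maxt_pvalues(t_stats, df_res)
        p_raw = 2 * sps.t.sf(np.abs(t_stats), df_res)
        comps = [
            TestResult(
                "dunnett_rm", float(t_stats[i]), float(df_res), float(p_raw[i]),
                float(min(p_adj[i], 1.0)), (g, control), (n, n),
            )
            for i, g in enumerate(others)
        ]
        return MultiGroupResult(omnibus, comps)

    if design == "kruskal_dunn":
        values = list(data.values())
        if np.ptp(np.concatenate(values)) == 0:
            h, p = 0.0, 1.0  # all observations identical: no rank variation
        else:
            h, p = sps.kruskal(*values)
        omnibus = TestResult(
            "kruskal_wallis", float(h), float(len(values) - 1), float(p), float(p),
            tuple(names), tuple(v.size for v in values),
        )
        comps = _dunn_vs_control(data, names, control, others)
        return MultiGroupResult(omnibus, comps)

    raise ParameterError(f"unknown design {design!r}")


def _dunn_vs_control(data, names, control, others) -> list[TestResult]:
    """Dunn's z post-hoc vs control with Bonferroni adjustment and tie correction."""
    pooled = np.concatenate([data[k] for k in names])
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    mean_rank = {}
    pos = 0
    for k in names:
        sz = data[k].size
        mean_rank[k] = float(ranks[pos : pos + sz].mean())
        pos += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (big_n - 1)) if big_n > 1 else 0.0
    base_var = big_n * (big_n + 1) / 12.0 - tie_term
    m = len(others)
    comps = []
    for g in others:
        se2 = base_var * (1.0 / data[g].size + 1.0 / data[control].size)
        if se2 <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_rank[g] - mean_rank[control]) / math.sqrt(se2)
            p_raw = float(2 * sps.norm.sf(abs(z)))
        comps.append(
            TestResult(
                "dunn", float(z), None, p_raw, float(min(p_raw * m, 1.0)),
                (g, control), (data[g].size, data[control].size),
            )
        )
    return comps


# --------------------------------------------------------------------------
# correlation with missing data
# --------------------------------------------------------------------------

def _pd_floor(sigma: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh((sigma + sigma.T) / 2)
    vals = np.clip(vals, floor * max(vals.max(), 1.0), None)
    return (vecs * vals) @ vecs.T


def em_mvn_covariance(
    x: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """EM maximum-likelihood mean/covariance of a MVN with MCAR/MAR missing cells.

    Rows with no observed cell are dropped.  Returns (mu, sigma, loglik,
    converged, n_iter); convergence is |d loglik| < tol * (1 + |loglik|).
    Rows are processed grouped by missingness pattern, so the E-step is
    vectorised within each pattern.
    """
    x = np.asarray(x, dtype=float)
    n_all, p = x.shape
    obs = np.isfinite(x)
    keep = obs.any(axis=1)
    x, obs = x[keep], obs[keep]
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError("EM needs at least 3 partially observed rows")

    mu = np.nanmean(np.where(obs, x, np.nan), axis=0)
    sigma = pd.DataFrame(np.where(obs, x, np.nan)).cov(ddof=0).to_numpy()
    sigma = np.where(np.isfinite(sigma), sigma, 0.0)
    diag = np.diag(sigma).copy()
    diag[diag <= 0] = 1.0
    np.fill_diagonal(sigma, diag)
    sigma = _pd_floor(sigma)

    patterns = {}
    for i in range(n):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    pattern_rows = {k: np.array(v) for k, v in patterns.items()}

    loglik_prev = -math.inf
    converged = False
    it = 0
    loglik = loglik_prev
    for it in range(1, max_iter + 1):
        sx = np.zeros(p)
        sxx = np.zeros((p, p))
        loglik = 0.0
        for patt, rows in pattern_rows.items():
            o = np.array(patt)
            m = ~o
            xo = x[np.ix_(rows, np.flatnonzero(o))]
            soo = sigma[np.ix_(o, o)]
            # log-likelihood of the observed block
            sign, logdet = np.linalg.slogdet(soo)
            soo_inv = np.linalg.inv(soo)
            dev = xo - mu[o]
            quad = np.einsum("ij,jk,ik->i", dev, soo_inv, dev)
            loglik += float(
                -0.5 * (quad.sum() + len(rows) * (logdet + o.sum() * math.log(2 * math.pi)))
            )
            comp = np.repeat(mu[None, :], len(rows), axis=0)
            comp[:, o] = xo
            c_full = np.zeros((p, p))
            if m.any():
                som = sigma[np.ix_(o, m)]
                b = soo_inv @ som  # (p_o, p_m)
                comp[:, m] = mu[m] + dev @ b
                c_full[np.ix_(m, m)] = sigma[np.ix_(m, m)] - som.T @ b
            sx += comp.sum(axis=0)
            sxx += comp.T @ comp + len(rows) * c_full
        mu = sx / n
        sigma = sxx / n - np.outer(mu, mu)
        sigma = _pd_floor(sigma)
        if abs(loglik - loglik_prev) < tol * (1 + abs(loglik)):
            converged = True
            break
        loglik_prev = loglik
    return mu, sigma, loglik, converged, it


def _corr_p(r: float, n: int) -> float:
    if n <= 2 or not math.isfinite(r):
        return math.nan
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), n - 2))


def correlation_matrix(
    table,
    method: str = "em_mvn",
    variables: list[str] | None = None,
) -> CorrelationResult:
    """Correlation matrix of a cohort table with missing cells.

    ``table`` is a DataFrame (or an object with a ``data`` DataFrame); only
    numeric columns are used unless ``variables`` is given.  Methods:
    ``pearson`` and ``spearman`` are computed pairwise-complete; ``em_mvn``
    estimates the joint MVN covariance by EM over missing cells and reads the
    correlations off the converged covariance (it coincides with Pearson on
    complete data).  p-values use the t-approximation with the pairwise
    effective n (count of rows observed for both variables).
    """
    if hasattr(table, "data"):
        table = table.data
    df = table[variables] if variables is not None else table.select_dtypes("number")
    cols = []
    for c in df.columns:
        if df[c].notna().sum() < 3:
            warnings.warn(f"variable {c!r} has < 3 observed values; excluded", stacklevel=2)
        else:
            cols.append(c)
    if len(cols) < 2:
        raise ValidationError("need at least 2 usable variables")
    df = df[cols]
    x = df.to_numpy(dtype=float)
    n_var = len(cols)
    obs = np.isfinite(x)
    n_eff = obs.T.astype(int) @ obs.astype(int)

    r = np.eye(n_var)
    p = np.zeros((n_var, n_var))
    converged, n_iter = True, 0

    if method in ("pearson", "spearman"):
        fn = sps.pearsonr if method == "pearson" else sps.spearmanr
        for i in range(n_var):
            for j in range(i + 1, n_var):
                both = obs[:, i] & obs[:, j]
                if both.sum() < 3:
                    r[i, j] = r[j, i] = math.nan
                    p[i, j] = p[j, i] = math.nan
                    continue
                res = fn(x[both, i], x[both, j])
                r[i, j] = r[j, i] = float(res.statistic)
                p[i, j] = p[j, i] = float(res.pvalue)
    elif method == "em_mvn":
        _, sigma, _, converged, n_iter = em_mvn_covariance(x)
        d = np.sqrt(np.diag(sigma))
        r = sigma / np.outer(d, d)
        r = np.clip((r + r.T) / 2, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        for i in range(n_var):
            for j in range(i + 1, n_var):
                p[i, j] = p[j, i] = _corr_p(r[i, j], int(n_eff[i, j]))
    else:
        raise ParameterError(f"unknown correlation method {method!r}")

    return CorrelationResult(cols, r, p, n_eff, method, converged, n_iter)


# --------------------------------------------------------------------------
# dose-response
# --------------------------------------------------------------------------

def four_pl(dose, ic50, hill, top=100.0, bottom=0.0):
    """Four-parameter logistic inhibition curve on a linear dose axis."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_dose_response(doses, responses) -> DoseResponseFit:
    """Fit a 4PL inhibition curve on log-dose; returns IC50, hill, top, bottom.

    Requires >= 4 distinct positive dose levels spanning the transition.
    A flat response raises NoFitError.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValidationError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ParameterError("doses must be positive")
    if np.unique(doses).size < 4:
        raise InsufficientDataError("need >= 4 distinct dose levels")
    span = float(responses.max() - responses.min())
    if span < 1e-9 * max(1.0, float(np.abs(responses).max())):
        raise NoFitError("response is flat; no transition to fit")

    logd = np.log10(doses)

    def model(ld, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - log_ic50)))

    top0, bot0 = float(responses.max()), float(responses.min())
    mid = bot0 + span / 2
    order = np.argsort(logd)
    crossing = np.interp(-mid, -responses[order], logd[order])  # monotone decreasing
    p0 = [float(crossing), 1.0, top0, bot0]
    lo = [logd.min() - 3, 0.05, -np.inf, -np.inf]
    hi = [logd.max() + 3, 10.0, np.inf, np.inf]
    try:
        popt, _ = curve_fit(model, logd, responses, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit failed: {exc}") from exc
    resid = float(np.linalg.norm(responses - model(logd, *popt)))
    ic50 = float(10.0 ** popt[0])
    return DoseResponseFit(
        ic50=ic50,
        hill=float(popt[1]),
        top=float(popt[2]),
        bottom=float(popt[3]),
        residual_norm=resid,
        converged=bool(ic50 > 0 and np.isfinite(popt).all()),
    )
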