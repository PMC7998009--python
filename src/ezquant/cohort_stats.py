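"""Cohort statistics: visit summaries, t-tests, ANOVA, correlations, and
longitudinal AR(1) mixed models.

The longitudinal model regresses VALS change from baseline on categorical
visit (M01, M06, M12, M24), a contemporaneous EZ predictor (continuous
defect area or the categorical grade), and their interaction.  Residuals
within a participant follow an AR(1) covariance sigma^2 * rho^|i-j| over
ordered visit indices; estimation is maximum likelihood with rho profiled
out — at each candidate rho, generalized least squares on each
participant's observed-visit submatrix, then a bounded 1-D search over rho.
Intermittently missing visits are handled by subsetting the AR(1)
correlation matrix (valid because AR(1) marginals of a subset of visits are
just the corresponding entries); no imputation.

Percentages are reported to one decimal, rounded half-up, matching
clinical-report conventions.  The family-wise significance threshold after
Bonferroni correction is a fixed alpha of 0.002.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .oct_synth import FOLLOW_UP_VISITS
from .quantify_grade import MIN_DEFECT_AREA_MM2

__all__ = [
    "VisitSummary",
    "TTestResult",
    "AnovaResult",
    "CorrelationResult",
    "Ar1ModelFit",
    "round_percentage",
    "summarize_visits",
    "ttest_unpaired",
    "anova_oneway",
    "corr_binary_vs_outcome",
    "fit_ar1_longitudinal",
    "apply_bonferroni",
    "BONFERRONI_ALPHA",
]

#: family-wise corrected significance threshold (fixed constant)
BONFERRONI_ALPHA = 0.002


def round_percentage(count: int, denominator: int) -> float:
    """100*count/denominator rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VisitSummary:
    visit: str
    n_total: int
    n_ungradable: int
    pct_ungradable: float
    n_measured: int
    n_defect_present: int
    n_defect_absent: int
    pct_defect_present: float
    pct_defect_absent: float
    grade_counts: dict
    grade_percentages: dict
    mean_area_mm2: float
    sd_area_mm2: float


def summarize_visits(table: pd.DataFrame, visits=FOLLOW_UP_VISITS) -> list[VisitSummary]:
    """Per-visit counts and one-decimal percentages.

    Denominators are visit-specific: attended scans for gradability,
    measured (gradable) scans for defect presence, and graded scans for the
    three-step grade distribution.  Empty visits are omitted.
    """
    out = []
    for visit in visits:
        rows = table[(table["visit"] == visit) & table["vals_letters"].notna()]
        n_total = len(rows)
        if n_total == 0:
            continue
        n_ungradable = int((rows["gradable"] == False).sum())  # noqa: E712
        measured = rows[rows["defect_area_mm2"].notna()]
        n_measured = len(measured)
        present = measured["defect_area_mm2"] > MIN_DEFECT_AREA_MM2
        n_present = int(present.sum())
        n_absent = n_measured - n_present
        graded = rows[rows["grade"].isin(["normal", "patchy", "absent"])]
        counts = {
            g: int((graded["grade"] == g).sum()) for g in ("normal", "patchy", "absent")
        }
        n_graded = sum(counts.values())
        out.append(
            VisitSummary(
                visit=str(visit),
                n_total=n_total,
                n_ungradable=n_ungradable,
                pct_ungradable=round_percentage(n_ungradable, n_total),
                n_measured=n_measured,
                n_defect_present=n_present,
                n_defect_absent=n_absent,
                pct_defect_present=(
                    round_percentage(n_present, n_measured) if n_measured else float("nan")
                ),
                pct_defect_absent=(
                    round_percentage(n_absent, n_measured) if n_measured else float("nan")
                ),
                grade_counts=counts,
                grade_percentages={
                    g: round_percentage(c, n_graded) if n_graded else float("nan")
                    for g, c in counts.items()
                },
                mean_area_mm2=float(measured["defect_area_mm2"].mean()) if n_measured else float("nan"),
                sd_area_mm2=float(measured["defect_area_mm2"].std()) if n_measured > 1 else float("nan"),
            )
        )
    return out


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float


def ttest_unpaired(group_a, group_b, pooled: bool = False) -> TTestResult:
    """Unpaired two-tailed t-test (Welch by default; pooled optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) != np.mean(b):
        raise ValueError("degenerate groups with zero variance")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TTestResult(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=len(a),
        n_b=len(b),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


@dataclass(frozen=True)
class AnovaResult:
    group_n: dict
    group_mean: dict
    group_sd: dict
    f: float
    p: float


def anova_oneway(groups: dict) -> AnovaResult:
    """One-way ANOVA over labeled groups (e.g. defect area by EZ grade)."""
    cleaned = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) >= 2:
            cleaned[label] = v
    if len(cleaned) < 2:
        raise ValueError("need >= 2 groups with n >= 2 each")
    f, p = stats.f_oneway(*cleaned.values())
    return AnovaResult(
        group_n={k: len(v) for k, v in cleaned.items()},
        group_mean={k: float(v.mean()) for k, v in cleaned.items()},
        group_sd={k: float(v.std(ddof=1)) for k, v in cleaned.items()},
        f=float(f),
        p=float(p),
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def corr_binary_vs_outcome(status, outcome) -> CorrelationResult:
    """Point-biserial correlation (Pearson with 0/1 coding) and its p."""
    s = np.asarray(status, dtype=float)
    y = np.asarray(outcome, dtype=float)
    keep = ~np.isnan(s) & ~np.isnan(y)
    s, y = s[keep], y[keep]
    if len(s) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.unique(s).size < 2:
        raise ValueError("binary status has a single class")
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")
    r, p = stats.pearsonr(s, y)
    return CorrelationResult(r=float(r), n=len(s), p=float(p))


# ---------------------------------------------------------------------------
# AR(1) longitudinal model
# ---------------------------------------------------------------------------


@dataclass
class Ar1ModelFit:
    params: pd.Series
    se: pd.Series
    rho: float
    sigma: float
    loglik: float
    converged: bool
    n_participants: int
    n_obs: int
    predictor: str

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (
            float(self.params[name] - z * self.se[name]),
            float(self.params[name] + z * self.se[name]),
        )


def _design_matrix(rows: pd.DataFrame, predictor: str) -> tuple[np.ndarray, list[str]]:
    """Saturated visit x predictor design (cell-means parameterization):
    one intercept per visit plus one predictor effect per visit, so each
    coefficient reads directly as that visit's effect."""
    visits = list(FOLLOW_UP_VISITS)
    cols, names = [], []
    for v in visits:
        cols.append((rows["visit"] == v).to_numpy(float))
        names.append(f"visit[{v}]")
    if predictor == "area_continuous":
        area = rows["defect_area_mm2"].to_numpy(float)
        for v in visits:
            cols.append(((rows["visit"] == v).to_numpy(float)) * area)
            names.append(f"area:visit[{v}]")
    elif predictor == "grade_categorical":
        for level in ("patchy", "absent"):
            ind = (rows["grade"] == level).to_numpy(float)
            for v in visits:
                cols.append(((rows["visit"] == v).to_numpy(float)) * ind)
                names.append(f"grade[{level}]:visit[{v}]")
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    return np.column_stack(cols), names


def _gls_profile(
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]], rho: float, p: int
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """GLS at fixed rho.  ``groups`` holds (X_i, y_i, visit_idx_i) per
    participant.  Returns (beta, XtVinvX, sigma2_ml, loglik, rss)."""
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    logdet = 0.0
    n_obs = 0
    solves = []
    for X, y, tidx in groups:
        R = rho ** np.abs(tidx[:, None] - tidx[None, :])
        L = np.linalg.cholesky(R)
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        xtvx += Xw.T @ Xw
        xtvy += Xw.T @ yw
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        n_obs += len(y)
        solves.append((Xw, yw))
    beta = np.linalg.solve(xtvx, xtvy)
    rss = 0.0
    for Xw, yw in solves:
        resid = yw - Xw @ beta
        rss += float(resid @ resid)
    sigma2 = rss / n_obs
    loglik = -0.5 * (
        n_obs * math.log(2.0 * math.pi * sigma2) + logdet + n_obs
    )
    return beta, xtvx, sigma2, loglik, rss


def fit_ar1_longitudinal(
    table: pd.DataFrame,
    predictor: str = "area_continuous",
    response: str = "vals_change",
    fix_rho: float | None = None,
) -> Ar1ModelFit:
    """ML fit of the longitudinal visit x predictor model with AR(1) errors.

    Parameters
    ----------
    table
        Cohort table with follow-up rows carrying ``visit``, the response,
        and the predictor columns (``defect_area_mm2`` or ``grade``).
        Participants contribute every follow-up visit at which all three
        are observed; participants with none are excluded.
    predictor
        ``"area_continuous"`` or ``"grade_categorical"``.
    response
        Column regressed (VALS change from baseline by default).  When the
        table lacks a ``vals_change`` column it is derived from
        ``vals_letters`` minus the participant's BL value.
    fix_rho
        Fix the AR(1) correlation instead of profiling it (``fix_rho=0``
        reduces the fit to ordinary least squares).
    """
    df = table.copy()
    if response == "vals_change" and "vals_change" not in df.columns:
        bl = df[df["visit"] == "BL"].set_index("participant_id")["vals_letters"]
        df["vals_change"] = df["vals_letters"] - df["participant_id"].map(bl)
    rows = df[df["visit"].isin(FOLLOW_UP_VISITS)].copy()
    rows = rows[rows[response].notna()]
    if predictor == "area_continuous":
        rows = rows[rows["defect_area_mm2"].notna()]
    else:
        rows = rows[rows["grade"].isin(["normal", "patchy", "absent"])]
    if rows.empty:
        raise ValueError("no usable follow-up observations")

    X, names = _design_matrix(rows, predictor)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        deficient = [
            names[j]
            for j in range(X.shape[1])
            if np.allclose(X[:, j], 0) or np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"singular design; aliased columns: {deficient or names}")
    y = rows[response].to_numpy(float)
    visit_idx = rows["visit"].map({v: i for i, v in enumerate(FOLLOW_UP_VISITS)}).to_numpy(int)
    pid = rows["participant_id"].to_numpy()

    groups = []
    for _, idx in pd.Series(range(len(rows))).groupby(pid):
        sel = idx.to_numpy()
        groups.append((X[sel], y[sel], visit_idx[sel]))

    p = X.shape[1]
    converged = True
    if fix_rho is not None:
        rho_hat = float(fix_rho)
    else:
        def neg_profile(rho: float) -> float:
            return -_gls_profile(groups, rho, p)[3]

        res = optimize.minimize_scalar(
            neg_profile, bounds=(-0.95, 0.95), method="bounded",
            options={"xatol": 1e-4},
        )
        converged = bool(res.success)
        rho_hat = float(res.x)
    beta, xtvx, sigma2, loglik, _ = _gls_profile(groups, rho_hat, p)
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    return Ar1ModelFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        rho=rho_hat,
        sigma=float(math.sqrt(sigma2)),
        loglik=float(loglik),
        converged=converged,
        n_participants=len(groups),
        n_obs=len(y),
        predictor=predictor,
    )


def apply_bonferroni(pvalues, alpha_corrected: float = BONFERRONI_ALPHA) -> list[bool]:
    """Significance flags at the fixed corrected threshold (strict <)."""
    flags = []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        flags.append(p < alpha_corrected)
    return flags
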