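"""Cohort statistics: random-intercept mixed model, ICC, and planning rules.

The protrusion effect is estimated with the linear mixed model

    y_ij = beta0 + beta1 * p_ij + b_i + eps_ij,
    b_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma_e^2),

with protrusion p in mm as a continuous fixed covariate and a random
intercept per patient. Unbalanced data (missing scans) are used as-is —
no row deletion. Fitting profiles the criterion down to the variance
ratio lambda = sigma_b^2 / sigma_e^2: for fixed lambda the GLS solution
and sigma_e^2 are closed-form (Sherman-Morrison per patient block), so
REML/ML reduces to a 1-D minimization. Wald p-values use the normal
reference; the likelihood-ratio test of beta1 = 0 refits by ML against a
chi-square(1) reference.

Reliability uses the two-way mixed-effects, single-measurement,
consistency ICC computed from the ANOVA mean squares; values above 0.8
count as high consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "LmmResult",
    "IccResult",
    "GroupContrast",
    "fit_lmm",
    "lrt_protrusion",
    "icc_intra_rater",
    "threshold_rules",
    "flow_ratio",
    "group_contrast",
    "stopbang_category",
    "cohort_report",
]


@dataclass
class LmmResult:
    beta0: float
    beta1: float
    se_beta1: float
    sigma_b: float
    sigma_e: float
    p_value: float
    n_obs: int
    n_groups: int
    loglik: float
    method: str
    outcome: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta1 - 1.96 * self.se_beta1, self.beta1 + 1.96 * self.se_beta1)


class _Sufficient:
    """Per-group sufficient statistics for the profiled criterion.

    With V_g = I + lam * J (unit residual variance), Sherman-Morrison gives
    V_g^-1 = I - c_g * J with c_g = lam / (1 + lam * n_g), so every GLS
    quantity reduces to per-group sums of X and y.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        _, inv = np.unique(groups, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        starts = np.flatnonzero(np.diff(inv[order], prepend=-1))
        self.n, self.p = X.shape
        self.ng = np.diff(np.append(starts, self.n)).astype(float)
        self.sx = np.add.reduceat(X[order], starts, axis=0)  # (G, p)
        self.sy = np.add.reduceat(y[order], starts)  # (G,)
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)

    def pieces(self, lam: float):
        c = lam / (1.0 + lam * self.ng)
        xtvx = self.xtx - (self.sx.T * c) @ self.sx
        xtvy = self.xty - self.sx.T @ (c * self.sy)
        ytvy = self.yty - float(c @ (self.sy**2))
        logdet = float(np.sum(np.log1p(lam * self.ng)))
        return xtvx, xtvy, ytvy, logdet


def _criterion(lam, suff: _Sufficient, reml):
    xtvx, xtvy, ytvy, logdet = suff.pieces(lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = max(ytvy - beta @ xtvy, 0.0)
    df = suff.n - suff.p if reml else suff.n
    sigma2 = max(rss / df, 1e-300)
    crit = df * math.log(sigma2) + logdet
    if reml:
        crit += math.log(max(np.linalg.det(xtvx), 1e-300))
    return crit, beta, sigma2, xtvx


def _fit_random_intercept(y, X, groups, reml=True):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design: need variation in the covariate across scans")

    if np.ptp(y) == 0:  # constant outcome: zero slope and zero variances
        beta = np.zeros(p)
        beta[0] = y[0]
        return dict(beta=beta, sigma_e=0.0, sigma_b=0.0, lam=0.0,
                    cov_unscaled=np.linalg.inv(X.T @ X), sigma2=0.0, loglik=math.inf)

    # degenerate (noise-free) outcomes short-circuit the profiling
    beta_ols, _res, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
    scale = float(y @ y) if y.size else 1.0
    if rss_ols <= 1e-12 * max(scale, 1.0):
        xtx = X.T @ X
        return dict(beta=beta_ols, sigma_e=0.0, sigma_b=0.0, lam=0.0,
                    cov_unscaled=np.linalg.inv(xtx), sigma2=0.0,
                    loglik=math.inf)

    suff = _Sufficient(y, X, np.asarray(groups))
    grid = np.concatenate([[0.0], np.logspace(-4, 5, 28)])
    crits = [_criterion(l, suff, reml)[0] for l in grid]
    k = int(np.argmin(crits))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        opt = optimize.minimize_scalar(
            lambda l: _criterion(l, suff, reml)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(opt.x)
        if _criterion(grid[k], suff, reml)[0] < opt.fun:
            lam = float(grid[k])
    else:
        lam = float(grid[k])

    crit, beta, sigma2, xtvx = _criterion(lam, suff, reml)
    df = n - p if reml else n
    # exact log-likelihood for ML; for REML the same expression up to the
    # REML constant (only ML values are ever differenced, in the LRT)
    loglik = -0.5 * (crit + df * (1.0 + math.log(2.0 * math.pi)))
    return dict(beta=beta, sigma_e=math.sqrt(sigma2), sigma_b=math.sqrt(lam * sigma2),
                lam=lam, cov_unscaled=np.linalg.inv(xtvx), sigma2=sigma2,
                loglik=loglik)


def fit_lmm(
    table: pd.DataFrame,
    outcome: str,
    protrusion_col: str = "protrusion_mm",
    group_col: str = "patient_id",
    reml: bool = True,
) -> LmmResult:
    """Fit the random-intercept model of an outcome on protrusion (mm).

    Rows with a missing outcome are dropped (scans that were never made);
    patients with a single remaining scan still contribute. Requires at
    least two distinct protrusion levels overall.
    """
    data = table[[group_col, protrusion_col, outcome]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    pvals = data[protrusion_col].to_numpy(dtype=float)
    if np.unique(pvals).size < 2:
        raise ValueError("need at least two protrusion levels to estimate a slope")
    X = np.column_stack([np.ones_like(pvals), pvals])
    fit = _fit_random_intercept(y, X, data[group_col].to_numpy(), reml=reml)
    se = math.sqrt(max(fit["sigma2"] * fit["cov_unscaled"][1, 1], 0.0))
    beta1 = float(fit["beta"][1])
    if se > 0:
        p_value = float(2.0 * sps.norm.sf(abs(beta1) / se))
    else:
        p_value = 1.0 if beta1 == 0 else 0.0
    return LmmResult(
        beta0=float(fit["beta"][0]),
        beta1=beta1,
        se_beta1=se,
        sigma_b=float(fit["sigma_b"]),
        sigma_e=float(fit["sigma_e"]),
        p_value=p_value,
        n_obs=len(y),
        n_groups=int(data[group_col].nunique()),
        loglik=float(fit["loglik"]),
        method="reml" if reml else "ml",
        outcome=outcome,
    )


def lrt_protrusion(
    table: pd.DataFrame,
    outcome: str,
    protrusion_col: str = "protrusion_mm",
    group_col: str = "patient_id",
) -> tuple[float, float]:
    """Likelihood-ratio test of beta1 = 0 (ML fits, chi-square(1) reference)."""
    data = table[[group_col, protrusion_col, outcome]].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return 0.0, 1.0
    pvals = data[protrusion_col].to_numpy(dtype=float)
    groups = data[group_col].to_numpy()
    X_full = np.column_stack([np.ones_like(pvals), pvals])
    X_null = np.ones((len(y), 1))
    full = _fit_random_intercept(y, X_full, groups, reml=False)
    null = _fit_random_intercept(y, X_null, groups, reml=False)
    if not (np.isfinite(full["loglik"]) and np.isfinite(null["loglik"])):
        return math.inf, 0.0
    stat = max(0.0, 2.0 * (full["loglik"] - null["loglik"]))
    return float(stat), float(sps.chi2.sf(stat, 1))


@dataclass
class IccResult:
    icc: float
    n_subjects: int
    n_repeats: int
    ms_subjects: float
    ms_error: float

    @property
    def high_consistency(self) -> bool:
        """ICC above 0.8 counts as high consistency."""
        return self.icc > 0.8


def icc_intra_rater(measurements: np.ndarray) -> IccResult:
    """Two-way mixed-effects, single-measurement, consistency ICC — ICC(3,1).

    ``measurements`` is (n_subjects, n_repeats); the repeat (occasion)
    effect is removed as a fixed effect, so exact re-measurement gives 1.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a (subjects x repeats) array with >= 2 repeats")
    n, k = m.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for a stable ICC")
    grand = m.mean()
    subj = m.mean(axis=1)
    occ = m.mean(axis=0)
    ss_subj = k * np.sum((subj - grand) ** 2)
    ss_occ = n * np.sum((occ - grand) ** 2)
    ss_tot = np.sum((m - grand) ** 2)
    ss_err = max(ss_tot - ss_subj - ss_occ, 0.0)
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj == 0 and ms_err == 0:
        icc = 1.0
    else:
        icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    return IccResult(float(icc), n, k, float(ms_subj), float(ms_err))


def threshold_rules(
    table: pd.DataFrame,
    small_mm2: float = 52.0,
    target_mm2: float = 110.0,
    slope_mm2_per_mm: float = 24.9,
    outcome: str = "minCSA_mm2",
) -> dict:
    """Screening and planning rules on minCSA.

    Reports the fraction of scans below ``small_mm2`` at each protrusion
    level, and the protrusion each patient would need for the minCSA to
    reach ``target_mm2`` given the per-mm slope: max(0, (target - minCSA0)
    / slope).
    """
    if slope_mm2_per_mm <= 0:
        raise ValueError("slope must be positive")
    frac = {}
    counts = {}
    for p, sub in table.groupby("protrusion_mm"):
        vals = sub[outcome].dropna()
        counts[float(p)] = (int((vals < small_mm2).sum()), int(len(vals)))
        frac[float(p)] = float((vals < small_mm2).mean()) if len(vals) else float("nan")
    base = table[table["protrusion_mm"] == 0].dropna(subset=[outcome])
    required = {
        str(r["patient_id"]): max(0.0, (target_mm2 - float(r[outcome])) / slope_mm2_per_mm)
        for _, r in base.iterrows()
    }
    return {
        "small_mm2": small_mm2,
        "target_mm2": target_mm2,
        "fraction_below_small": frac,
        "counts_below_small": counts,
        "required_protrusion_mm": required,
    }


def flow_ratio(area_before_mm2: float, area_after_mm2: float) -> float:
    """Laminar (Hagen-Poiseuille) volumetric flow ratio at a fixed pressure
    gradient for circular cross-sections: resistance scales with 1/r^4, so
    flow scales with the square of the area."""
    if area_before_mm2 <= 0 or area_after_mm2 <= 0:
        raise ValueError("areas must be positive")
    return float((area_after_mm2 / area_before_mm2) ** 2)


@dataclass
class GroupContrast:
    covariate: str
    outcome: str
    protrusion_mm: float
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    difference: float
    t_stat: float
    p_value: float


def group_contrast(
    table: pd.DataFrame,
    covariate: str,
    outcome: str,
    protrusion_mm: float,
) -> GroupContrast:
    """Welch two-sample comparison of an outcome between two covariate
    groups at one protrusion level."""
    sub = table[table["protrusion_mm"] == protrusion_mm].dropna(subset=[outcome])
    levels = sorted(sub[covariate].unique(), key=str, reverse=True)
    if len(levels) != 2:
        raise ValueError(f"covariate {covariate!r} must have exactly two groups")
    a = sub.loc[sub[covariate] == levels[0], outcome].to_numpy(dtype=float)
    b = sub.loc[sub[covariate] == levels[1], outcome].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.array_equal(np.sort(a), np.sort(b)):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupContrast(
        covariate=covariate,
        outcome=outcome,
        protrusion_mm=float(protrusion_mm),
        group_a=str(levels[0]),
        group_b=str(levels[1]),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
        difference=float(a.mean() - b.mean()),
        t_stat=float(t),
        p_value=float(p),
    )


def stopbang_category(score: int) -> str:
    """OSA risk category from the 8-item STOP-BANG score:
    >= 5 high, 3-4 moderate, <= 2 low."""
    score = int(score)
    if not 0 <= score <= 8:
        raise ValueError("STOP-BANG score must be between 0 and 8")
    if score >= 5:
        return "high"
    if score >= 3:
        return "moderate"
    return "low"


_REPORT_OUTCOMES = (
    "minCSA_mm2",
    "meanCSA_overall_mm2",
    "meanCSA_naso_mm2",
    "meanCSA_oro_mm2",
    "meanCSA_hypo_mm2",
    "volume_total_cm3",
)


def cohort_report(table: pd.DataFrame, outcomes=_REPORT_OUTCOMES) -> dict:
    """Per-protrusion summaries, LMM slopes, LRTs, and group contrasts."""
    report: dict = {"group_means": {}, "slopes": {}, "contrasts": {}}
    for outcome in outcomes:
        if outcome not in table.columns:
            continue
        by_p = table.groupby("protrusion_mm")[outcome]
        report["group_means"][outcome] = {
            float(p): {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.count())}
            for p, v in by_p
        }
        res = fit_lmm(table, outcome)
        stat, p = lrt_protrusion(table, outcome)
        report["slopes"][outcome] = {
            "beta1_per_mm": res.beta1,
            "se": res.se_beta1,
            "sigma_b": res.sigma_b,
            "sigma_e": res.sigma_e,
            "wald_p": res.p_value,
            "lrt_stat": stat,
            "lrt_p": p,
            "n_obs": res.n_obs,
            "n_patients": res.n_groups,
        }
    for covariate in ("reconstruction", "radiotherapy"):
        if covariate not in table.columns:
            continue
        report["contrasts"][covariate] = {}
        for outcome in ("minCSA_mm2", "meanCSA_overall_mm2", "volume_total_cm3"):
            if outcome not in table.columns:
                continue
            per_level = {}
            for p in sorted(table["protrusion_mm"].unique()):
                try:
                    c = group_contrast(table, covariate, outcome, p)
                except ValueError:
                    continue
                per_level[float(p)] = {
                    "groups": [c.group_a, c.group_b],
                    "means": [c.mean_a, c.mean_b],
                    "sds": [c.sd_a, c.sd_b],
                    "ns": [c.n_a, c.n_b],
                    "p": c.p_value,
                }
            report["contrasts"][covariate][outcome] = per_level
    return report
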