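"""Statistical comparisons: intervention regression with/without the baseline
covariate, permutation inference, Pearson correlation, paired t-tests and the
mixed-effects repeated-immunisation comparison.

The intervention model is ordinary least squares,

    Y = b0 + b1 * X1 (+ b2 * X2),

with X1 the intervention indicator (control = 0, intervention = 1) and X2 the
per-subject baseline sensitivity. Permutation p-values use group-label
permutation for the covariate-free model and Freedman-Lane residual
permutation when the baseline covariate is a nuisance regressor, with the
never-zero convention p = (1 + #{|t*| >= |t|}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datagen import GROUP_INTERVENTION, as_rng

__all__ = [
    "RegressionResult", "MixedModelResult", "PairedTResult",
    "fit_intervention_model", "permutation_p", "pearson_perm",
    "fit_mixed_immunisation", "paired_t",
]


@dataclass
class RegressionResult:
    b0: float
    b1: float
    b2: float | None
    t_stats: dict
    p_param: float
    adjusted: bool
    n_obs: int
    p_perm: float | None = None
    n_perm: int | None = None

    @property
    def coef(self) -> dict:
        out = {"b0": self.b0, "b1": self.b1}
        if self.b2 is not None:
            out["b2"] = self.b2
        return out


def _design(cohort: pd.DataFrame, adjusted: bool):
    g = (cohort["group"] == GROUP_INTERVENTION).to_numpy(float)
    cols = {"const": np.ones(len(cohort)), "intervention": g}
    if adjusted:
        x = cohort["x"].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError("baseline covariate is constant: design is rank-deficient")
        cols["baseline"] = x
    y = cohort["y"].to_numpy(float)
    return pd.DataFrame(cols), y


def fit_intervention_model(cohort: pd.DataFrame,
                           adjusted: bool = True) -> RegressionResult:
    """OLS fit of the intervention model; two-sided t-test on b1.

    ``cohort`` needs columns ``y`` and ``group`` (plus ``x`` when
    ``adjusted``); subject-summary tables can be passed after renaming
    ``baseline_sensitivity``/``clinical_response`` to ``x``/``y``.
    """
    X, y = _design(cohort, adjusted)
    p = X.shape[1]
    if len(cohort) < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} coefficients")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        b0=float(fit.params["const"]),
        b1=float(fit.params["intervention"]),
        b2=float(fit.params["baseline"]) if adjusted else None,
        t_stats={k: float(v) for k, v in fit.tvalues.items()},
        p_param=float(fit.pvalues["intervention"]),
        adjusted=adjusted,
        n_obs=int(fit.nobs),
    )


def _ols_t_intervention(y: np.ndarray, g: np.ndarray,
                        x: np.ndarray | None) -> float:
    """Closed-form t-statistic for the intervention coefficient."""
    n = y.size
    if x is None:
        X = np.column_stack([np.ones(n), g])
    else:
        X = np.column_stack([np.ones(n), g, x])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - X.shape[1])
    return float(beta[1] / np.sqrt(s2 * xtx_inv[1, 1]))


def permutation_p(cohort: pd.DataFrame,
                  adjusted: bool = False,
                  n_perm: int = 10_000,
                  scheme: str | None = None,
                  seed=None,
                  enumerate_exact: bool | None = None) -> float:
    """Permutation p-value for the intervention coefficient.

    scheme "label_flip" permutes group labels (exact under the unadjusted
    null); "freedman_lane" permutes residuals of the nuisance-only model and
    is the default when the baseline covariate is present. With
    ``enumerate_exact`` (auto when the number of distinct relabelings does
    not exceed ``n_perm``, label_flip only) all relabelings are evaluated and
    p = #{|t*| >= |t|} / n_distinct, the identity included.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme is None:
        scheme = "freedman_lane" if adjusted else "label_flip"
    if scheme not in ("label_flip", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    rng = as_rng(seed)
    g = (cohort["group"] == GROUP_INTERVENTION).to_numpy(float)
    y = cohort["y"].to_numpy(float)
    x = cohort["x"].to_numpy(float) if adjusted else None
    t_obs = abs(_ols_t_intervention(y, g, x))
    n = y.size

    if scheme == "label_flip":
        n1 = int(g.sum())
        n_distinct = math.comb(n, n1)
        if enumerate_exact is None:
            enumerate_exact = n_distinct <= n_perm
        if enumerate_exact:
            count = 0
            for pos in itertools.combinations(range(n), n1):
                gp = np.zeros(n)
                gp[list(pos)] = 1.0
                if abs(_ols_t_intervention(y, gp, x)) >= t_obs - 1e-12:
                    count += 1
            return count / n_distinct
        exceed = 0
        for _ in range(n_perm):
            gp = rng.permutation(g)
            if abs(_ols_t_intervention(y, gp, x)) >= t_obs:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)

    # Freedman-Lane: permute residuals under the nuisance-only model
    Z = np.column_stack([np.ones(n), x]) if x is not None else np.ones((n, 1))
    gamma, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ gamma
    resid = y - fitted
    exceed = 0
    for _ in range(n_perm):
        y_star = fitted + rng.permutation(resid)
        if abs(_ols_t_intervention(y_star, g, x)) >= t_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def pearson_perm(x, y, n_perm: int = 10_000, seed=None) -> dict:
    """Pearson r with a permutation p-value (y permuted)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r = float(xc @ yc / denom)
    rng = as_rng(seed)
    # |r*| only needs the permuted numerator; denominator is invariant
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    r_null = perms @ xc / denom
    p = (1 + int((np.abs(r_null) >= abs(r) - 1e-15).sum())) / (1 + n_perm)
    return {"r": r, "R2": r * r, "p_perm": p}


@dataclass
class PairedTResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_t(before, after) -> PairedTResult:
    """Two-sided paired t-test with explicit zero-variance handling."""
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.size != after.size or before.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = after - before
    if np.ptp(d) == 0:
        if d[0] == 0:
            return PairedTResult(t=0.0, p=1.0, n=d.size, degenerate=True)
        sign = math.copysign(1.0, d[0])
        return PairedTResult(t=sign * math.inf, p=0.0, n=d.size, degenerate=True)
    t, p = stats.ttest_rel(after, before)
    return PairedTResult(t=float(t), p=float(p), n=d.size)


@dataclass
class MixedModelResult:
    fixed_effect: float
    t: float
    p: float
    random_sds: dict
    resid_sd: float
    n_obs: int
    n_subjects: int
    singular: bool
    converged: bool


def fit_mixed_immunisation(magnitudes: pd.DataFrame,
                           imm_coding: str = "random") -> MixedModelResult:
    """Group comparison of repeated immunisation responses.

    Linear mixed model with a fixed group effect and, by default, crossed
    random intercepts for subject and for immunisation index (1st/2nd/3rd
    injection on the test occasion), fitted by REML. ``imm_coding="fixed"``
    instead enters the immunisation index as a fixed covariate with a
    subject random intercept only.

    ``magnitudes`` columns: subject, group, immunisation_index, magnitude.
    """
    df = magnitudes.copy()
    counts = df.groupby("group")["subject"].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 subjects in each of two groups")
    df["g"] = (df["group"] == GROUP_INTERVENTION).astype(float)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if imm_coding == "random":
            model = sm.MixedLM.from_formula(
                "magnitude ~ g", groups=np.ones(len(df)),
                vc_formula={"subject": "0 + C(subject)",
                            "immunisation": "0 + C(immunisation_index)"},
                re_formula="0", data=df)
        elif imm_coding == "fixed":
            model = sm.MixedLM.from_formula(
                "magnitude ~ g + immunisation_index",
                groups=df["subject"], data=df)
        else:
            raise ValueError("imm_coding must be 'random' or 'fixed'")
        fit = model.fit(reml=True)
        singular = any("singular" in str(w.message).lower()
                       or "boundary" in str(w.message).lower() for w in caught)

    random_sds = {}
    if imm_coding == "random":
        for name, var in fit.vcomp_named.items() if hasattr(fit, "vcomp_named") \
                else zip(model.exog_vc.names, fit.vcomp):
            random_sds[name] = float(np.sqrt(max(var, 0.0)))
    else:
        random_sds["subject"] = float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0)))
    return MixedModelResult(
        fixed_effect=float(fit.params["g"]),
        t=float(fit.tvalues["g"]),
        p=float(fit.pvalues["g"]),
        random_sds=random_sds,
        resid_sd=float(np.sqrt(fit.scale)),
        n_obs=len(df),
        n_subjects=int(df["subject"].nunique()),
        singular=bool(singular),
        converged=bool(fit.converged),
    )
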