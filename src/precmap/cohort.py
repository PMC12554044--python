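"""Cohort-level trajectory statistics on connectivity-strength records.

Three analyses, each run independently per network on the tidy records table
(one row per session × network):

* ``fit_age_model`` — OLS of strength on scan age, sex, motion, preterm
  status and the prematurity × age interaction.  The age-at-scan p-value
  (p_SA) tests maturation; the preterm p-value (p_PB) tests a persistent
  offset; the interaction p-value tests whether preterm and term
  trajectories converge.
* ``group_comparison`` — adjusted two-sided test of the preterm/term
  difference at term-equivalent age (OLS of strength on group, sex, motion,
  scan age, restricted to a scan-age window).
* ``longitudinal_slope`` — two-scan-per-subject maturation rate: strength is
  first residualised on motion, then regressed on scan age; per-subject
  two-point slopes are returned alongside the group slope and its 95% CI.

Scan age is centered at 40 weeks postmenstrual age by default so the preterm
coefficient is the offset at term age rather than an extrapolation to age 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

DEFAULT_AGE_CENTER = 40.0
DEFAULT_TERM_EQUIVALENT_WINDOW = (37.0, 44.9)


@dataclass
class CohortFit:
    """Per-network OLS coefficient table and fit metadata."""

    network: str
    table: pd.DataFrame          # index: term; columns: estimate, se, tvalue, pvalue
    n_sessions: int
    df_resid: int
    cov_params: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "pvalue"])

    def estimate(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def recovery_contrast(self, term: str, true_relative_effect: float):
        """Test recovery of a multiplicative-generator effect.

        When the generator scales a baseline strength k by
        (1 + effect · x), the expected coefficient of x is k·effect and the
        expected intercept is k, so the contrast
        ``beta_term − effect·beta_intercept`` has mean zero under correct
        recovery.  Returns ``(contrast, se)`` using the OLS coefficient
        covariance.
        """
        if self.cov_params is None:
            raise ValueError("fit has no coefficient covariance")
        terms = list(self.table.index)
        c = np.zeros(len(terms))
        c[terms.index(term)] = 1.0
        c[terms.index("intercept")] = -true_relative_effect
        est = float(c @ self.table["estimate"].to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se


def _design(df: pd.DataFrame, terms: list, age_center: float) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for t in terms:
        if t == "scan_age":
            X["scan_age"] = df["scan_age"] - age_center
        elif t == "sex":
            X["sex"] = (df["sex"].astype(str) == "M").astype(float)
        elif t == "motion":
            X["motion"] = df["motion"].astype(float)
        elif t == "preterm":
            X["preterm"] = df["preterm"].astype(bool).astype(float)
        elif t == "preterm:scan_age":
            X["preterm:scan_age"] = (
                df["preterm"].astype(bool).astype(float)
                * (df["scan_age"] - age_center)
            )
        else:
            raise ValueError(f"unknown model term {t!r}")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy()
    if np.linalg.matrix_rank(A) < A.shape[1]:
        degenerate = [
            c for c in X.columns
            if c != "intercept" and X[c].nunique() <= 1
        ]
        raise ValueError(
            "collinear design matrix"
            + (f"; degenerate columns: {degenerate}" if degenerate else "")
        )


def _ols_fit(df: pd.DataFrame, terms: list, network: str,
             age_center: float) -> CohortFit:
    X = _design(df, terms, age_center)
    _check_full_rank(X)
    res = sm.OLS(df["strength"].astype(float), X).fit()
    table = pd.DataFrame({
        "estimate": res.params,
        "se": res.bse,
        "tvalue": res.tvalues,
        "pvalue": res.pvalues,
    })
    return CohortFit(
        network=network,
        table=table,
        n_sessions=len(df),
        df_resid=int(res.df_resid),
        cov_params=res.cov_params(),
    )


def _network_frame(records: pd.DataFrame, network: str) -> pd.DataFrame:
    df = records[records["network"] == network].copy()
    df = df.dropna(subset=["strength", "motion"])
    if df["session_id"].duplicated().any():
        dups = df.loc[df["session_id"].duplicated(), "session_id"].tolist()
        raise ValueError(f"duplicate session×network rows: {dups}")
    return df


def fit_age_model(
    records: pd.DataFrame,
    network: str,
    age_center: float = DEFAULT_AGE_CENTER,
) -> CohortFit:
    """Cross-sectional trajectory model for one network.

    OLS of strength on {scan_age, sex, motion, preterm, preterm×scan_age}
    with two-sided t-distribution p-values.  Requires at least two sessions
    in each prematurity group.
    """
    df = _network_frame(records, network)
    for flag, label in ((True, "preterm"), (False, "term")):
        if (df["preterm"].astype(bool) == flag).sum() < 2:
            raise ValueError(f"fewer than 2 {label} sessions for {network!r}")
    terms = ["scan_age", "sex", "motion", "preterm", "preterm:scan_age"]
    return _ols_fit(df, terms, network, age_center)


def group_comparison(
    records: pd.DataFrame,
    network: str,
    age_window: tuple = DEFAULT_TERM_EQUIVALENT_WINDOW,
    age_center: float = DEFAULT_AGE_CENTER,
) -> CohortFit:
    """Adjusted preterm-vs-term difference at term-equivalent age.

    OLS of strength on {preterm, sex, motion, scan_age} over sessions scanned
    within ``age_window``; the reported statistic is the two-sided t-test of
    the preterm coefficient.
    """
    df = _network_frame(records, network)
    lo, hi = age_window
    df = df[(df["scan_age"] >= lo) & (df["scan_age"] <= hi)]
    groups = df["preterm"].astype(bool)
    if groups.nunique() < 2:
        raise ValueError("both prematurity groups must be present in the window")
    terms = ["preterm", "sex", "motion", "scan_age"]
    fit = _ols_fit(df, terms, network, age_center)
    fit.extras["group_difference"] = fit.estimate("preterm")
    fit.extras["group_pvalue"] = fit.pvalue("preterm")
    return fit


def longitudinal_slope(
    records: pd.DataFrame,
    network: str,
    conf_level: float = 0.95,
    method: str = "simultaneous",
) -> dict:
    """Average maturation rate from two-scan subjects, motion-adjusted.

    ``method='simultaneous'`` (default) fits one OLS of strength on scan age
    with motion as a covariate, so the slope CI has exact OLS coverage.
    ``method='two_step'`` first residualises strength on motion (mean added
    back) and then regresses on scan age; its CI ignores step-1 uncertainty
    and runs slightly narrow.  Returns the group slope with its confidence
    interval and the per-subject two-point slopes of the motion-adjusted
    strengths.
    """
    df = _network_frame(records, network)
    counts = df.groupby("subject_id")["session_id"].count()
    offenders = counts[counts != 2].index.tolist()
    if offenders:
        raise ValueError(f"subjects without exactly 2 sessions: {offenders}")
    strength = df["strength"].astype(float).to_numpy()
    age = df["scan_age"].astype(float).to_numpy()
    motion = df["motion"].astype(float).to_numpy()
    motion_varies = np.ptp(motion) > 0
    if method == "simultaneous":
        X = sm.add_constant(np.column_stack([age, motion])
                            if motion_varies else age)
        full = sm.OLS(strength, X).fit()
        res = full
        if motion_varies:
            resid = strength - full.params[2] * (motion - motion.mean())
        else:
            resid = strength.copy()
    elif method == "two_step":
        if motion_varies:
            Xm = sm.add_constant(motion)
            resid = sm.OLS(strength, Xm).fit().resid + strength.mean()
        else:
            resid = strength.copy()
        res = sm.OLS(resid, sm.add_constant(age)).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    ci = res.conf_int(alpha=1.0 - conf_level)[1]
    work = df.assign(_resid=resid)
    subj_slopes = {}
    for sub, g in work.groupby("subject_id"):
        g = g.sort_values("scan_age")
        da = g["scan_age"].iloc[1] - g["scan_age"].iloc[0]
        subj_slopes[sub] = float(
            (g["_resid"].iloc[1] - g["_resid"].iloc[0]) / da
        ) if da != 0 else float("nan")
    return {
        "network": network,
        "slope": float(res.params[1]),
        "se": float(res.bse[1]),
        "ci": (float(ci[0]), float(ci[1])),
        "pvalue": float(res.pvalues[1]),
        "subject_slopes": subj_slopes,
        "n_pairs": len(subj_slopes),
    }


def motion_balance_check(records: pd.DataFrame) -> float:
    """Two-sided paired comparison of motion between first and second scans.

    Returns the paired t-test p-value; identical motion in every pair is a
    degenerate (zero-variance) case reported as p = 1.
    """
    df = records.drop_duplicates("session_id").copy()
    counts = df.groupby("subject_id")["session_id"].count()
    pairs = counts[counts == 2].index
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired subjects")
    first, second = [], []
    for sub in pairs:
        g = df[df["subject_id"] == sub].sort_values("scan_age")
        first.append(float(g["motion"].iloc[0]))
        second.append(float(g["motion"].iloc[1]))
    diffs = np.asarray(second) - np.asarray(first)
    if np.allclose(diffs, 0.0):
        return 1.0
    return float(stats.ttest_rel(second, first).pvalue)


def fit_all_networks(records: pd.DataFrame, model: str = "age",
                     **kwargs) -> dict:
    """Run one of the per-network analyses over every network in the table."""
    fits = {}
    for network in sorted(records["network"].unique()):
        if model == "age":
            fits[network] = fit_age_model(records, network, **kwargs)
        elif model == "group":
            fits[network] = group_comparison(records, network, **kwargs)
        elif model == "longitudinal":
            fits[network] = longitudinal_slope(records, network, **kwargs)
        else:
            raise ValueError(f"unknown model {model!r}")
    return fits
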