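"""Cohort-level statistics.

Per-patient summaries, 2x2 contingency tests (Pearson chi-square without
continuity correction, two-sided Fisher), Woolf odds-ratio intervals,
bootstrap CIs for per-deletion proportions, Wilcoxon rank-sum group
comparisons, age-at-diagnosis linear associations, and a random-intercept
logistic model of per-deletion RAG status with exposure group as the fixed
effect.

The mixed model is estimated by maximum likelihood with fixed-order
Gauss-Hermite quadrature over the patient-level intercept; its Wald CI is
on the log-odds scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import logsumexp

from .models import DeletionAnnotation, PatientRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency machinery


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = exposure groups (high, low), columns = yes/no."""

    a: int  # high, yes
    b: int  # high, no
    c: int  # low, yes
    d: int  # low, no

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_printed(cls, n_high: int, pct_high: float, n_low: int, pct_low: float) -> "ContingencyTable":
        """Reconstruct integer counts from group totals and printed percentages."""
        a = round(n_high * pct_high / 100.0)
        c = round(n_low * pct_low / 100.0)
        return cls(a, n_high - a, c, n_low - c)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def prop_high(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def prop_low(self) -> float:
        return self.c / (self.c + self.d)


def chi_square_test(t: ContingencyTable) -> Tuple[float, float]:
    """Pearson chi-square on a 2x2, 1 df, no continuity correction."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive margins")
    stat, p, _, expected = sps.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ValueError("all expected cells must be positive")
    return float(stat), float(p)


def fisher_exact_test(t: ContingencyTable) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of tables (at
    fixed margins) no more probable than the observed one."""
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return float(p)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def odds_ratio(t: ContingencyTable) -> OddsRatioResult:
    """Crude OR = ad/bc with the Woolf (log-scale Wald) 95% CI."""
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        logger.warning("zero cell in 2x2; Haldane-Anscombe 0.5 correction applied")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), corrected)


def bootstrap_proportion_ci(
    outcomes: Sequence[bool], B: int = 10_000, seed: int = 0
) -> Tuple[float, float]:
    """Seeded percentile 95% CI of a proportion, resampling units with
    replacement (here: deletions, matching per-deletion bar plots)."""
    y = np.asarray(outcomes, dtype=float)
    if y.size == 0:
        raise ValueError("cannot bootstrap an empty outcome vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(B, y.size))
    props = y[idx].mean(axis=1)
    lo, hi = np.percentile(props, [2.5, 97.5])
    return float(lo), float(hi)


def wilcoxon_group_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact when the combined sample is small (n <= 20) and tie-free,
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical groups give p = 1).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def age_association(values: Sequence[float], ages: Sequence[float]) -> Tuple[float, float]:
    """OLS slope of a per-patient quantity on age-at-diagnosis, with t-test p."""
    values, ages = np.asarray(values, float), np.asarray(ages, float)
    if values.size < 3:
        raise ValueError("need >= 3 patients")
    if np.allclose(ages, ages[0]):
        raise ValueError("age predictor is constant")
    res = sps.linregress(ages, values)
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# per-patient summaries


def patient_summaries(
    annotations: Sequence[DeletionAnnotation],
    patients: Sequence[PatientRecord],
) -> pd.DataFrame:
    """Per-patient deletion counts and RAG proportions.

    Proportions use each patient's own denominator; patients with zero
    off-target deletions get NaN off-target proportions (excluded from
    proportion summaries downstream, logged).
    """
    by_pid = {p.patient_id: p for p in patients}
    orphans = {a.deletion.patient_id for a in annotations} - set(by_pid)
    if orphans:
        raise ValueError(f"deletions reference unknown patients: {sorted(orphans)}")
    rows = []
    for p in patients:
        mine = [a for a in annotations if a.deletion.patient_id == p.patient_id]
        off = [a for a in mine if a.target_status == "off_target"]
        n_off_rag = sum(a.rag_mediated for a in off)
        if not off:
            logger.info("patient %s has no off-target deletions", p.patient_id)
        rows.append(
            {
                "patient_id": p.patient_id,
                "exposure_group": p.exposure_group,
                "age_at_dx": p.age_at_dx,
                "n_deletions": len(mine),
                "n_rag": sum(a.rag_mediated for a in mine),
                "n_off_target": len(off),
                "n_off_target_rag": n_off_rag,
                "prop_off_target_rag": n_off_rag / len(off) if off else np.nan,
            }
        )
    return pd.DataFrame(rows)


def group_medians(summaries: pd.DataFrame, column: str) -> pd.DataFrame:
    """Median / range / IQR of a per-patient column by exposure group."""
    def agg(s: pd.Series) -> pd.Series:
        s = s.dropna()
        q1, q3 = s.quantile([0.25, 0.75])
        return pd.Series(
            {"median": s.median(), "min": s.min(), "max": s.max(), "iqr": q3 - q1}
        )

    return summaries.groupby("exposure_group")[column].apply(agg).unstack()


def cohort_contingency(
    annotations: Sequence[DeletionAnnotation],
    patients: Sequence[PatientRecord],
    indicator: str = "rag_mediated",
    subset: str = "off_target",
) -> ContingencyTable:
    """Per-deletion 2x2 of exposure group vs a boolean annotation column.

    ``indicator``: rag_mediated, or a motif indicator string like "full:both",
    "heptamer:any", "nonamer:any".  ``subset``: off_target, ig_tcr or all.
    """
    group_of = {p.patient_id: p.exposure_group for p in patients}

    def value(a: DeletionAnnotation) -> bool:
        if indicator == "rag_mediated":
            return a.rag_mediated
        kind, _, side = indicator.partition(":")
        return a.has_motif(kind, side or "any")

    counts = {("high", True): 0, ("high", False): 0, ("low", True): 0, ("low", False): 0}
    for a in annotations:
        if subset != "all" and a.target_status != subset:
            continue
        g = group_of[a.deletion.patient_id]
        counts[(g, value(a))] += 1
    return ContingencyTable(
        counts[("high", True)], counts[("high", False)],
        counts[("low", True)], counts[("low", False)],
    )


# ---------------------------------------------------------------------------
# random-intercept logistic model


@dataclass
class MultilevelFit:
    """ML fit of logit P(y_ij=1) = b0 + b1*high_i + u_i, u_i ~ N(0, s^2)."""

    fixed_effect_or: float
    ci_low: float
    ci_high: float
    random_intercept_var: float
    converged: bool
    separated: bool = False
    intercept: float = 0.0
    log_likelihood: float = float("nan")


_GH_NODES = 41


def fit_mixed_logit(
    y: Sequence[int],
    x: Sequence[int],
    cluster: Sequence[str],
    ridge: float = 0.0,
    n_nodes: int = _GH_NODES,
) -> MultilevelFit:
    """Random-intercept logistic regression by Gauss-Hermite ML.

    ``y`` per-observation 0/1 outcome, ``x`` 0/1 exposure indicator
    (constant within cluster), ``cluster`` the patient id.  On complete
    separation of exposure vs outcome the fit is re-run with a weak ridge
    penalty and flagged.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    cluster = np.asarray(cluster)
    t_nodes, t_weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(t_weights) - 0.5 * np.log(np.pi)

    # sort observations by cluster so per-cluster sums are reduceat slices
    order = np.argsort(cluster, kind="stable")
    y, x, cluster = y[order], x[order], cluster[order]
    boundaries = np.flatnonzero(np.r_[True, cluster[1:] != cluster[:-1]])

    # detect complete separation in the exposure x outcome margin
    separated = False
    for g in (0.0, 1.0):
        sel = x == g
        if sel.any() and (y[sel].min() == y[sel].max()):
            separated = True
    if separated and ridge == 0.0:
        logger.warning("complete separation detected; refitting with a ridge penalty")
        fit = fit_mixed_logit(y, x, cluster, ridge=0.5, n_nodes=n_nodes)
        fit.separated = True
        return fit

    sign = np.where(y > 0, 1.0, -1.0)  # log p(y|eta) = -softplus(-sign*eta)

    def negloglik(params: np.ndarray) -> float:
        b0, b1, log_sigma = params
        sigma = np.exp(log_sigma)
        u = np.sqrt(2.0) * sigma * t_nodes  # (K,)
        lin = (b0 + b1 * x)[None, :] + u[:, None]  # (K, n)
        ll_obs = -np.logaddexp(0.0, -sign[None, :] * lin)
        ll_cluster = np.add.reduceat(ll_obs, boundaries, axis=1)  # (K, C)
        total = logsumexp(log_w[:, None] + ll_cluster, axis=0).sum()
        pen = 0.5 * ridge * (params[0] ** 2 + params[1] ** 2)
        return -total + pen

    p_bar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    x0 = np.array([np.log(p_bar / (1 - p_bar)), 0.0, np.log(0.5)])
    res = optimize.minimize(negloglik, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    b0, b1, log_sigma = res.x
    se = _wald_se(negloglik, res.x, index=1)
    or_ = float(np.exp(b1))
    ci = (float(np.exp(b1 - 1.96 * se)), float(np.exp(b1 + 1.96 * se)))
    return MultilevelFit(
        fixed_effect_or=or_, ci_low=ci[0], ci_high=ci[1],
        random_intercept_var=float(np.exp(2 * log_sigma)),
        converged=bool(res.success), separated=False,
        intercept=float(b0), log_likelihood=float(-res.fun),
    )


def _wald_se(f, xhat: np.ndarray, index: int, h: float = 1e-4) -> float:
    """SE of one parameter from a finite-difference Hessian of -loglik."""
    n = len(xhat)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(xhat + ei + ej) - f(xhat + ei - ej)
                - f(xhat - ei + ej) + f(xhat - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        var = cov[index, index]
        if var <= 0:
            raise np.linalg.LinAlgError
        return float(np.sqrt(var))
    except np.linalg.LinAlgError:
        logger.warning("Hessian not positive definite; Wald SE unavailable")
        return float("nan")


def multilevel_rag_model(
    annotations: Sequence[DeletionAnnotation],
    patients: Sequence[PatientRecord],
    outcome: str = "rag_mediated",
) -> MultilevelFit:
    """Mixed model of per-deletion RAG status on exposure group.

    Run on off-target deletions; ``outcome`` is "rag_mediated" (full RSS at
    >= 1 breakpoint) or "full_both".
    """
    group_of = {p.patient_id: p.exposure_group for p in patients}
    off = [a for a in annotations if a.target_status == "off_target"]
    if not off:
        raise ValueError("no off-target deletions to model")
    if outcome == "rag_mediated":
        yv = [int(a.rag_mediated) for a in off]
    elif outcome == "full_both":
        yv = [int(a.rag_class == "full_both") for a in off]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    xv = [int(group_of[a.deletion.patient_id] == "high") for a in off]
    cl = [a.deletion.patient_id for a in off]
    return fit_mixed_logit(yv, xv, cl)
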