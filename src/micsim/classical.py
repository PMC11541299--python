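"""Change-score-based MIC estimators.

Four estimators that operate on the observed sum-score change and the
transition rating: mean change of the "a little better" subgroup, the
ROC/Youden cutoff, predictive modeling (logistic regression, likelihood
ratio = 1), and adjusted predictive modeling which corrects the PM
estimate for the prior-odds bias using the anchor's reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .grm import cronbach_alpha

__all__ = [
    "MicEstimate",
    "mic_mean_change",
    "mic_roc",
    "mic_predictive_modeling",
    "mic_adjusted_pm",
    "change_score_reliability",
    "polyserial_correlation",
    "transition_reliability",
]

A_LITTLE_BETTER = 4


@dataclass
class MicEstimate:
    """One estimator's MIC with convergence status and diagnostics."""

    method: str
    mic_prom: float = np.nan
    mic_latent: float | None = None
    converged: bool = True
    reason: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.mic_prom):
            raise ValueError("converged estimate must have a finite mic_prom")


def _failed(method: str, reason: str, **diag) -> MicEstimate:
    return MicEstimate(
        method=method, mic_prom=np.nan, converged=False, reason=reason,
        diagnostics=diag,
    )


def mic_mean_change(change_scores, ratings) -> MicEstimate:
    """Mean change score of the subgroup rating themselves 'A little better'."""
    change_scores = np.asarray(change_scores, dtype=float)
    ratings = np.asarray(ratings)
    if change_scores.shape != ratings.shape:
        raise ValueError("change_scores and ratings must have the same length")
    mask = ratings == A_LITTLE_BETTER
    n_sub = int(mask.sum())
    if n_sub == 0:
        return _failed("mc", "no simulees rated 'a little better'")
    return MicEstimate(
        method="mc",
        mic_prom=float(change_scores[mask].mean()),
        diagnostics={"n_subgroup": n_sub},
    )


def _youden_scan(change_scores, improved):
    """All candidate cutoffs (midpoints between adjacent distinct values)
    with their Youden J = sensitivity + specificity - 1."""
    values = np.unique(change_scores)
    if values.size < 2:
        return None, None
    cutoffs = (values[:-1] + values[1:]) / 2.0
    n_pos = improved.sum()
    n_neg = improved.size - n_pos
    # classification rule: "improved" when change > cutoff
    pos_sorted = np.sort(change_scores[improved])
    neg_sorted = np.sort(change_scores[~improved])
    sens = 1.0 - np.searchsorted(pos_sorted, cutoffs, side="right") / n_pos
    spec = np.searchsorted(neg_sorted, cutoffs, side="right") / n_neg
    return cutoffs, sens + spec - 1.0


def mic_roc(change_scores, improved, tie_rule: str = "smallest") -> MicEstimate:
    """Youden-optimal cutoff classifying improved vs not-improved.

    Candidate cutoffs are midpoints between adjacent distinct observed
    change scores.  Exact ties in J are broken toward the smallest
    cutoff by default (``tie_rule="mean"`` averages the tied cutoffs).
    """
    change_scores = np.asarray(change_scores, dtype=float)
    improved = np.asarray(improved, dtype=bool)
    if improved.all() or not improved.any():
        return _failed("roc", "both improved and not-improved simulees required")
    cutoffs, j = _youden_scan(change_scores, improved)
    if cutoffs is None:
        return _failed("roc", "all change scores identical")
    best = np.flatnonzero(np.isclose(j, j.max()))
    if tie_rule == "smallest":
        cut = cutoffs[best[0]]
    elif tie_rule == "mean":
        cut = cutoffs[best].mean()
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    return MicEstimate(
        method="roc",
        mic_prom=float(cut),
        diagnostics={"youden_j": float(j.max()), "n_tied": int(best.size)},
    )


def _fit_logistic(change_scores, improved):
    exog = sm.add_constant(change_scores)
    model = sm.Logit(improved.astype(float), exog)
    return model.fit(disp=False, method="newton", tol=1e-8, maxiter=100)


def mic_predictive_modeling(change_scores, improved) -> MicEstimate:
    """Change score where the likelihood ratio of improvement equals 1.

    Fits logit P(improved) = C + B * change; at LR = 1 the posterior
    odds equal the prior odds, so the MIC is (ln(prior odds) - C) / B.
    """
    change_scores = np.asarray(change_scores, dtype=float)
    improved = np.asarray(improved, dtype=bool)
    if improved.all() or not improved.any():
        return _failed("pm", "both improved and not-improved simulees required")
    try:
        res = _fit_logistic(change_scores, improved)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return _failed("pm", "logistic fit failed (perfect separation?)")
    if not res.mle_retvals.get("converged", False):
        return _failed("pm", "logistic fit did not converge")
    c, b = res.params
    if b <= 0:
        return _failed("pm", "non-positive slope: change does not predict improvement",
                       C=float(c), B=float(b))
    p = improved.mean()
    log_prior_odds = float(np.log(p / (1.0 - p)))
    mic = (log_prior_odds - c) / b
    return MicEstimate(
        method="pm",
        mic_prom=float(mic),
        diagnostics={
            "C": float(c), "B": float(b),
            "prop_improved": float(p),
            "log_prior_odds": log_prior_odds,
        },
    )


def change_score_reliability(responses_t1, responses_t2) -> float:
    """Reliability of the sum-score change from two-wave item responses.

    Classical difference-score reliability: wave reliabilities come from
    Cronbach's alpha and the between-wave true-score covariance from the
    observed covariance (wave errors independent).
    """
    s1 = np.asarray(responses_t1).sum(axis=1).astype(float)
    s2 = np.asarray(responses_t2).sum(axis=1).astype(float)
    a1 = cronbach_alpha(responses_t1)
    a2 = cronbach_alpha(responses_t2)
    v1, v2 = s1.var(ddof=1), s2.var(ddof=1)
    c12 = np.cov(s1, s2, ddof=1)[0, 1]
    denom = v1 + v2 - 2.0 * c12
    if denom <= 0:
        raise ValueError("change score has zero variance")
    return float((a1 * v1 + a2 * v2 - 2.0 * c12) / denom)


def polyserial_correlation(x, ordinal) -> float:
    """Two-step ML polyserial correlation.

    Thresholds are fixed at the inverse-normal cumulative proportions of
    the ordinal variable; the correlation maximizes the conditional
    likelihood of the ordinal responses given the standardized
    continuous variable.
    """
    x = np.asarray(x, dtype=float)
    z = (x - x.mean()) / x.std(ddof=1)
    codes = np.unique(ordinal)
    if codes.size < 2:
        raise ValueError("ordinal variable must have >= 2 observed categories")
    y = np.searchsorted(codes, ordinal)
    props = np.bincount(y) / y.size
    taus = norm.ppf(np.cumsum(props)[:-1])
    upper = np.append(taus, np.inf)[y]
    lower = np.append(-np.inf, taus)[y]

    def negll(rho):
        s = np.sqrt(1.0 - rho * rho)
        prob = norm.cdf((upper - rho * z) / s) - norm.cdf((lower - rho * z) / s)
        return -np.log(np.clip(prob, 1e-300, None)).sum()

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def transition_reliability(ratings, responses_t1, responses_t2,
                           method: str = "structural") -> float:
    """Estimate the transition-rating reliability from two-wave data.

    ``method="structural"`` (default) treats the rating as an ordinal
    indicator of a latent perceived change driven by the two wave true
    scores: polyserial correlations of the rating with each wave's sum
    score are disattenuated by the wave reliabilities (Cronbach's
    alpha) and combined into the R^2 of the latent rating variable on
    the two true scores.  That R^2 is the rating's reliability w.r.t.
    its own latent continuum, so it remains stable even when ratings
    are driven by the follow-up state rather than by true change.

    ``method="concurrent"`` instead squares the polyserial correlation
    between the rating and the observed change score and disattenuates
    by the change-score reliability; it estimates the rating's
    reliability *as a measure of true change* and therefore shrinks
    when present-state bias decouples the rating from the change.
    """
    s1 = np.asarray(responses_t1).sum(axis=1).astype(float)
    s2 = np.asarray(responses_t2).sum(axis=1).astype(float)
    a1 = cronbach_alpha(responses_t1)
    a2 = cronbach_alpha(responses_t2)
    if method == "concurrent":
        rho = polyserial_correlation(s2 - s1, ratings)
        r_x = change_score_reliability(responses_t1, responses_t2)
        return float(np.clip(rho * rho / r_x, 0.02, 1.0))
    if method != "structural":
        raise ValueError("method must be 'structural' or 'concurrent'")
    r1 = polyserial_correlation(s1, ratings) / np.sqrt(a1)
    r2 = polyserial_correlation(s2, ratings) / np.sqrt(a2)
    r12 = min(np.corrcoef(s1, s2)[0, 1] / np.sqrt(a1 * a2), 0.999)
    r_sq = (r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * r12) / (1.0 - r12 * r12)
    return float(np.clip(r_sq, 1e-6, 1.0))


# scaling constant between the logistic and probit metrics
_LOGIT_PROBIT = 1.702


def mic_adjusted_pm(
    change_scores,
    improved,
    tr_reliability: float | str = "estimate",
    ratings=None,
    responses_t1=None,
    responses_t2=None,
) -> MicEstimate:
    """Predictive-modeling MIC with the prior-odds bias correction.

    The PM cutoff is biased away from the true MIC when the proportion
    improved differs from 0.5.  Under a bivariate-normal model for the
    change score X and the latent anchor continuum, the bias of the PM
    cutoff relative to the anchor-implied true threshold equals

        ln(prior odds) / 1.702 * SD(X)
            * [ sqrt(R_X / r) + (sqrt(1 - rho^2) - 1) / rho ]

    with ``R_X`` the change-score reliability, ``r`` the anchor
    (transition-rating) reliability and ``rho = sqrt(R_X * r)`` their
    implied correlation; 1.702 converts the fitted logistic metric to
    the probit metric.  That predicted bias is subtracted from the PM
    estimate, so the adjustment vanishes exactly when half the sample
    improved.  With ``tr_reliability = "estimate"`` the anchor
    reliability is estimated from the data (requires ``ratings`` and
    both waves' item responses); pass a known value in simulation mode
    to bypass the estimator.
    """
    pm = mic_predictive_modeling(change_scores, improved)
    if not pm.converged:
        return _failed("apm", f"pm stage failed: {pm.reason}")
    if responses_t1 is None or responses_t2 is None:
        raise ValueError("item responses at both waves are required for APM")
    r_x = change_score_reliability(responses_t1, responses_t2)
    if tr_reliability == "estimate":
        if ratings is None:
            raise ValueError("ratings are required when estimating reliability")
        rel = transition_reliability(ratings, responses_t1, responses_t2)
    else:
        rel = float(tr_reliability)
        if not 0.0 < rel <= 1.0:
            raise ValueError("tr_reliability must be in (0, 1]")
    rho_sq = min(r_x * rel, 1.0 - 1e-9)
    rho = np.sqrt(rho_sq)
    sd_x = float(np.std(np.asarray(change_scores, dtype=float), ddof=1))
    predicted_bias = (
        pm.diagnostics["log_prior_odds"] / _LOGIT_PROBIT * sd_x
        * (np.sqrt(r_x / rel) + (np.sqrt(1.0 - rho_sq) - 1.0) / rho)
    )
    return MicEstimate(
        method="apm",
        mic_prom=float(pm.mic_prom - predicted_bias),
        diagnostics={
            **pm.diagnostics,
            "mic_pm": pm.mic_prom,
            "change_reliability": float(r_x),
            "tr_reliability": float(rel),
            "correction": float(predicted_bias),
        },
    )
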