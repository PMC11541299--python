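"""Longitudinal graded-response-model fitting and MIC extraction.

Two correlated latent factors (one per wave) measured by the same items
with wave-invariant parameters, plus a dichotomous transition indicator
loading on both factors.  Estimation is marginal maximum likelihood via
an EM algorithm over a fixed rectangular quadrature grid, with the
wave-1 factor identified as standard normal and the wave-2 mean,
variance and covariance free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .grm import ItemParameters, latent_to_prom_change
from .classical import MicEstimate

__all__ = [
    "LirtFit",
    "fit_longitudinal_grm",
    "mic_from_lirt",
    "estimate_psb",
]


@dataclass
class LirtFit:
    """Fitted longitudinal GRM."""

    slopes: np.ndarray           # (n_items,), wave-invariant
    locations: np.ndarray        # (n_items, K-1)
    alpha_tr1: float             # transition-item slope on wave-1 factor
    alpha_tr2: float             # transition-item slope on wave-2 factor
    delta_tr: float              # transition-item intercept
    mu2: float                   # wave-2 latent mean (wave 1 fixed N(0,1))
    var2: float
    cov12: float
    loglik: float
    n_cycles: int
    converged: bool
    constrained: bool
    n_obs: int
    history: list = field(default_factory=list, repr=False)

    @property
    def item_parameters(self) -> ItemParameters:
        return ItemParameters(self.slopes, self.locations, link="logistic")

    def to_json(self) -> str:
        d = asdict(self)
        d["slopes"] = self.slopes.tolist()
        d["locations"] = self.locations.tolist()
        d["history"] = [float(h) for h in self.history]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LirtFit":
        d = json.loads(text)
        d["slopes"] = np.asarray(d["slopes"])
        d["locations"] = np.asarray(d["locations"])
        return cls(**d)


# ---------------------------------------------------------------------------
# GRM likelihood pieces (logistic link), slope/ordered-location items

def _grm_probs(theta, a, b):
    """Category probabilities at grid ``theta`` for one item: (Q, K)."""
    cum = expit(a * (theta[:, None] - b[None, :]))        # (Q, K-1)
    ones = np.ones((theta.shape[0], 1))
    zeros = np.zeros((theta.shape[0], 1))
    return np.clip(np.hstack([ones, cum]) - np.hstack([cum, zeros]), 1e-300, 1.0)


def _pack_item(a, b):
    d = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(d)])


def _unpack_item(x):
    a = np.exp(x[0])
    b = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(x[2:]))])
    return a, b


def _fit_grm_item(theta, counts, a0, b0, maxiter=200):
    """Weighted ML for one GRM item from expected category counts.

    ``theta``: (Q,) stacked grid nodes (both waves); ``counts``: (Q, K)
    expected responses per node and category.  Analytic gradient in the
    packed (log slope, first location, log gaps) parameterization.
    """
    n_bound = b0.shape[0]

    def negll_grad(x):
        a, b = _unpack_item(x)
        z = a * (theta[:, None] - b[None, :])
        cum = expit(z)                                   # (Q, K-1)
        ones = np.ones((theta.shape[0], 1))
        zeros = np.zeros((theta.shape[0], 1))
        probs = np.clip(np.hstack([ones, cum]) - np.hstack([cum, zeros]),
                        1e-300, 1.0)
        f = -np.sum(counts * np.log(probs))
        w = counts / probs                               # (Q, K)
        # dP_k = dF_k - dF_{k+1}; collect per-boundary factor
        # coef_j = w[:, j] - w[:, j+1] multiplies dF_j
        coef = w[:, :-1] - w[:, 1:]                      # (Q, K-1)
        dens = cum * (1.0 - cum)                         # dF/dz
        common = coef * dens
        g_a = np.sum(common * (theta[:, None] - b[None, :])) * a  # d/d log a
        g_b = -np.sum(common, axis=0) * a                # d negll / d b_j
        grad = np.empty(2 + n_bound - 1)
        grad[0] = g_a
        grad[1] = g_b.sum()                              # b1 shifts all
        for m in range(1, n_bound):
            grad[1 + m] = g_b[m:].sum() * np.exp(x[1 + m])
        return f, grad

    res = minimize(negll_grad, _pack_item(a0, b0), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12})
    return _unpack_item(res.x)


def _fit_transition(design_cols, counts1, counts0, x0):
    """Weighted logistic regression for the transition indicator.

    ``design_cols``: (M, P) regressor values at the flattened grid
    nodes; ``counts1``/``counts0``: expected improved / not-improved
    counts per node.
    """

    def negll_grad(x):
        eta = design_cols @ x
        p = expit(eta)
        ll = np.sum(counts1 * np.log(np.clip(p, 1e-300, 1)))
        ll += np.sum(counts0 * np.log(np.clip(1 - p, 1e-300, 1)))
        grad = design_cols.T @ (counts1 - (counts1 + counts0) * p)
        return -ll, -grad

    res = minimize(negll_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12})
    return res.x


def _start_values(responses, n_cats):
    """Marginal-proportion starting locations, unit slopes."""
    n_items = responses.shape[1]
    locations = np.zeros((n_items, n_cats - 1))
    for i in range(n_items):
        cum = np.array([(responses[:, i] >= k).mean() for k in range(1, n_cats)])
        cum = np.clip(cum, 0.01, 0.99)
        locations[i] = np.sort(-np.log(cum / (1 - cum)))
        locations[i] += np.linspace(0, 1e-3, n_cats - 1)  # break exact ties
    return np.ones(n_items), locations


def fit_longitudinal_grm(
    responses_t1: np.ndarray,
    responses_t2: np.ndarray,
    improved: np.ndarray,
    constrained: bool = False,
    n_quad: int = 21,
    tol: float = 1e-5,
    max_cycles: int = 500,
    grid_span: float = 4.5,
) -> LirtFit:
    """Fit the two-factor longitudinal GRM by marginal ML (EM).

    Wave-1 items load on factor 1 only, wave-2 items on factor 2 only,
    with item parameters equal across waves.  The dichotomized
    transition item is a binary 2-parameter item in both factors; with
    ``constrained=True`` its slopes are forced equal-and-opposite so it
    indicates the plain latent change.  Returns a fit flagged
    ``converged=False`` when the log-likelihood has not stabilized
    within ``max_cycles``.
    """
    y1 = np.asarray(responses_t1, dtype=np.int64)
    y2 = np.asarray(responses_t2, dtype=np.int64)
    imp = np.asarray(improved, dtype=bool)
    n, n_items = y1.shape
    if y2.shape != y1.shape or imp.shape[0] != n:
        raise ValueError("input shapes disagree")
    n_cats = int(max(y1.max(), y2.max())) + 1

    slopes, locations = _start_values(np.vstack([y1, y2]), n_cats)

    # crude moment starts for the wave-2 latent distribution
    s1 = y1.sum(1).astype(float)
    s2 = y2.sum(1).astype(float)
    sd1 = max(s1.std(ddof=1), 1e-6)
    mu2 = float((s2.mean() - s1.mean()) / sd1)
    var2 = float(max((s2.std(ddof=1) / sd1) ** 2, 0.1))
    cov12 = float(np.corrcoef(s1, s2)[0, 1] * np.sqrt(var2))

    p_imp = np.clip(imp.mean(), 0.01, 0.99)
    a_tr2 = 1.0
    a_tr1 = -1.0
    d_tr = float(np.log(p_imp / (1 - p_imp)))

    grid1 = np.linspace(-grid_span, grid_span, n_quad)
    lo = mu2 - grid_span * np.sqrt(var2) - 1.0
    hi = mu2 + grid_span * np.sqrt(var2) + 1.0
    grid2 = np.linspace(lo, hi, n_quad)
    g1 = np.repeat(grid1, n_quad)
    g2 = np.tile(grid2, n_quad)
    tr_design = (
        np.column_stack([g2 - g1, np.ones_like(g1)])
        if constrained
        else np.column_stack([g1, g2, np.ones_like(g1)])
    )

    onehots1 = [np.eye(n_cats)[y1[:, i]] for i in range(n_items)]
    onehots2 = [np.eye(n_cats)[y2[:, i]] for i in range(n_items)]

    loglik_prev = -np.inf
    history: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        # ---- E step
        log_l1 = np.zeros((n, n_quad))
        log_l2 = np.zeros((n, n_quad))
        for i in range(n_items):
            p1 = _grm_probs(grid1, slopes[i], locations[i])
            p2 = _grm_probs(grid2, slopes[i], locations[i])
            log_l1 += np.log(p1)[:, y1[:, i]].T
            log_l2 += np.log(p2)[:, y2[:, i]].T
        eta = (tr_design @ np.array(
            [a_tr2, d_tr] if constrained else [a_tr1, a_tr2, d_tr]
        )).reshape(n_quad, n_quad)
        p_grid = expit(eta)
        log_t = np.where(imp[:, None, None],
                         np.log(np.clip(p_grid, 1e-300, 1))[None],
                         np.log(np.clip(1 - p_grid, 1e-300, 1))[None])
        # prior over the grid from the current bivariate normal
        rho = np.clip(cov12 / np.sqrt(var2), -0.999, 0.999)
        resid_var = max(var2 - cov12 ** 2, 1e-6)
        log_w = (-0.5 * grid1[:, None] ** 2
                 - 0.5 * (grid2[None, :] - mu2 - cov12 * grid1[:, None]) ** 2
                 / resid_var)
        log_w -= logsumexp(log_w)
        log_post = log_l1[:, :, None] + log_l2[:, None, :] + log_t + log_w[None]
        person_ll = logsumexp(log_post.reshape(n, -1), axis=1)
        loglik = float(person_ll.sum())
        post = np.exp(log_post - person_ll[:, None, None])
        history.append(loglik)

        if abs(loglik - loglik_prev) < tol:
            converged = True
            break
        loglik_prev = loglik

        # ---- M step: items (combined expected counts from both waves)
        post1 = post.sum(axis=2)                      # (n, Q) wave-1 marginal
        post2 = post.sum(axis=1)                      # (n, Q) wave-2 marginal
        theta_both = np.concatenate([grid1, grid2])
        for i in range(n_items):
            c1 = onehots1[i].T @ post1                # (K, Q)
            c2 = onehots2[i].T @ post2
            counts = np.vstack([c1.T, c2.T])          # (2Q, K)
            slopes[i], locations[i] = _fit_grm_item(
                theta_both, counts, slopes[i], locations[i]
            )

        # transition item
        flat = post.reshape(n, -1)
        counts1 = flat[imp].sum(axis=0)
        counts0 = flat[~imp].sum(axis=0)
        if constrained:
            a_tr2, d_tr = _fit_transition(tr_design, counts1, counts0,
                                          np.array([a_tr2, d_tr]))
            a_tr1 = -a_tr2
        else:
            a_tr1, a_tr2, d_tr = _fit_transition(
                tr_design, counts1, counts0, np.array([a_tr1, a_tr2, d_tr])
            )

        # latent distribution: wave-1 fixed N(0,1); free conditional
        # theta2 | theta1 ~ N(a + b*theta1, tau^2) maximized from
        # posterior moments, then mapped back to (mu2, var2, cov12).
        m1 = post1 @ grid1 / 1.0
        m2 = post2 @ grid2
        e11 = post1 @ grid1 ** 2
        e22 = post2 @ grid2 ** 2
        e12 = np.einsum("nij,i,j->n", post, grid1, grid2)
        M1, M2 = m1.mean(), m2.mean()
        S11 = e11.mean() - M1 ** 2
        S22 = e22.mean() - M2 ** 2
        S12 = e12.mean() - M1 * M2
        b = S12 / max(S11, 1e-8)
        a = M2 - b * M1
        tau2 = max(S22 - b * b * S11, 1e-6)
        mu2 = float(a)            # a + b * E[theta1], E fixed at 0
        cov12 = float(b)          # b * var(theta1), fixed at 1
        var2 = float(b * b + tau2)

    return LirtFit(
        slopes=slopes,
        locations=locations,
        alpha_tr1=float(a_tr1),
        alpha_tr2=float(a_tr2),
        delta_tr=float(d_tr),
        mu2=float(mu2),
        var2=float(var2),
        cov12=float(cov12),
        loglik=float(history[-1]),
        n_cycles=cycle,
        converged=converged,
        constrained=constrained,
        n_obs=n,
        history=history,
    )


def mic_from_lirt(
    fit: LirtFit,
    conversion_n: int = 500_000,
    rng: np.random.Generator | None = None,
) -> MicEstimate:
    """MIC from a fitted longitudinal GRM, in latent and sum-score units.

    The latent MIC is the transition item's 50% point expressed against
    its change-direction slope, -delta / alpha_2: on the latent-change
    scale when the slopes are constrained equal-and-opposite, and on the
    (PSB-weighted) perceived-change scale otherwise, where it remains
    the mean personal threshold.  Conversion to sum-score points maps
    the latent MIC through the fitted items' expected-score curve over
    the fitted wave-1 latent distribution (standard normal under the
    identification used here).
    """
    method = "lirt" if fit.constrained else "lirt-unconstrained"
    if not fit.converged:
        return MicEstimate(method=method, mic_prom=np.nan, converged=False,
                           reason="EM did not converge")
    if fit.alpha_tr2 <= 0:
        return MicEstimate(
            method=method, mic_prom=np.nan, converged=False,
            reason="alpha_TR2 <= 0: transition item does not indicate improvement",
        )
    mic_latent = -fit.delta_tr / fit.alpha_tr2
    mic_prom = latent_to_prom_change(
        mic_latent, 0.0, 1.0, fit.item_parameters, n=conversion_n, rng=rng
    )
    return MicEstimate(
        method=method,
        mic_prom=float(mic_prom),
        mic_latent=float(mic_latent),
        diagnostics={
            "alpha_tr1": fit.alpha_tr1,
            "alpha_tr2": fit.alpha_tr2,
            "delta_tr": fit.delta_tr,
            "loglik": fit.loglik,
            "n_cycles": fit.n_cycles,
        },
    )


def estimate_psb(fit: LirtFit) -> float:
    """Degree of present-state bias implied by the transition slopes.

    q = alpha_TR1 / alpha_TR2 + 1: zero when the slopes are
    equal-and-opposite (the rating tracks true change), one when the
    wave-1 slope vanishes (the rating tracks the present state only).
    Only meaningful for unconstrained fits.
    """
    if fit.constrained:
        raise ValueError("PSB is identically 0 by construction in a constrained fit")
    if fit.alpha_tr2 == 0:
        raise ValueError("alpha_TR2 is zero; PSB undefined")
    return float(fit.alpha_tr1 / fit.alpha_tr2 + 1.0)
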