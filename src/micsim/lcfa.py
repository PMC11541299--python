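"""Longitudinal ordinal-indicator confirmatory factor analysis.

Limited-information pipeline: univariate thresholds and pairwise
polychoric correlations first, then a (diagonally) weighted least
squares fit of a two-factor model in which the same items load on the
wave-1 and wave-2 factors with invariant loadings and the dichotomized
transition item loads on both.  Delta convention throughout: latent
response variables have unit variance at wave 1; wave-2 variables keep
the wave-1 residual variances, and their total variance is implied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri

from .grm import ItemParameters, latent_to_prom_change
from .classical import MicEstimate

__all__ = [
    "polychoric_correlation",
    "polychoric_matrix",
    "LcfaFit",
    "fit_longitudinal_ordinal_cfa",
    "fit_lcfa_from_sample_data",
    "mic_from_lcfa",
]

_INF = 8.5  # effective infinity on the standard normal scale

# Gauss-Legendre nodes/weights used by the Genz bivariate-normal algorithm
_GL = {
    3: (
        np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904]),
        np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970]),
    ),
    6: (
        np.array([0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                  0.2031674267230659, 0.2334925365383547, 0.2491470458134029]),
        np.array([0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                  0.5873179542866171, 0.3678314989981802, 0.1252334085114692]),
    ),
    10: (
        np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                  0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                  0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                  0.1527533871307259]),
        np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                  0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                  0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                  0.07652652113349733]),
    ),
}


def bvn_upper(dh, dk, r: float):
    """P(X > dh, Y > dk) for standard bivariate normal, correlation r.

    Vectorized over ``dh``/``dk`` (Genz's adaptation of the
    Drezner-Wesolowsky algorithm; absolute accuracy ~5e-16).
    """
    dh = np.asarray(dh, dtype=float)
    dk = np.asarray(dk, dtype=float)
    r = float(r)
    if abs(r) < 0.3:
        w, x = _GL[3]
    elif abs(r) < 0.75:
        w, x = _GL[6]
    else:
        w, x = _GL[10]
    h, k = dh, dk
    hk = h * k
    if abs(r) < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(r)
        sn = np.sin(asr * np.concatenate([x, -x]) / 2.0 + asr / 2.0)  # (2L,)
        ww = np.concatenate([w, w])
        term = np.exp(
            (sn[:, None] * hk.ravel()[None, :] - hs.ravel()[None, :])
            / (1.0 - sn[:, None] ** 2)
        )
        bvn = (ww @ term).reshape(h.shape) * asr / (4.0 * np.pi)
        bvn = bvn + ndtr(-h) * ndtr(-k)
        return np.clip(bvn, 0.0, 1.0)
    # |r| >= 0.925: singular expansion
    if r < 0:
        k = -k
        hk = -hk
    bvn = np.zeros_like(h)
    if abs(r) < 1:
        ass = (1.0 - r) * (1.0 + r)
        a = np.sqrt(ass)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / ass + hk) / 2.0
        mask = asr > -100
        bvn = np.where(
            mask,
            a * np.exp(asr) * (1 - c * (bs - ass) * (1 - d * bs / 5) / 3
                               + c * d * ass * ass / 5),
            0.0,
        )
        mask2 = -hk < 100
        b = np.sqrt(bs)
        sp = np.sqrt(2 * np.pi) * ndtr(-b / a)
        bvn = bvn - np.where(
            mask2, np.exp(-hk / 2) * sp * b * (1 - c * bs * (1 - d * bs / 5) / 3), 0.0
        )
        a2 = a / 2.0
        for i in range(w.size):
            for sgn in (-1.0, 1.0):
                xs = (a2 * (sgn * x[i] + 1)) ** 2
                rs = np.sqrt(1 - xs)
                asr = -(bs / xs + hk) / 2.0
                mask = asr > -100
                spv = 1 + c * xs * (1 + d * xs)
                ep = np.exp(-hk * (1 - rs) / (2 * (1 + rs))) / rs
                bvn = bvn + np.where(mask, a2 * w[i] * np.exp(asr) * (ep - spv), 0.0)
        bvn = -bvn / (2.0 * np.pi)
    if r > 0:
        bvn = bvn + ndtr(-np.maximum(h, k))
    else:
        bvn = -bvn + np.maximum(0.0, ndtr(k) - ndtr(h))
    return np.clip(bvn, 0.0, 1.0)


def _cell_probabilities(tau_row, tau_col, rho):
    """Rectangle probabilities of a bivariate normal over a threshold grid."""
    er = np.concatenate([[-_INF], tau_row, [_INF]])
    ec = np.concatenate([[-_INF], tau_col, [_INF]])
    upper = bvn_upper(er[:, None] * np.ones_like(ec)[None, :],
                      np.ones_like(er)[:, None] * ec[None, :], rho)
    return np.clip(upper[:-1, :-1] - upper[1:, :-1]
                   - upper[:-1, 1:] + upper[1:, 1:], 1e-300, 1.0)


def univariate_thresholds(x: np.ndarray, n_cats: int | None = None) -> np.ndarray:
    """Inverse-normal thresholds from the cumulative category proportions."""
    x = np.asarray(x, dtype=np.int64)
    if n_cats is None:
        n_cats = int(x.max()) + 1
    props = np.bincount(x, minlength=n_cats) / x.size
    if np.count_nonzero(props) < 2:
        raise ValueError("variable has fewer than 2 observed categories")
    cum = np.clip(np.cumsum(props)[:-1], 1e-12, 1 - 1e-12)
    return ndtri(cum)


def polychoric_correlation(x, y, return_info: bool = False):
    """Two-stage ML polychoric correlation of two ordinal variables.

    Thresholds are fixed at their univariate estimates; the correlation
    maximizes the contingency-table likelihood.  With
    ``return_info=True`` also returns the observed information of rho at
    the optimum (for asymptotic-variance weighting).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    kx, ky = int(x.max()) + 1, int(y.max()) + 1
    tau_x = univariate_thresholds(x, kx)
    tau_y = univariate_thresholds(y, ky)
    table = np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky).astype(float)

    def negll(rho):
        return -np.sum(table * np.log(_cell_probabilities(tau_x, tau_y, rho)))

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-7})
    rho = float(res.x)
    if not return_info:
        return rho
    h = 5e-4
    hi = min(rho + h, 0.999)
    lo = max(rho - h, -0.999)
    info = (negll(hi) - 2 * res.fun + negll(lo)) / ((hi - rho) * (rho - lo))
    return rho, float(max(info, 1e-6))


def polychoric_matrix(ordinal_data: np.ndarray, return_info: bool = False):
    """Univariate thresholds and pairwise polychoric correlation matrix.

    ``ordinal_data``: (n, p) integer matrix, each column coded 0..K-1.
    Returns (thresholds list, correlation matrix) and optionally a
    matching matrix of observed informations of each correlation.
    """
    data = np.asarray(ordinal_data, dtype=np.int64)
    n, p = data.shape
    thresholds = [univariate_thresholds(data[:, j]) for j in range(p)]
    corr = np.eye(p)
    info = np.full((p, p), np.inf)
    for i in range(p):
        for j in range(i + 1, p):
            r, inf_ij = polychoric_correlation(data[:, i], data[:, j],
                                               return_info=True)
            corr[i, j] = corr[j, i] = r
            info[i, j] = info[j, i] = inf_ij
    if return_info:
        return thresholds, corr, info
    return thresholds, corr


def smooth_psd(matrix: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues at ``eps`` and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= eps:
        return matrix, False
    fixed = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d), True


@dataclass
class LcfaFit:
    """Fitted longitudinal ordinal CFA (limited information)."""

    loadings: np.ndarray          # (n_items,), wave-invariant
    lambda_tr1: float
    lambda_tr2: float
    tau_tr: float                 # transition-item threshold (model metric)
    item_thresholds_t1: np.ndarray
    item_thresholds_t2: np.ndarray
    psi22: float
    psi12: float
    mu2: float                    # wave-2 latent mean from threshold shifts
    discrepancy: float
    converged: bool
    constrained: bool
    heywood: bool
    weighted: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("loadings", "item_thresholds_t1", "item_thresholds_t2"):
            d[key] = getattr(self, key).tolist()
        return json.dumps(d, indent=2)


def _implied_correlations(lam, l1, l2, psi12, psi22, n_items):
    """Model-implied correlation matrix of (wave1 items, wave2 items, TR)."""
    p = 2 * n_items + 1
    lam_mat = np.zeros((p, 2))
    lam_mat[:n_items, 0] = lam
    lam_mat[n_items:2 * n_items, 1] = lam
    lam_mat[-1] = (l1, l2)
    psi = np.array([[1.0, psi12], [psi12, psi22]])
    c = lam_mat @ psi @ lam_mat.T
    resid = 1.0 - lam ** 2                     # wave-1 residuals, kept at wave 2
    total = np.concatenate([np.ones(n_items),
                            lam ** 2 * psi22 + resid,
                            [1.0]])            # TR: delta convention
    d = np.sqrt(np.clip(total, 1e-8, None))
    sigma = c / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    return sigma, c[-1, -1]


def fit_longitudinal_ordinal_cfa(
    thresholds: list[np.ndarray],
    corr_matrix: np.ndarray,
    n: int,
    constrained: bool = False,
    weights: np.ndarray | None = None,
    weight_threshold_n: int = 1000,
) -> LcfaFit:
    """Least-squares fit of the two-factor wave-invariant model.

    ``thresholds``/``corr_matrix`` come from :func:`polychoric_matrix`
    on the 2*n_items + 1 columns (wave-1 items, wave-2 items, dichotomous
    transition item, in that order).  Factor 1 variance is fixed at 1;
    factor 2 variance and the covariance are free.  ``weights`` (same
    shape as the matrix) supplies per-correlation weights for DWLS; by
    default unweighted when ``n < weight_threshold_n``.
    """
    p = corr_matrix.shape[0]
    n_items = (p - 1) // 2
    if 2 * n_items + 1 != p:
        raise ValueError("expected an odd number of variables (items twice + TR)")
    corr, smoothed = smooth_psd(corr_matrix)
    iu = np.triu_indices(p, 1)
    r_obs = corr[iu]
    weighted = weights is not None and n >= weight_threshold_n
    w = weights[iu] if weighted else np.ones_like(r_obs)
    w = w / w.mean()

    # start values: loadings from mean absolute within-wave correlation
    r11 = corr[:n_items, :n_items]
    mean_r = np.clip(np.mean(r11[np.triu_indices(n_items, 1)]), 0.05, 0.95)
    lam0 = np.full(n_items, np.sqrt(mean_r))
    psi22_0 = 1.5
    psi12_0 = 0.5
    x0 = np.concatenate([lam0, [-0.5, 0.5], [np.log(psi22_0)],
                         [np.arctanh(psi12_0 / np.sqrt(psi22_0))]])
    if constrained:
        x0 = np.concatenate([lam0, [0.5], [np.log(psi22_0)],
                             [np.arctanh(psi12_0 / np.sqrt(psi22_0))]])

    def unpack(x):
        lam = x[:n_items]
        if constrained:
            l2 = x[n_items]
            l1 = -l2
            log_psi22, z = x[n_items + 1], x[n_items + 2]
        else:
            l1, l2 = x[n_items], x[n_items + 1]
            log_psi22, z = x[n_items + 2], x[n_items + 3]
        psi22 = np.exp(log_psi22)
        psi12 = np.tanh(z) * np.sqrt(psi22) * 0.999
        return lam, l1, l2, psi12, psi22

    def objective(x):
        lam, l1, l2, psi12, psi22 = unpack(x)
        sigma, _ = _implied_correlations(lam, l1, l2, psi12, psi22, n_items)
        resid = sigma[iu] - r_obs
        return float(np.sum(w * resid * resid))

    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    lam, l1, l2, psi12, psi22 = unpack(res.x)
    sigma, tr_latent_var = _implied_correlations(lam, l1, l2, psi12, psi22, n_items)
    heywood = bool(np.any(np.abs(lam) >= 1.0) or tr_latent_var > 1.0)

    tau1 = np.array([thresholds[i] for i in range(n_items)])
    tau2 = np.array([thresholds[n_items + i] for i in range(n_items)])
    tau_tr_obs = float(thresholds[-1][0])

    # wave-2 latent mean from the wave-invariance of item thresholds:
    # observed wave-2 thresholds are (tau - lam*mu2) / sqrt(total var)
    v2 = lam ** 2 * psi22 + (1.0 - lam ** 2)
    shifts = (tau1 - tau2 * np.sqrt(v2)[:, None]) / lam[:, None]
    mu2 = float(np.mean(shifts))
    tau_tr = tau_tr_obs + l2 * mu2             # TR total variance 1 (delta)

    return LcfaFit(
        loadings=lam,
        lambda_tr1=float(l1),
        lambda_tr2=float(l2),
        tau_tr=float(tau_tr),
        item_thresholds_t1=tau1,
        item_thresholds_t2=tau2,
        psi22=float(psi22),
        psi12=float(psi12),
        mu2=mu2,
        discrepancy=float(res.fun),
        converged=bool(res.success),
        constrained=constrained,
        heywood=heywood,
        weighted=weighted,
        n_obs=n,
        diagnostics={
            "smoothed": smoothed,
            "tau_tr_observed": tau_tr_obs,
            "n_iter": int(res.nit),
        },
    )


def fit_lcfa_from_sample_data(
    responses_t1, responses_t2, improved, constrained: bool = False
) -> LcfaFit:
    """Convenience wrapper: polychorics + CFA fit from raw two-wave data."""
    data = np.column_stack([
        np.asarray(responses_t1, dtype=np.int64),
        np.asarray(responses_t2, dtype=np.int64),
        np.asarray(improved, dtype=np.int64),
    ])
    n = data.shape[0]
    thresholds, corr, info = polychoric_matrix(data, return_info=True)
    weights = info  # observed information ~ 1 / asymptotic variance
    return fit_longitudinal_ordinal_cfa(
        thresholds, corr, n, constrained=constrained, weights=weights
    )


def mic_from_lcfa(
    fit: LcfaFit,
    conversion_n: int = 500_000,
    rng: np.random.Generator | None = None,
) -> MicEstimate:
    """MIC from a fitted ordinal CFA, in latent and sum-score units.

    The latent MIC is the transition threshold against the wave-2
    loading, tau_TR / lambda_TR2 (including the wave-2 latent mean
    absorbed into the threshold).  Conversion to sum-score points maps
    the fitted ordinal-CFA measurement model to an equivalent
    probit-metric graded item set (slope a = lambda / sqrt(1 - lambda^2),
    boundary b = tau / lambda) and applies the expected-score mapping
    over the wave-1 standard-normal factor.
    """
    method = "lcfa" if fit.constrained else "lcfa-unconstrained"
    if not fit.converged:
        return MicEstimate(method=method, mic_prom=np.nan, converged=False,
                           reason="discrepancy minimization failed")
    if fit.lambda_tr2 <= 0:
        return MicEstimate(
            method=method, mic_prom=np.nan, converged=False,
            reason="lambda_TR2 <= 0: transition item does not indicate improvement",
        )
    mic_latent = fit.tau_tr / fit.lambda_tr2
    lam = np.clip(np.abs(fit.loadings), 1e-6, 0.999)
    slopes = lam / np.sqrt(1.0 - lam ** 2)
    locations = fit.item_thresholds_t1 / lam[:, None]
    params = ItemParameters(slopes, locations, link="probit")
    mic_prom = latent_to_prom_change(
        mic_latent, 0.0, 1.0, params, n=conversion_n, rng=rng
    )
    return MicEstimate(
        method=method,
        mic_prom=float(mic_prom),
        mic_latent=float(mic_latent),
        diagnostics={
            "lambda_tr1": fit.lambda_tr1,
            "lambda_tr2": fit.lambda_tr2,
            "tau_tr": fit.tau_tr,
            "mu2": fit.mu2,
            "heywood": fit.heywood,
            "discrepancy": fit.discrepancy,
        },
    )
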