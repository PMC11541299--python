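"""Study orchestration and performance evaluation.

Runs estimators over a (subset of the) factorial design, collects one
row per sample x method, and summarizes residuals against the
per-sample true MIC as bias / residual SD / MSE with Monte Carlo
standard errors.  Also provides the residual meta-regression on the
design factors with backward selection.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .grm import ItemParameters
from .simulate import DesignPoint, SimulatedSample, sample_seed, simulate_sample
from .classical import (
    mic_mean_change,
    mic_roc,
    mic_predictive_modeling,
    mic_adjusted_pm,
)
from .lirt import fit_longitudinal_grm, mic_from_lirt
from .lcfa import fit_lcfa_from_sample_data, mic_from_lcfa

__all__ = [
    "METHODS",
    "estimate_sample",
    "run_study",
    "summarize_performance",
    "residual_regression",
    "save_results",
    "load_results",
]

logger = logging.getLogger("micsim")

FACTORS = ["theta1_mean", "delta_sd", "cor_theta1_delta",
           "prop_improved", "tr_reliability", "psb_mean"]

METHODS = ("mc", "roc", "pm", "apm",
           "lirt", "lirt-unconstrained", "lcfa", "lcfa-unconstrained")


def estimate_sample(
    sample: SimulatedSample,
    methods,
    tr_reliability: float | str = "estimate",
    conversion_n: int = 500_000,
    lirt_options: dict | None = None,
):
    """Apply the requested MIC estimators to one simulated sample."""
    cs = sample.change_score
    imp = sample.improved
    tr = sample.transition_rating
    out = []
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        t0 = time.perf_counter()
        if method == "mc":
            est = mic_mean_change(cs, tr)
        elif method == "roc":
            est = mic_roc(cs, imp)
        elif method == "pm":
            est = mic_predictive_modeling(cs, imp)
        elif method == "apm":
            rel = (sample.design.tr_reliability
                   if tr_reliability == "true" else tr_reliability)
            est = mic_adjusted_pm(cs, imp, rel, ratings=tr,
                                  responses_t1=sample.responses_t1,
                                  responses_t2=sample.responses_t2)
        elif method in ("lirt", "lirt-unconstrained"):
            fit = fit_longitudinal_grm(
                sample.responses_t1, sample.responses_t2, imp,
                constrained=(method == "lirt"), **(lirt_options or {}),
            )
            est = mic_from_lirt(fit, conversion_n=conversion_n)
        else:
            fit = fit_lcfa_from_sample_data(
                sample.responses_t1, sample.responses_t2, imp,
                constrained=(method == "lcfa"),
            )
            est = mic_from_lcfa(fit, conversion_n=conversion_n)
        est.diagnostics["runtime_s"] = time.perf_counter() - t0
        out.append(est)
    return out


def run_study(
    grid,
    params: ItemParameters,
    methods=("mc", "roc", "pm", "apm"),
    n: int = 2000,
    master_seed: int = 0,
    conversion_n: int = 500_000,
    tr_reliability: float | str = "estimate",
    lirt_options: dict | None = None,
    checkpoint_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the factorial study over ``grid`` and return long results.

    Each sample's RNG stream is derived from (master_seed, cell index,
    replicate), so subsets of the grid reproduce the same samples as
    full runs.  With ``checkpoint_dir`` set, finished samples are
    written to per-sample CSV files and skipped on rerun.
    """
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for point in grid:
        tag = f"c{point.cell_index:04d}_r{point.replicate:02d}"
        if checkpoint_dir is not None:
            ck = checkpoint_dir / f"{tag}.csv"
            if ck.exists():
                frames.append(_normalize_results(pd.read_csv(ck)))
                continue
        seed = sample_seed(master_seed, point.cell_index, point.replicate)
        rng = np.random.default_rng(seed)
        sample = simulate_sample(point, params, n=n, rng=rng,
                                 conversion_n=conversion_n)
        rows = []
        for est in estimate_sample(sample, methods,
                                   tr_reliability=tr_reliability,
                                   conversion_n=conversion_n,
                                   lirt_options=lirt_options):
            row = point.as_dict()
            row.update(
                master_seed=master_seed,
                method=est.method,
                mic_prom=est.mic_prom,
                mic_latent=(np.nan if est.mic_latent is None else est.mic_latent),
                true_mic_prom=sample.true_mic_prom,
                residual=est.mic_prom - sample.true_mic_prom,
                converged=est.converged,
                reason=est.reason,
            )
            rows.append(row)
            logger.info(
                "sample=%s method=%s mic=%.4f converged=%s runtime=%.2fs",
                tag, est.method, est.mic_prom, est.converged,
                est.diagnostics.get("runtime_s", float("nan")),
            )
        frame = pd.DataFrame(rows)
        if checkpoint_dir is not None:
            frame.to_csv(checkpoint_dir / f"{tag}.csv", index=False,
                         float_format="%.12g")
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def summarize_performance(results: pd.DataFrame,
                          by=("method", "psb_mean")) -> pd.DataFrame:
    """Bias, residual SD and MSE per group, with Monte Carlo SEs.

    Uses the standard simulation-study formulas: MCSE(bias) =
    SD/sqrt(n); MCSE(SD) = SD/sqrt(2(n-1)); MCSE(MSE) =
    sqrt(sum((e_i^2 - MSE)^2) / (n(n-1))).  Non-converged estimates are
    excluded, with counts reported.
    """
    rows = []
    for key, group in results.groupby(list(by)):
        ok = group[group["converged"].astype(bool)]
        n_tot, n_ok = len(group), len(ok)
        if n_ok < 2:
            logger.warning("cell %s has %d converged results; omitted", key, n_ok)
            continue
        e = ok["residual"].to_numpy(float)
        bias = e.mean()
        sd = e.std(ddof=1)
        mse = np.mean(e ** 2)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n_simulations=n_ok,
            n_failed=n_tot - n_ok,
            bias=bias,
            mcse_bias=sd / np.sqrt(n_ok),
            sd=sd,
            mcse_sd=sd / np.sqrt(2.0 * (n_ok - 1)),
            mse=mse,
            mcse_mse=np.sqrt(np.sum((e ** 2 - mse) ** 2) / (n_ok * (n_ok - 1))),
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# residual meta-regression

def _term_formula(term: frozenset, categorical: bool) -> str:
    wrap = (lambda f: f"C({f})") if categorical else (lambda f: f)
    return ":".join(wrap(f) for f in sorted(term))


def _adj_r2(data: pd.DataFrame, terms, categorical: bool) -> float:
    if not terms:
        return 0.0
    rhs = " + ".join(_term_formula(t, categorical) for t in sorted(terms, key=sorted))
    fit = smf.ols(f"residual ~ {rhs}", data=data).fit()
    return float(fit.rsquared_adj)


def residual_regression(
    results: pd.DataFrame,
    method: str,
    max_order: int | None = None,
    threshold: float = 0.02,
    categorical: bool = True,
) -> dict:
    """Backward-selected OLS of MIC residuals on the design factors.

    Starts from all factors and all interactions (up to ``max_order``;
    by default every order the data can support) and repeatedly removes
    the maximal term whose removal costs the least adjusted R-squared,
    while that cost is below ``threshold``.  Marginality is respected: a
    term is only removable while no retained higher-order term contains
    it.  Returns the retained terms and the final adjusted R-squared.
    """
    data = results[(results["method"] == method)
                   & results["converged"].astype(bool)].copy()
    varying = [f for f in FACTORS if data[f].nunique() > 1]
    if not varying:
        raise ValueError("no design factor varies in the supplied results")
    levels = int(np.prod([data[f].nunique() for f in varying]))
    if max_order is None:
        max_order = len(varying)
        # keep the model below saturation
        while max_order > 1 and levels >= len(data):
            max_order -= 1
            levels = sum(
                int(np.prod([data[f].nunique() - 1 for f in t]))
                for t in _all_terms(varying, max_order)
            )
    terms = set(_all_terms(varying, max_order))
    current = _adj_r2(data, terms, categorical)
    while terms:
        maximal = [t for t in terms
                   if not any(t < other for other in terms)]
        drops = [(t, current - _adj_r2(data, terms - {t}, categorical))
                 for t in maximal]
        term, cost = min(drops, key=lambda kv: kv[1])
        if cost < threshold:
            terms.discard(term)
            current = _adj_r2(data, terms, categorical)
        else:
            break
    return {
        "method": method,
        "terms": sorted(["*".join(sorted(t)) for t in terms]),
        "adjusted_r2": current,
        "n": len(data),
    }


def _all_terms(factors, max_order):
    from itertools import combinations
    terms = []
    for order in range(1, max_order + 1):
        terms.extend(frozenset(c) for c in combinations(factors, order))
    return terms


# ---------------------------------------------------------------------------
# I/O

def _normalize_results(df: pd.DataFrame) -> pd.DataFrame:
    """Make CSV round-trips dtype-stable (factors float, reason string)."""
    for col in FACTORS + ["mic_prom", "mic_latent", "true_mic_prom", "residual"]:
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "reason" in df.columns:
        df["reason"] = df["reason"].fillna("").astype(str)
    return df


def save_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False, float_format="%.12g")


def load_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "reason" not in df.columns:
        df["reason"] = ""
    return _normalize_results(df)
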