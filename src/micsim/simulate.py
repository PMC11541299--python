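"""Factorial design and sample generation.

One simulated sample holds n = 2000 simulees with latent states at two
waves, individual change thresholds, a present-state-bias weight per
simulee, a perceived-change variable with a target reliability, a
5-category transition rating, and item responses at both waves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grm import ItemParameters, latent_to_prom_change, simulate_item_responses

__all__ = [
    "DesignPoint",
    "LatentState",
    "PsbWeights",
    "ThresholdSet",
    "SimulatedSample",
    "FACTOR_LEVELS",
    "build_design_grid",
    "solve_mean_latent_change",
    "draw_latents",
    "draw_q_weights",
    "weighted_change",
    "draw_thresholds",
    "perceive_and_rate",
    "simulate_sample",
    "sample_seed",
]

#: Factor levels of the full factorial design (3*3*2*3*2*6 = 648 cells).
FACTOR_LEVELS: dict[str, tuple] = {
    "theta1_mean": (-1.0, 0.0, 1.0),
    "delta_sd": (0.75, 1.0, 1.25),
    "cor_theta1_delta": (-0.50, 0.0),
    "prop_improved": (0.2, 0.5, 0.8),
    "tr_reliability": (0.3, 0.5),
    "psb_mean": (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
}

#: Mean personal thresholds between adjacent transition categories, on
#: the latent-change scale.  The third one is the individual MIC.
THRESHOLD_MEANS = (-1.5, -0.5, 0.5, 1.5)
THRESHOLD_SD = 0.075
MIC_LATENT_TRUE = 0.5


@dataclass(frozen=True)
class DesignPoint:
    theta1_mean: float
    delta_sd: float
    cor_theta1_delta: float
    prop_improved: float
    tr_reliability: float
    psb_mean: float
    cell_index: int = -1
    replicate: int = 0

    def __post_init__(self) -> None:
        for name, levels in FACTOR_LEVELS.items():
            value = getattr(self, name)
            if not any(np.isclose(value, lv) for lv in levels):
                raise ValueError(
                    f"{name}={value!r} not in allowed set {levels}"
                )

    def as_dict(self) -> dict:
        return asdict(self)


def build_design_grid(replicates: int = 5) -> list[DesignPoint]:
    """Full factorial cross of all factor levels, each cell replicated.

    Ordering is deterministic: cells vary slowest in ``theta1_mean`` and
    fastest in ``psb_mean``; replicates of a cell are adjacent.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = []
    for cell_index, values in enumerate(product(*FACTOR_LEVELS.values())):
        kwargs = dict(zip(FACTOR_LEVELS.keys(), values))
        for rep in range(replicates):
            grid.append(DesignPoint(cell_index=cell_index, replicate=rep, **kwargs))
    return grid


def sample_seed(master_seed: int, cell_index: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based per-sample seed: stable under grid subsetting."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index, replicate))


def solve_mean_latent_change(
    prop_improved: float,
    delta_sd: float,
    mic_mean: float = MIC_LATENT_TRUE,
    mic_sd: float = THRESHOLD_SD,
) -> float:
    """Mean of the latent change giving a target improved proportion.

    A simulee improves when their latent change exceeds their personal
    MIC.  With change ~ N(mu, delta_sd) and MIC ~ N(mic_mean, mic_sd)
    independent, P(improved) = Phi((mu - mic_mean) / sqrt(delta_sd^2 +
    mic_sd^2)), which inverts in closed form.
    """
    if not 0.0 < prop_improved < 1.0:
        raise ValueError("prop_improved must be in (0, 1)")
    spread = np.hypot(delta_sd, mic_sd)
    return float(mic_mean + norm.ppf(prop_improved) * spread)


@dataclass(frozen=True)
class LatentState:
    theta_t1: np.ndarray
    theta_t2: np.ndarray
    delta_theta: np.ndarray
    theta_t1_mean: float  # design-level (population) baseline mean

    def __post_init__(self) -> None:
        if not np.allclose(self.theta_t2 - self.theta_t1, self.delta_theta):
            raise ValueError("theta_t2 - theta_t1 must equal delta_theta")


def draw_latents(
    design: DesignPoint, n: int = 2000, rng: np.random.Generator | None = None
) -> LatentState:
    """Draw correlated baseline trait and latent change.

    theta_T1 ~ N(theta1_mean, 1).  The change is built from the
    standardized baseline draw plus an independent normal so the
    population correlation equals the design value and the change keeps
    its target mean and SD.
    """
    rng = np.random.default_rng() if rng is None else rng
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    theta_t1 = design.theta1_mean + z1
    r = design.cor_theta1_delta
    mu_delta = solve_mean_latent_change(design.prop_improved, design.delta_sd)
    delta = mu_delta + design.delta_sd * (r * z1 + np.sqrt(1.0 - r * r) * z2)
    return LatentState(
        theta_t1=theta_t1,
        theta_t2=theta_t1 + delta,
        delta_theta=delta,
        theta_t1_mean=design.theta1_mean,
    )


@dataclass(frozen=True)
class PsbWeights:
    q: np.ndarray
    q_mean: float

    @property
    def q_sd(self) -> float:
        return q_weight_sd(self.q_mean)


def q_weight_sd(q_mean: float) -> float:
    """SD of the per-simulee PSB weight: (0.5 - |0.5 - q_mean|) / 4."""
    return (0.5 - abs(0.5 - q_mean)) / 4.0


def draw_q_weights(
    q_mean: float, n: int, rng: np.random.Generator | None = None
) -> PsbWeights:
    """Normal weights around ``q_mean``, truncated by clipping to [0, 1]."""
    if not 0.0 <= q_mean <= 1.0:
        raise ValueError("q_mean must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    sd = q_weight_sd(q_mean)
    if sd == 0.0:
        q = np.full(n, float(q_mean))
    else:
        q = np.clip(rng.normal(q_mean, sd, size=n), 0.0, 1.0)
    return PsbWeights(q=q, q_mean=float(q_mean))


def weighted_change(latent: LatentState, weights: PsbWeights) -> np.ndarray:
    """Present-state-weighted change.

    A weight-q mixture of the follow-up state relative to the collective
    baseline reference point (the population baseline mean) and the true
    individual change:  q*(theta_T2 - mean_T1) + (1-q)*delta.
    """
    q = weights.q
    if q.shape != latent.delta_theta.shape:
        raise ValueError("q and latent vectors must have the same shape")
    present = latent.theta_t2 - latent.theta_t1_mean
    return q * present + (1.0 - q) * latent.delta_theta


@dataclass(frozen=True)
class ThresholdSet:
    """Personal thresholds between adjacent transition categories."""

    taus: np.ndarray  # (n, 4), columns tau1..tau4

    @property
    def individual_mic(self) -> np.ndarray:
        return self.taus[:, 2]


def draw_thresholds(
    n: int, rng: np.random.Generator | None = None, max_redraws: int = 100
) -> ThresholdSet:
    """Draw tau1..tau4 per simulee around (-1.5, -0.5, 0.5, 1.5), SD 0.075.

    With unit gaps and tiny SDs, crossed thresholds have negligible
    probability; any crossed row is redrawn so orderings always hold.
    """
    rng = np.random.default_rng() if rng is None else rng
    means = np.asarray(THRESHOLD_MEANS)
    taus = rng.normal(means, THRESHOLD_SD, size=(n, 4))
    for _ in range(max_redraws):
        bad = np.any(np.diff(taus, axis=1) <= 0, axis=1)
        if not bad.any():
            break
        taus[bad] = rng.normal(means, THRESHOLD_SD, size=(int(bad.sum()), 4))
    return ThresholdSet(taus=taus)


def perceive_and_rate(
    change: np.ndarray,
    reliability: float,
    thresholds: ThresholdSet,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add perception noise, then cut at the personal thresholds.

    The error SD is set from the sample SD of ``change`` so that
    var(change) / var(perceived) equals the target reliability.  The
    rating is 1 plus the number of personal thresholds the perceived
    change exceeds (1 = "Much worse" ... 5 = "Much better").
    """
    if not 0.0 < reliability <= 1.0:
        raise ValueError("reliability must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    sd_change = float(np.std(change, ddof=1))
    if sd_change <= 0:
        raise ValueError("change vector has zero variance")
    sigma_e = sd_change * np.sqrt((1.0 - reliability) / reliability)
    perceived = change + rng.normal(0.0, sigma_e, size=change.shape)
    rating = 1 + (perceived[:, None] > thresholds.taus).sum(axis=1)
    return perceived, rating.astype(np.int64)


@dataclass(frozen=True)
class SimulatedSample:
    design: DesignPoint
    latent: LatentState
    q: PsbWeights
    weighted: np.ndarray
    thresholds: ThresholdSet
    perceived: np.ndarray
    transition_rating: np.ndarray
    responses_t1: np.ndarray
    responses_t2: np.ndarray
    true_mic_prom: float
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.transition_rating.shape[0]

    @property
    def sum_t1(self) -> np.ndarray:
        return self.responses_t1.sum(axis=1)

    @property
    def sum_t2(self) -> np.ndarray:
        return self.responses_t2.sum(axis=1)

    @property
    def change_score(self) -> np.ndarray:
        return self.sum_t2 - self.sum_t1

    @property
    def improved(self) -> np.ndarray:
        """Dichotomized anchor: rating 4-5 vs 1-3."""
        return self.transition_rating >= 4


def simulate_sample(
    design: DesignPoint,
    params: ItemParameters,
    n: int = 2000,
    rng: np.random.Generator | int | None = None,
    conversion_n: int = 500_000,
    reference_mean: str = "population",
) -> SimulatedSample:
    """Generate one complete simulated sample for a design cell.

    The same item parameters are applied at both waves (no response
    shift).  The per-sample true MIC in sum-score points is the
    expected-score gain for a 0.5 latent improvement at the design's
    baseline trait distribution.  ``reference_mean`` selects the
    collective baseline reference point of the weighted change: the
    design-level population mean (default) or the realized sample mean.
    """
    if reference_mean not in ("population", "sample"):
        raise ValueError("reference_mean must be 'population' or 'sample'")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = None if rng is None else int(rng)
        rng = np.random.default_rng(rng)
    latent = draw_latents(design, n=n, rng=rng)
    if reference_mean == "sample":
        latent = LatentState(latent.theta_t1, latent.theta_t2,
                             latent.delta_theta,
                             theta_t1_mean=float(latent.theta_t1.mean()))
    weights = draw_q_weights(design.psb_mean, n=n, rng=rng)
    change_w = weighted_change(latent, weights)
    thresholds = draw_thresholds(n, rng=rng)
    perceived, rating = perceive_and_rate(
        change_w, design.tr_reliability, thresholds, rng=rng
    )
    responses_t1 = simulate_item_responses(latent.theta_t1, params, rng)
    responses_t2 = simulate_item_responses(latent.theta_t2, params, rng)
    true_mic = latent_to_prom_change(
        MIC_LATENT_TRUE, design.theta1_mean, 1.0, params, n=conversion_n
    )
    return SimulatedSample(
        design=design,
        latent=latent,
        q=weights,
        weighted=change_w,
        thresholds=thresholds,
        perceived=perceived,
        transition_rating=rating,
        responses_t1=responses_t1,
        responses_t2=responses_t2,
        true_mic_prom=true_mic,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization

def sample_to_frame(sample: SimulatedSample) -> pd.DataFrame:
    n_items = sample.responses_t1.shape[1]
    data = {
        "simulee": np.arange(sample.n),
        "theta_t1": sample.latent.theta_t1,
        "theta_t2": sample.latent.theta_t2,
        "delta_theta": sample.latent.delta_theta,
        "weighted_change": sample.weighted,
        "q": sample.q.q,
    }
    for k in range(4):
        data[f"tau{k + 1}"] = sample.thresholds.taus[:, k]
    data["perceived"] = sample.perceived
    data["tr"] = sample.transition_rating
    for j in range(n_items):
        data[f"item_t1_{j + 1}"] = sample.responses_t1[:, j]
    for j in range(n_items):
        data[f"item_t2_{j + 1}"] = sample.responses_t2[:, j]
    return pd.DataFrame(data)


def save_sample(sample: SimulatedSample, csv_path, meta_path=None) -> None:
    """Write a sample as CSV plus a JSON sidecar with design metadata."""
    csv_path = Path(csv_path)
    sample_to_frame(sample).to_csv(csv_path, index=False, float_format="%.12g")
    meta = {
        "design": sample.design.as_dict(),
        "seed": sample.seed,
        "true_mic_prom": sample.true_mic_prom,
        "n": sample.n,
    }
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_sample(csv_path, meta_path=None) -> SimulatedSample:
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    design = DesignPoint(**meta["design"])
    t1_cols = sorted((c for c in df.columns if c.startswith("item_t1_")),
                     key=lambda c: int(c.rsplit("_", 1)[1]))
    t2_cols = sorted((c for c in df.columns if c.startswith("item_t2_")),
                     key=lambda c: int(c.rsplit("_", 1)[1]))
    latent = LatentState(
        theta_t1=df["theta_t1"].to_numpy(),
        theta_t2=df["theta_t2"].to_numpy(),
        delta_theta=df["delta_theta"].to_numpy(),
        theta_t1_mean=design.theta1_mean,
    )
    return SimulatedSample(
        design=design,
        latent=latent,
        q=PsbWeights(q=df["q"].to_numpy(), q_mean=design.psb_mean),
        weighted=df["weighted_change"].to_numpy(),
        thresholds=ThresholdSet(df[[f"tau{k}" for k in range(1, 5)]].to_numpy()),
        perceived=df["perceived"].to_numpy(),
        transition_rating=df["tr"].to_numpy(np.int64),
        responses_t1=df[t1_cols].to_numpy(np.int64),
        responses_t2=df[t2_cols].to_numpy(np.int64),
        true_mic_prom=float(meta["true_mic_prom"]),
        seed=meta.get("seed"),
    )
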