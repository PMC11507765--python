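"""DMS-like synthetic data with known ground truth.

Generates assay score tables whose latent, type-specific quantile
distributions are truncated exponentials with known lambda* per ordered
replacement type, so the whole rank -> fit -> selection pipeline can be
validated end to end.  Two regimes are available:

``fitness``
    every type truncated-exponential, target means drawn uniformly over
    the observed span of real mean quantiles (default [0.22, 0.71], a
    ~3-fold dynamic range);
``stability``
    a designated ~1/5 of types instead draw from unimodal interior-mode
    (Beta-shaped) distributions, mimicking thermostability-like measures
    where the exponential law should be *rejected*.

Raw scores are produced by pushing latent quantiles through a monotone
overall scale map (default: logarithmic, heavy left tail — most mutations
deleterious).  Rank-based inference is invariant to this choice.  Because
the pooled within-assay score distribution mixes all types, re-ranked
quantiles deviate slightly from the latent ones; recovery tolerances in
the tests account for this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import AMINO_ACIDS, ORDERED_PAIRS, AssayTable
from .selection import LambdaMatrix, UPrediction, predict_U
from .truncexp import ScaleMap, TruncExpModel, fit_lambda_from_mean

__all__ = [
    "SyntheticScenario",
    "default_scale",
    "gen_lambda_matrix",
    "gen_assay",
    "gen_scenario_assays",
    "gen_stability_scenario",
    "gen_observed_U",
]

#: span of real mean quantiles the default generator mimics
DEFAULT_MEAN_RANGE = (0.22, 0.71)


def default_scale() -> ScaleMap:
    """Heavy-left-tailed monotone raw-score map, log(u): DMS fitness-like."""
    return ScaleMap(lambda u: np.log(np.clip(u, 1e-12, None)), _checked=True)


def gen_lambda_matrix(
    seed: int, mean_range: tuple[float, float] = DEFAULT_MEAN_RANGE
) -> LambdaMatrix:
    """Ground-truth lambda* for all 380 types from uniformly drawn means."""
    lo, hi = mean_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid mean range {mean_range}")
    rng = np.random.default_rng(seed)
    means = rng.uniform(lo, hi, size=len(ORDERED_PAIRS))
    entries = {
        pair: fit_lambda_from_mean(m).lambda_ for pair, m in zip(ORDERED_PAIRS, means)
    }
    return LambdaMatrix(entries, provenance=f"synthetic(seed={seed})")


@dataclass
class SyntheticScenario:
    """Specification of a synthetic DMS study set.

    Defaults give 20 assays x 19,000 mutations = 380,000 records, about
    1000 observations per type under uniform composition — matching the
    per-type depth of large aggregated DMS compilations.
    """

    lambda_star: LambdaMatrix
    seed: int
    n_assays: int = 20
    muts_per_assay: int = 19_000
    composition: dict[tuple[str, str], float] | None = None
    overall_scale: ScaleMap = field(default_factory=default_scale)
    regime: str = "fitness"
    #: filled only in the stability regime
    intermediate_types: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.regime not in ("fitness", "stability"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not self.lambda_star.complete:
            raise ValueError("lambda_star must cover all 380 ordered types")

    def composition_weights(self) -> np.ndarray:
        if self.composition is None:
            return np.full(len(ORDERED_PAIRS), 1.0 / len(ORDERED_PAIRS))
        w = np.array([self.composition.get(p, 0.0) for p in ORDERED_PAIRS])
        if w.sum() <= 0:
            raise ValueError("composition weights sum to zero")
        return w / w.sum()


def _beta_params(pair: tuple[str, str], rng: np.random.Generator) -> tuple[float, float]:
    """Interior-mode Beta shape for one stability-regime type."""
    mode = rng.uniform(0.3, 0.7)
    conc = 12.0
    return 1.0 + conc * mode, 1.0 + conc * (1.0 - mode)


def gen_assay(scenario: SyntheticScenario, assay_index: int) -> AssayTable:
    """One synthetic assay table, deterministic given (seed, assay_index).

    Each mutation draws its type from the composition weights and its
    latent quantile from that type's ground-truth distribution; the raw
    score is the scale map applied to the latent quantile.  Variant
    positions are sequential, so every row is a valid single missense.
    """
    rng = np.random.default_rng([scenario.seed, assay_index])
    m = scenario.muts_per_assay
    weights = scenario.composition_weights()
    type_idx = rng.choice(len(ORDERED_PAIRS), size=m, p=weights)
    u = np.empty(m)
    beta_rng = np.random.default_rng([scenario.seed, 10_007])
    beta_shapes = {
        pair: _beta_params(pair, beta_rng) for pair in sorted(scenario.intermediate_types)
    }
    for t in np.unique(type_idx):
        pair = ORDERED_PAIRS[t]
        mask = type_idx == t
        if pair in beta_shapes:
            a, b = beta_shapes[pair]
            u[mask] = rng.beta(a, b, size=mask.sum())
        else:
            model = TruncExpModel(scenario.lambda_star.entries[pair])
            u[mask] = model.ppf(rng.random(mask.sum()))
    scores = np.asarray(scenario.overall_scale(u), dtype=float)
    from_aa = np.array([p[0] for p in ORDERED_PAIRS])[type_idx]
    to_aa = np.array([p[1] for p in ORDERED_PAIRS])[type_idx]
    positions = np.arange(1, m + 1)
    variants = pd.Series(from_aa) + pd.Series(positions).astype(str) + pd.Series(to_aa)
    return AssayTable(
        assay_id=f"synth_{scenario.seed}_{assay_index:03d}",
        records=list(zip(variants.tolist(), scores.tolist())),
        higher_is_fitter=True,
    )


def gen_scenario_assays(scenario: SyntheticScenario) -> list[AssayTable]:
    """All assays of a scenario."""
    return [gen_assay(scenario, i) for i in range(scenario.n_assays)]


def gen_stability_scenario(
    seed: int,
    n_assays: int = 20,
    muts_per_assay: int = 19_000,
    intermediate_fraction: float = 0.2,
) -> SyntheticScenario:
    """Stability-regime scenario: ~1/5 of types get interior-mode DFEs.

    The designated types draw latent quantiles from unimodal Beta humps
    with modes in [0.3, 0.7]; the remainder stay truncated-exponential.
    Used to verify that the split-half fit test rejects the exponential
    law where it should.
    """
    rng = np.random.default_rng([seed, 4242])
    n_mid = int(round(intermediate_fraction * len(ORDERED_PAIRS)))
    chosen = rng.choice(len(ORDERED_PAIRS), size=n_mid, replace=False)
    return SyntheticScenario(
        lambda_star=gen_lambda_matrix(seed),
        seed=seed,
        n_assays=n_assays,
        muts_per_assay=muts_per_assay,
        regime="stability",
        intermediate_types=frozenset(ORDERED_PAIRS[i] for i in chosen),
    )


def gen_observed_U(
    lm: LambdaMatrix, q: float, noise_cv: float, seed: int
) -> pd.DataFrame:
    """Noisy observed-exchangeability table for end-to-end comparison tests.

    predict_U entries are multiplied by independent lognormal noise with
    coefficient of variation ``noise_cv`` and re-centered to mean 1.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    pred = predict_U(lm, q)
    u = pred.u_pred.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=u.size)
        u = u * noise
    u = u / u.mean()
    return pd.DataFrame(
        {"aa1": [p[0] for p in pred.pairs], "aa2": [p[1] for p in pred.pairs], "U": u}
    )
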