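"""Statistical characterization of the 380 type-specific DFEs.

For each ordered replacement type this module asks: is the quantile
distribution distinguishable from uniform (i.e. from the background DFE)?
Does it follow the fitted truncated exponential (tested split-half to
avoid testing against a distribution fitted on the same data)?  Is the
binned histogram monotone?  And for each unordered pair, do the forward
and reverse directions differ?  All p-values are Bonferroni-corrected
within their family (380 per-type tests, 190 direction-asymmetry tests).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .truncexp import ConvergenceError, TruncExpModel, fit_lambda_from_mean

__all__ = [
    "DFETestReport",
    "ks_one_sample",
    "ks_two_sample",
    "split_half_fit_test",
    "monotonicity_score",
    "bonferroni",
    "summarize_all",
]

#: Bonferroni family sizes: per-type tests and unordered-pair asymmetry tests
FAMILY_TYPES = 380
FAMILY_PAIRS = 190


def ks_one_sample(sample, cdf: Callable) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fully specified CDF.

    D is the supremum gap between the empirical CDF and ``cdf``; the
    p-value is from the asymptotic Kolmogorov distribution (per-type
    samples run to the hundreds or thousands).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_1samp(sample, cdf, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS test (asymptotic p-value)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def split_half_fit_test(quantiles, seed: int) -> tuple[float, float, float]:
    """Goodness of fit to the truncated exponential, without double-dipping.

    A random (seeded) half of the sample estimates the mean, which fixes
    lambda; the held-out half is KS-tested against the fitted CDF.  With
    odd n the estimation half gets the extra point.

    Returns ``(lambda_hat, D, p)``.
    """
    q = np.asarray(quantiles, dtype=float)
    n = q.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_est = (n + 1) // 2
    est, test = q[perm[:n_est]], q[perm[n_est:]]
    model = fit_lambda_from_mean(float(est.mean()))
    d, p = ks_one_sample(test, model.cdf)
    return model.lambda_, d, p


def monotonicity_score(sample, nbins: int = 15) -> float:
    """|Spearman correlation| between bin order and bin counts.

    The sample is histogrammed into ``nbins`` equal-width, right-closed
    bins on [0, 1] (values of exactly 1.0 fall in the last bin); 1.0 means
    the histogram rises or falls strictly monotonically, 0 means bin order
    carries no information about bin occupancy.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    q = np.asarray(sample, dtype=float)
    # right-closed bins: value v goes to bin ceil(v*nbins)-1
    idx = np.clip(np.ceil(q * nbins).astype(int) - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    if np.all(counts == counts[0]):
        return 0.0
    rho = sps.spearmanr(np.arange(1, nbins + 1), counts).statistic
    return float(abs(rho))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value min(1, p*m) for a family of m tests."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * m)


@dataclass
class DFETestReport:
    """Full test battery result for one ordered replacement type."""

    from_aa: str
    to_aa: str
    n: int
    mean_quantile: float
    lambda_hat: float
    ks_uniform_D: float
    ks_uniform_p_bonf: float
    fit_lambda_half: float
    fit_D: float
    fit_p_bonf: float
    monotonicity: float
    asym_D: float
    asym_p_bonf: float


def _uniform_cdf(x):
    return np.clip(x, 0.0, 1.0)


def summarize_all(
    dfes: Mapping[tuple[str, str], "TypeDFE"],
    seed: int,
    nbins: int = 15,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Run the whole battery over a pooled DFE map.

    Returns one report row per ordered type present plus an aggregate
    summary (uniform-indistinguishable count, median KS-vs-uniform D,
    median monotonicity, asymmetric pair count, split-half fit pass
    fraction, mean-quantile span, total record count).  Per-type split
    halves derive child seeds from ``seed`` in sorted pair order, so the
    whole battery is deterministic.
    """
    if not dfes:
        raise ValueError("no DFEs supplied")
    master = np.random.default_rng(seed)
    pairs = sorted(dfes)
    child_seed = {p: int(master.integers(2**31)) for p in pairs}

    rows: list[DFETestReport] = []
    asym: dict[frozenset, tuple[float, float]] = {}
    for a, b in pairs:
        key = frozenset((a, b))
        if key not in asym and (b, a) in dfes and a != b:
            d, p = ks_two_sample(dfes[(a, b)].quantiles, dfes[(b, a)].quantiles)
            asym[key] = (d, bonferroni(p, FAMILY_PAIRS))
    for a, b in pairs:
        q = dfes[(a, b)].quantiles
        n = q.size
        mean_q = float(q.mean())
        d_u, p_u = ks_one_sample(q, _uniform_cdf)
        try:
            lam_hat = fit_lambda_from_mean(mean_q).lambda_
        except (ValueError, ConvergenceError):
            lam_hat = np.nan
        if n >= 4:
            lam_half, d_fit, p_fit = split_half_fit_test(q, child_seed[(a, b)])
            p_fit_b = bonferroni(p_fit, FAMILY_TYPES)
        else:
            lam_half = d_fit = p_fit_b = np.nan
        d_a, p_a = asym.get(frozenset((a, b)), (np.nan, np.nan))
        rows.append(
            DFETestReport(
                from_aa=a,
                to_aa=b,
                n=n,
                mean_quantile=mean_q,
                lambda_hat=lam_hat,
                ks_uniform_D=d_u,
                ks_uniform_p_bonf=bonferroni(p_u, FAMILY_TYPES),
                fit_lambda_half=lam_half,
                fit_D=d_fit,
                fit_p_bonf=p_fit_b,
                monotonicity=monotonicity_score(q, nbins=nbins),
                asym_D=d_a,
                asym_p_bonf=p_a,
            )
        )
    reports = pd.DataFrame([asdict(r) for r in rows])
    fit_ok = reports["fit_p_bonf"].dropna()
    aggregate = {
        "n_types": int(len(reports)),
        "total_records": int(reports["n"].sum()),
        "n_uniform_indistinguishable": int((reports["ks_uniform_p_bonf"] > alpha).sum()),
        "median_ks_uniform_D": float(reports["ks_uniform_D"].median()),
        "median_monotonicity": float(reports["monotonicity"].median()),
        "n_pairs_tested_asym": int(len(asym)),
        "n_asymmetric": int(sum(p < alpha for _, p in asym.values())),
        "fit_pass_fraction": float((fit_ok > alpha).mean()) if len(fit_ok) else np.nan,
        "mean_quantile_min": float(reports["mean_quantile"].min()),
        "mean_quantile_max": float(reports["mean_quantile"].max()),
    }
    return reports, aggregate
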