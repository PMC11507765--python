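"""Threshold model of purifying selection and exchangeability prediction.

Selection is modeled as a sharp stringency threshold q in [0, 1):
replacements with fitness quantile below q are rejected, those above are
accepted.  For a replacement type whose quantile DFE is truncated
exponential with parameter lambda, the normalized substitution rate
(the type-specific analog of Ka/Ks) is

    K_lambda/K_s(q) = (1 - e^(-2(1-q)(-lambda))) / (1 - e^(-2(-lambda))),

formally the Kimura fixation probability with scaled selection
coefficient -2*lambda and initial frequency 1-q.  As q -> 1 the ratio
K_lambda/K_s / (1-q) converges to 2(-lambda)/(1 - e^(-2(-lambda))):
benign-leaning types (lambda < 0) are linearly enriched, deleterious
types exponentially depleted.

Combining the forward and reverse rates of a pair by their harmonic mean,
over the 75 amino-acid pairs reachable by a single-nucleotide change in
the standard genetic code, predicts the relative exchangeability index U
(conventionally centered so the 75 entries average 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .ingest import AMINO_ACIDS, ORDERED_PAIRS

__all__ = [
    "Q_NEAR_ONE",
    "LambdaMatrix",
    "UPrediction",
    "k_ratio",
    "k_ratio_limit",
    "singlet_pairs",
    "predict_U",
    "compare_U",
    "read_observed_u",
    "write_u_table",
]

#: default operationalization of the q -> 1 limit
Q_NEAR_ONE = 1.0 - 1e-6


def _check_q(q: float) -> float:
    q = float(q)
    if not (0.0 <= q < 1.0):
        raise ValueError(f"stringency q must lie in [0, 1), got {q}")
    return q


def k_ratio(lambda_: float, q: float) -> float:
    """Normalized substitution rate K_lambda/K_s at stringency q.

    Equals 1 at q=0 (no selection) and (1-q) at lambda=0 (neutral type).
    Strictly decreasing in both lambda and q.
    """
    q = _check_q(q)
    lam = float(lambda_)
    if lam == 0.0:
        return 1.0 - q
    a = 2.0 * lam * (1.0 - q)
    b = 2.0 * lam
    if lam > 0.0:
        # expm1(a)/expm1(b) = e^(a-b) * (1-e^-a)/(1-e^-b); overflow-safe
        return math.exp(a - b) * math.expm1(-a) / math.expm1(-b)
    return math.expm1(a) / math.expm1(b)


def k_ratio_limit(lambda_: float) -> float:
    """The q->1 limit of k_ratio(lambda, q)/(1-q): 2(-lambda)/(1-e^(2 lambda))."""
    lam = float(lambda_)
    if lam == 0.0:
        return 1.0
    try:
        return 2.0 * lam / math.expm1(2.0 * lam)
    except OverflowError:
        return 0.0


def singlet_pairs(codon_table: CodonTable.CodonTable | None = None) -> frozenset:
    """Unordered amino-acid pairs interchangeable by one nucleotide change.

    Enumerates all sense-codon pairs of the given code (default: the
    standard code, NCBI table 1) differing at exactly one position; stop
    codons contribute nothing.  For the standard code there are 75 pairs.
    """
    table = codon_table or CodonTable.unambiguous_dna_by_id[1]
    fwd = table.forward_table
    if not fwd or any(len(c) != 3 for c in fwd):
        raise ValueError("malformed codon table")
    codons = list(fwd)
    pairs = set()
    for c1 in codons:
        for c2 in codons:
            if sum(x != y for x, y in zip(c1, c2)) == 1 and fwd[c1] != fwd[c2]:
                pairs.add(frozenset((fwd[c1], fwd[c2])))
    return frozenset(pairs)


#: the 75 singlet pairs of the standard code, as sorted letter tuples
SINGLET_PAIRS = tuple(sorted(tuple(sorted(p)) for p in singlet_pairs()))


@dataclass
class LambdaMatrix:
    """Fitted lambda for each of the 380 ordered replacement types."""

    entries: dict[tuple[str, str], float]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = [k for k in self.entries if k not in ORDERED_PAIRS]
        if bad:
            raise ValueError(f"invalid ordered pairs: {bad[:5]}")

    @property
    def complete(self) -> bool:
        return len(self.entries) == len(ORDERED_PAIRS)

    def to_frame(self) -> pd.DataFrame:
        """20x20 layout: rows = wild-type, columns = mutant, diagonal empty."""
        aa = list(AMINO_ACIDS)
        frame = pd.DataFrame(np.nan, index=aa, columns=aa)
        for (a, b), lam in self.entries.items():
            frame.loc[a, b] = lam
        frame.index.name = "from_aa"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "LambdaMatrix":
        entries = {}
        for a in frame.index:
            for b in frame.columns:
                v = frame.loc[a, b]
                if a != b and pd.notna(v):
                    entries[(a, b)] = float(v)
        return cls(entries, provenance)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, provenance: str | None = None) -> "LambdaMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame, provenance or str(path))


@dataclass
class UPrediction:
    """Predicted exchangeability over the 75 singlet pairs at stringency q.

    ``u_pred`` is centered so that the mean over the 75 pairs is exactly 1,
    matching the published scaling convention.
    """

    pairs: tuple[tuple[str, str], ...]
    u_pred: np.ndarray = field(repr=False)
    q_used: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aa1": [p[0] for p in self.pairs],
                "aa2": [p[1] for p in self.pairs],
                "U": self.u_pred,
                "q": self.q_used,
            }
        )

    @property
    def dynamic_range(self) -> float:
        return float(self.u_pred.max() / self.u_pred.min())


def predict_U(lm: LambdaMatrix, q: float) -> UPrediction:
    """Predict U for the 75 singlet pairs from a fitted lambda matrix.

    Each pair's raw value is the harmonic mean of the forward and reverse
    k_ratio; the 75 raw values are then divided by their mean.
    """
    q = _check_q(q)
    raw = []
    for a, b in SINGLET_PAIRS:
        for direction in ((a, b), (b, a)):
            if direction not in lm.entries:
                raise ValueError(
                    f"lambda matrix missing direction {direction[0]}->{direction[1]}"
                )
        kf = k_ratio(lm.entries[(a, b)], q)
        kr = k_ratio(lm.entries[(b, a)], q)
        raw.append(2.0 / (1.0 / kf + 1.0 / kr))
    u = np.asarray(raw)
    return UPrediction(SINGLET_PAIRS, u / u.mean(), q)


def compare_U(
    pred: UPrediction, observed: Mapping[tuple[str, str], float] | pd.DataFrame
) -> tuple[float, float, float]:
    """Pearson r and dynamic ranges of predicted vs observed U.

    ``observed`` maps unordered singlet pairs (sorted letter tuples) to U,
    or is a DataFrame with columns aa1, aa2, U.  Returns
    ``(pearson_r, range_pred, range_obs)`` where range = max/min.
    """
    if isinstance(observed, pd.DataFrame):
        observed = {
            tuple(sorted((r.aa1, r.aa2))): float(r.U) for r in observed.itertuples()
        }
    pred_keys = set(pred.pairs)
    obs_keys = {tuple(sorted(k)) for k in observed}
    if pred_keys != obs_keys:
        missing = sorted(pred_keys - obs_keys)
        extra = sorted(obs_keys - pred_keys)
        raise ValueError(f"pair-set mismatch; missing={missing} extra={extra}")
    obs = np.array([observed[tuple(sorted(p))] for p in pred.pairs])
    r = float(np.corrcoef(pred.u_pred, obs)[0, 1])
    return r, pred.dynamic_range, float(obs.max() / obs.min())


def read_observed_u(path) -> pd.DataFrame:
    """Observed-U TSV with columns aa1, aa2, U."""
    df = pd.read_csv(path, sep="\t")
    for col in ("aa1", "aa2", "U"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_u_table(pred: UPrediction, path) -> None:
    pred.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
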