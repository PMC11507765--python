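"""Parsing and rank-normalization of deep mutational scanning assays.

Each assay measures raw effect scores for protein variants on its own
scale.  Scores are converted to within-assay percentile ranks (average
tie-breaking), giving quantiles in (0, 1] with 1 = fittest, so assays with
arbitrary measurement scales can be pooled.  Pooling groups quantiles by
the ordered amino-acid replacement type (e.g. A->V), producing up to
20*19 = 380 type-specific DFE samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ORDERED_PAIRS",
    "Replacement",
    "VariantError",
    "AssayTable",
    "TypeDFE",
    "parse_variant",
    "filter_single_missense",
    "percentile_rank",
    "rank_assay",
    "pool_by_type",
    "balance_resample",
    "read_assay_csv",
    "DIALECTS",
]

#: canonical one-letter codes, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: the 380 ordered (wild-type, mutant) pairs, lexicographic
ORDERED_PAIRS = tuple(
    (a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS if a != b
)

_VARIANT_RE = re.compile(r"^([A-Za-z*])(\d+)([A-Za-z*])$")


class Replacement(NamedTuple):
    """A single amino-acid substitution in 1-based protein coordinates."""

    from_aa: str
    position: int
    to_aa: str


class VariantError(ValueError):
    """Variant string not a usable single missense substitution.

    ``reason`` is one of ``"malformed"``, ``"position"``, ``"stop"``,
    ``"synonymous"``, ``"multiple"`` so callers can tally why records drop.
    """

    def __init__(self, token: str, reason: str):
        super().__init__(f"variant {token!r}: {reason}")
        self.token = token
        self.reason = reason


def parse_variant(s: str) -> Replacement:
    """Parse a ``"A24G"``-style variant string into a :class:`Replacement`.

    Raises :class:`VariantError` for anything that is not a single,
    non-synonymous substitution between the 20 standard amino acids;
    ``err.reason`` flags synonymous, stop-containing and multi-mutant
    strings for downstream removal tallies.
    """
    if ":" in s:
        raise VariantError(s, "multiple")
    m = _VARIANT_RE.match(s.strip())
    if m is None:
        raise VariantError(s, "malformed")
    from_aa, pos, to_aa = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if from_aa == "*" or to_aa == "*":
        raise VariantError(s, "stop")
    if from_aa not in AMINO_ACIDS or to_aa not in AMINO_ACIDS:
        raise VariantError(s, "malformed")
    if pos < 1:
        raise VariantError(s, "position")
    if from_aa == to_aa:
        raise VariantError(s, "synonymous")
    return Replacement(from_aa, pos, to_aa)


def filter_single_missense(
    records: Iterable[tuple[str, float]],
) -> tuple[list[tuple[Replacement, float]], dict[str, int]]:
    """Keep single-site, non-synonymous, standard-alphabet substitutions.

    Returns the retained ``(Replacement, score)`` list and a tally of
    dropped records keyed by drop reason.
    """
    kept: list[tuple[Replacement, float]] = []
    dropped: dict[str, int] = {}
    for variant, score in records:
        try:
            kept.append((parse_variant(variant), float(score)))
        except VariantError as err:
            dropped[err.reason] = dropped.get(err.reason, 0) + 1
    return kept, dropped


def percentile_rank(scores: Sequence[float]) -> np.ndarray:
    """Average-tie percentile ranks: (average rank)/n, values in (0, 1].

    Order-preserving; equal scores receive equal quantiles.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 scores to rank")
    return (s.rank(method="average") / len(s)).to_numpy()


@dataclass
class AssayTable:
    """One DMS experiment: variant strings with raw scores.

    ``higher_is_fitter`` states the score polarity; when False, ranking is
    performed on negated scores so that quantile 1 is always the fittest.
    """

    assay_id: str
    records: list[tuple[str, float]]
    higher_is_fitter: bool = True

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(f"assay {self.assay_id!r}: at least 2 records required")


def rank_assay(assay: AssayTable) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter to single missense variants and percentile-rank within assay.

    Returns a long DataFrame (assay_id, from_aa, to_aa, position, quantile)
    and the drop tally.  Filtering happens *before* ranking so that
    synonymous/multi-mutant rows do not influence the quantiles.
    """
    kept, dropped = filter_single_missense(assay.records)
    if len(kept) < 2:
        return (
            pd.DataFrame(columns=["assay_id", "from_aa", "to_aa", "position", "quantile"]),
            dropped,
        )
    scores = np.array([score for _, score in kept])
    if not assay.higher_is_fitter:
        scores = -scores
    q = percentile_rank(scores)
    return (
        pd.DataFrame(
            {
                "assay_id": assay.assay_id,
                "from_aa": [r.from_aa for r, _ in kept],
                "to_aa": [r.to_aa for r, _ in kept],
                "position": [r.position for r, _ in kept],
                "quantile": q,
            }
        ),
        dropped,
    )


@dataclass
class TypeDFE:
    """Pooled quantile sample for one ordered replacement type."""

    pair: tuple[str, str]
    quantiles: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        if np.any(self.quantiles <= 0.0) or np.any(self.quantiles > 1.0):
            raise ValueError("quantiles must lie in (0, 1]")

    @property
    def n(self) -> int:
        return len(self.quantiles)

    @property
    def mean_quantile(self) -> float:
        return float(self.quantiles.mean())


def pool_by_type(
    assays: Iterable[AssayTable],
) -> tuple[dict[tuple[str, str], TypeDFE], pd.DataFrame, dict[str, int]]:
    """Rank each assay independently and pool quantiles by ordered type.

    Returns the per-type DFE map, the concatenated long table, and the
    summed drop tally.  Total pooled count equals total retained records.
    """
    frames = []
    dropped: dict[str, int] = {}
    for assay in assays:
        frame, d = rank_assay(assay)
        frames.append(frame)
        for k, v in d.items():
            dropped[k] = dropped.get(k, 0) + v
    long = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["assay_id", "from_aa", "to_aa", "position", "quantile"])
    )
    dfes = {
        (fa, ta): TypeDFE((fa, ta), grp["quantile"].to_numpy())
        for (fa, ta), grp in long.groupby(["from_aa", "to_aa"], sort=True)
    }
    return dfes, long, dropped


def balance_resample(
    assays: Sequence[AssayTable], mode: str, seed: int
) -> list[AssayTable]:
    """Equalize per-type representation within each assay.

    ``mode="up"`` samples every type with replacement up to the assay's
    maximum per-type count; ``mode="down"`` samples without replacement
    down to the minimum.  Requires the pooled assays to cover all 380
    types.  Deterministic given ``seed``.
    """
    if mode not in ("up", "down"):
        raise ValueError(f"mode must be 'up' or 'down', got {mode!r}")
    parsed_all: list[list[tuple[tuple[str, str], str, float]]] = []
    covered: set[tuple[str, str]] = set()
    for assay in assays:
        kept, _ = filter_single_missense(assay.records)
        rows = [
            ((r.from_aa, r.to_aa), f"{r.from_aa}{r.position}{r.to_aa}", s)
            for r, s in kept
        ]
        parsed_all.append(rows)
        covered.update(p for p, _, _ in rows)
    missing = sorted(set(ORDERED_PAIRS) - covered)
    if missing:
        raise ValueError(
            f"assays do not cover all 380 types; missing {len(missing)}: "
            + ", ".join(f"{a}->{b}" for a, b in missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    rng = np.random.default_rng(seed)
    out: list[AssayTable] = []
    for assay, rows in zip(assays, parsed_all):
        by_type: dict[tuple[str, str], list[tuple[str, float]]] = {}
        for pair, variant, score in rows:
            by_type.setdefault(pair, []).append((variant, score))
        counts = [len(v) for v in by_type.values()]
        target = max(counts) if mode == "up" else min(counts)
        new_records: list[tuple[str, float]] = []
        for pair in sorted(by_type):
            recs = by_type[pair]
            idx = rng.choice(len(recs), size=target, replace=(mode == "up"))
            new_records.extend(recs[i] for i in idx)
        out.append(AssayTable(assay.assay_id, new_records, higher_is_fitter=True))
    return out


#: named CSV dialects -> (variant column, score column)
DIALECTS = {
    "generic": ("mutant", "score"),
    "proteingym": ("mutant", "DMS_score"),
}


def read_assay_csv(
    path,
    assay_id: str | None = None,
    dialect: str = "generic",
    variant_col: str | None = None,
    score_col: str | None = None,
    higher_is_fitter: bool = True,
) -> AssayTable:
    """Load one assay from a headered CSV/TSV file.

    The ``proteingym`` dialect reads the ``mutant``/``DMS_score`` column
    pair; column names can also be overridden directly.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    vcol, scol = DIALECTS[dialect]
    vcol = variant_col or vcol
    scol = score_col or scol
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (vcol, scol):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = list(zip(df[vcol].astype(str), df[scol].astype(float)))
    return AssayTable(assay_id or path.stem, records, higher_is_fitter=higher_is_fitter)
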