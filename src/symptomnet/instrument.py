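"""Scoring and screening logic for the Middle School Student Mental Health
Test (MHT).

The MHT is a 100-item, 0/1-scored questionnaire for Chinese middle- and
high-school students.  Ninety items form eight content subscales (learning
anxiety, social anxiety, loneliness, self-blame, allergy/over-sensitivity,
somatic symptoms, phobic tendency, impulsive tendency); the remaining ten
items form a lie (validity) scale.  A subscale score of 8 or more marks a
clear tendency toward psychological problems, 3 or less marks none.  The
total of the eight content scores grades overall mental health: 0-55 normal,
56-64 poor, 65 and above severe.  Protocols with a lie score in [7, 10] are
considered unreliable and excluded.

The authentic item key is proprietary; :func:`default_instrument_spec`
ships a documented stand-in layout (contiguous blocks, 90 content + 10 lie
items) that can be overridden with the real key via :class:`InstrumentSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "InstrumentSpec",
    "ItemResponseMatrix",
    "SubscaleScoreTable",
    "ExclusionReport",
    "default_instrument_spec",
    "score_responses",
    "apply_exclusions",
    "classify_total",
    "flag_subscale",
    "descriptive_stats",
    "percentage",
    "read_responses_csv",
    "write_scores_csv",
]

#: Grade labels for the total score.
GRADE_NORMAL = "normal"
GRADE_POOR = "poor"
GRADE_SEVERE = "severe"

#: Flag labels for a single subscale score.
FLAG_CLEAR = "clear_tendency"
FLAG_INTERMEDIATE = "intermediate"
FLAG_NONE = "no_tendency"

#: Lie-scale validity window: a score in this closed interval invalidates
#: the protocol.
LIE_INVALID_LOW = 7
LIE_INVALID_HIGH = 10

#: Subscale flag cutoffs.
FLAG_CUTOFF = 8
NO_TENDENCY_CUTOFF = 3

#: Total-score grade boundaries (content items only; lie excluded).
POOR_LOW, POOR_HIGH = 56, 64


@dataclass(frozen=True)
class InstrumentSpec:
    """Item-to-scale key of the instrument.

    Parameters
    ----------
    subscale_names : sequence of str
        Ordered labels of the eight content subscales.
    items_per_subscale : mapping label -> list of 1-based item indices
    lie_items : list of 1-based item indices of the validity scale
    total_items : int
        Number of questionnaire columns (100 for the MHT).
    """

    subscale_names: tuple[str, ...]
    items_per_subscale: Mapping[str, tuple[int, ...]]
    lie_items: tuple[int, ...]
    total_items: int = 100

    def __post_init__(self) -> None:
        if len(self.subscale_names) != 8:
            raise ValueError(
                f"expected 8 content subscales, got {len(self.subscale_names)}"
            )
        seen: set[int] = set()
        for label in self.subscale_names:
            items = self.items_per_subscale[label]
            if seen & set(items):
                raise ValueError(f"subscale {label!r} overlaps another scale")
            seen |= set(items)
        if seen & set(self.lie_items):
            raise ValueError("lie scale overlaps a content subscale")
        seen |= set(self.lie_items)
        if seen != set(range(1, self.total_items + 1)):
            raise ValueError(
                "item indices must partition 1..%d exactly" % self.total_items
            )

    @property
    def n_content_items(self) -> int:
        return self.total_items - len(self.lie_items)

    def subscale_sizes(self) -> dict[str, int]:
        return {k: len(self.items_per_subscale[k]) for k in self.subscale_names}

    def column_indices(self, label: str) -> np.ndarray:
        """0-based response-matrix columns of a subscale (or 'lie')."""
        items = self.lie_items if label == "lie" else self.items_per_subscale[label]
        return np.asarray(items, dtype=int) - 1


def default_instrument_spec() -> InstrumentSpec:
    """Stand-in MHT key: contiguous item blocks.

    Learning anxiety and somatic symptoms get 15 items each (their printed
    means reach ~9 on a 0-15 support); the other six content subscales get
    10; the last 10 items form the lie scale.  Replace with the authentic
    key for real data.
    """
    names = tuple(f"MHT{i}" for i in range(1, 9))
    sizes = (15, 10, 10, 10, 10, 15, 10, 10)
    items: dict[str, tuple[int, ...]] = {}
    start = 1
    for name, size in zip(names, sizes):
        items[name] = tuple(range(start, start + size))
        start += size
    lie = tuple(range(start, start + 10))
    return InstrumentSpec(names, items, lie, total_items=100)


@dataclass
class ItemResponseMatrix:
    """Per-participant 0/1 item answers; missing entries stored as NaN."""

    participant_ids: list
    responses: np.ndarray  # n x total_items float array, NaN = missing
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D matrix")
        if len(self.participant_ids) != self.responses.shape[0]:
            raise ValueError("participant_ids length mismatch")

    @property
    def n(self) -> int:
        return self.responses.shape[0]


@dataclass
class SubscaleScoreTable:
    """Eight content subscale scores plus lie and total per participant.

    The total is the sum of the eight content scores; the lie score never
    enters it.
    """

    participant_ids: list
    scores: pd.DataFrame  # n x 8, integer, columns = subscale names
    lie_score: np.ndarray
    total_score: np.ndarray

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    @property
    def node_labels(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.insert(0, "id", self.participant_ids)
        out["lie"] = self.lie_score
        out["total"] = self.total_score
        out["grade"] = [classify_total(int(t)) for t in self.total_score]
        return out


@dataclass
class ExclusionReport:
    """Bookkeeping of the screening step (incomplete first, then lie)."""

    n_received: int
    n_incomplete: int
    n_lie_invalid: int

    @property
    def n_retained(self) -> int:
        return self.n_received - self.n_incomplete - self.n_lie_invalid

    @property
    def effective_rate(self) -> float:
        if self.n_received == 0:
            return 0.0
        return 100.0 * self.n_retained / self.n_received

    def to_dict(self) -> dict:
        return {
            "n_received": self.n_received,
            "n_incomplete": self.n_incomplete,
            "n_lie_invalid": self.n_lie_invalid,
            "n_retained": self.n_retained,
            "effective_rate": round(self.effective_rate, 2),
        }


def score_responses(
    responses: ItemResponseMatrix, spec: InstrumentSpec
) -> SubscaleScoreTable:
    """Sum 0/1 items into subscale scores.

    Expects a complete (exclusion already applied) binary matrix.  Raises
    ``ValueError`` naming the offending cell for non-binary entries and for
    a column-count mismatch.
    """
    X = responses.responses
    if X.shape[1] != spec.total_items:
        raise ValueError(
            f"expected {spec.total_items} item columns, got {X.shape[1]}"
        )
    bad = ~np.isin(X, (0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary response at row {r}, item {c + 1}: {X[r, c]!r}"
        )
    cols = {}
    for name in spec.subscale_names:
        cols[name] = X[:, spec.column_indices(name)].sum(axis=1).astype(int)
    scores = pd.DataFrame(cols, columns=list(spec.subscale_names))
    lie = X[:, spec.column_indices("lie")].sum(axis=1).astype(int)
    total = scores.to_numpy().sum(axis=1)
    return SubscaleScoreTable(
        participant_ids=list(responses.participant_ids),
        scores=scores,
        lie_score=lie,
        total_score=total,
    )


def apply_exclusions(
    responses: ItemResponseMatrix, spec: InstrumentSpec
) -> tuple[ItemResponseMatrix, ExclusionReport]:
    """Screen protocols: drop incomplete rows, then rows with lie in [7, 10].

    The two causes are counted in that fixed order, so a row that is both
    incomplete and lie-invalid counts as incomplete.  Idempotent.
    """
    X = responses.responses
    n_received = X.shape[0]
    complete = ~np.isnan(X).any(axis=1)
    n_incomplete = int((~complete).sum())

    lie_cols = spec.column_indices("lie")
    lie = np.where(complete, np.nansum(X[:, lie_cols], axis=1), -1)
    lie_invalid = complete & (lie >= LIE_INVALID_LOW) & (lie <= LIE_INVALID_HIGH)
    n_lie_invalid = int(lie_invalid.sum())

    keep = complete & ~lie_invalid
    kept = ItemResponseMatrix(
        participant_ids=[pid for pid, k in zip(responses.participant_ids, keep) if k],
        responses=X[keep],
        metadata=(
            responses.metadata.loc[keep].reset_index(drop=True)
            if responses.metadata is not None
            else None
        ),
    )
    return kept, ExclusionReport(n_received, n_incomplete, n_lie_invalid)


def classify_total(total_score: int) -> str:
    """Grade the content total: 0-55 normal, 56-64 poor, >=65 severe."""
    if total_score < 0:
        raise ValueError(f"total score must be non-negative, got {total_score}")
    if total_score < POOR_LOW:
        return GRADE_NORMAL
    if total_score <= POOR_HIGH:
        return GRADE_POOR
    return GRADE_SEVERE


def flag_subscale(score: int) -> str:
    """Flag one subscale score: >=8 clear tendency, <=3 none, else mid."""
    if score < 0:
        raise ValueError(f"subscale score must be non-negative, got {score}")
    if score >= FLAG_CUTOFF:
        return FLAG_CLEAR
    if score <= NO_TENDENCY_CUTOFF:
        return FLAG_NONE
    return FLAG_INTERMEDIATE


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage rounded the way the report tables print it (1 decimal)."""
    return round(100.0 * count / total, ndigits)


def descriptive_stats(scores: SubscaleScoreTable) -> pd.DataFrame:
    """Per-subscale mean, sample SD, skew g1, excess kurtosis g2 and flag
    counts (score >= 8).

    Moment conventions: SD uses the n-1 denominator; skewness is the
    population g1 = m3 / m2**1.5; kurtosis is the excess g2 = m4 / m2**2 - 3.
    A constant column gets NaN for skew/kurt deliberately (undefined, not a
    propagated division error).
    """
    if scores.n < 2:
        raise ValueError("descriptive statistics need at least 2 participants")
    rows = []
    n = scores.n
    for name in scores.node_labels:
        x = scores.scores[name].to_numpy(dtype=float)
        m2 = np.mean((x - x.mean()) ** 2)
        if m2 == 0.0:
            skew = kurt = float("nan")
        else:
            skew = float(_sps.skew(x, bias=True))
            kurt = float(_sps.kurtosis(x, fisher=True, bias=True))
        n_flagged = int((x >= FLAG_CUTOFF).sum())
        rows.append(
            {
                "node": name,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)),
                "skew": skew,
                "kurt": kurt,
                "n_flagged": n_flagged,
                "pct_flagged": percentage(n_flagged, n),
            }
        )
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# CSV dialects


def read_responses_csv(path) -> ItemResponseMatrix:
    """Read `id,item_001..item_100[,age,sex]`; empty cell = missing."""
    df = pd.read_csv(path, dtype={"id": str})
    item_cols = [c for c in df.columns if c.startswith("item_")]
    meta_cols = [c for c in df.columns if c != "id" and not c.startswith("item_")]
    responses = df[item_cols].to_numpy(dtype=float)
    meta = df[meta_cols].copy() if meta_cols else None
    return ItemResponseMatrix(list(df["id"]), responses, meta)


def write_responses_csv(responses: ItemResponseMatrix, path) -> None:
    n_items = responses.responses.shape[1]
    cols = [f"item_{i:03d}" for i in range(1, n_items + 1)]
    df = pd.DataFrame(responses.responses, columns=cols)
    # keep 0/1 as integers, missing as empty cells
    df = df.astype("Int64")
    df.insert(0, "id", responses.participant_ids)
    if responses.metadata is not None:
        for c in responses.metadata.columns:
            df[c] = responses.metadata[c].to_numpy()
    df.to_csv(path, index=False)


def write_scores_csv(scores: SubscaleScoreTable, path) -> None:
    """Write `id,MHT1..MHT8,lie,total,grade`."""
    scores.to_frame().to_csv(path, index=False)


def read_scores_csv(path) -> SubscaleScoreTable:
    df = pd.read_csv(path, dtype={"id": str})
    content = [c for c in df.columns if c not in ("id", "lie", "total", "grade")]
    scores = df[content].astype(int)
    lie = (
        df["lie"].to_numpy(dtype=int)
        if "lie" in df
        else np.zeros(len(df), dtype=int)
    )
    total = scores.to_numpy().sum(axis=1)
    return SubscaleScoreTable(list(df["id"]), scores, lie, total)
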