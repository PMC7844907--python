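"""Scoring of the 11-item Child Depression Screening Tool (CDST).

The CDST asks one question per symptom theme (mood, interest in leisure,
hope of living, fatigue, psychomotor activity, sleep, appetite,
concentration, interpersonal relationships, suicidality, guilt), each on a
four-point frequency scale: 0 = symptom absent, 1 = sometimes present,
2 = frequently present, 3 = always present.  The instrument total is the
unweighted sum of the 11 item values, so it ranges from 0 to 33, and a
child screens positive when the total reaches a chosen cutoff
(``total >= cutoff``).
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

#: Symptom themes, in instrument order.
ITEM_THEMES: tuple[str, ...] = (
    "mood",
    "interest_in_leisure",
    "hope_of_living",
    "fatigue",
    "psychomotor_activity",
    "sleep",
    "appetite",
    "concentration",
    "interpersonal_relationships",
    "suicidality",
    "guilt",
)

#: Column names used for the items in the cohort CSV schema, aligned with
#: :data:`ITEM_THEMES`.
ITEM_COLUMNS: tuple[str, ...] = (
    "item_mood",
    "item_interest",
    "item_hope",
    "item_fatigue",
    "item_psychomotor",
    "item_sleep",
    "item_appetite",
    "item_concentration",
    "item_interpersonal",
    "item_suicidality",
    "item_guilt",
)

N_ITEMS = 11
MAX_ITEM_VALUE = 3
MAX_SCORE = N_ITEMS * MAX_ITEM_VALUE  # 33


class ItemValidationError(ValueError):
    """Raised when item responses violate the instrument's answer scale."""


class ScreenInputError(ValueError):
    """Raised for out-of-range total scores or cutoffs."""


@dataclass(frozen=True)
class ItemResponses:
    """One child's answers to the 11 CDST questions.

    ``values`` is a tuple aligned with :data:`ITEM_THEMES`; every entry is
    an integer in ``{0, 1, 2, 3}``.
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_ITEMS:
            raise ItemValidationError(
                f"expected {N_ITEMS} item values, got {len(self.values)}"
            )
        for theme, value in zip(ITEM_THEMES, self.values):
            _check_item_value(theme, value)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "ItemResponses":
        """Build responses from a mapping keyed by theme or CSV column name."""
        values = []
        for theme, column in zip(ITEM_THEMES, ITEM_COLUMNS):
            if theme in mapping:
                values.append(mapping[theme])
            elif column in mapping:
                values.append(mapping[column])
            else:
                raise ItemValidationError(f"missing item '{theme}'")
        return cls(tuple(int(v) for v in values))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(ITEM_THEMES, self.values))


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of applying a cutoff to a CDST total score."""

    total_score: int
    cutoff: int
    positive: bool


ItemsLike = Union[ItemResponses, Sequence[Optional[int]], Mapping[str, Optional[int]]]


def _check_item_value(theme: str, value: object) -> int:
    # accept python and numpy integers; reject floats and other types
    if isinstance(value, bool):
        value = int(value)
    if not isinstance(value, numbers.Integral):
        raise ItemValidationError(f"item '{theme}' has non-integer value {value!r}")
    v = int(value)
    if not 0 <= v <= MAX_ITEM_VALUE:
        raise ItemValidationError(
            f"item '{theme}' value {v} outside the 0-{MAX_ITEM_VALUE} answer scale"
        )
    return v


def _coerce_items(items: ItemsLike) -> list[tuple[str, Optional[int]]]:
    """Normalise the accepted input forms to (theme, value-or-None) pairs."""
    if isinstance(items, ItemResponses):
        return list(zip(ITEM_THEMES, items.values))
    if isinstance(items, Mapping):
        pairs = []
        for theme, column in zip(ITEM_THEMES, ITEM_COLUMNS):
            if theme in items:
                pairs.append((theme, items[theme]))
            elif column in items:
                pairs.append((theme, items[column]))
            else:
                raise ItemValidationError(f"missing item '{theme}'")
        return pairs
    seq = list(items)
    if len(seq) != N_ITEMS:
        raise ItemValidationError(f"expected {N_ITEMS} item values, got {len(seq)}")
    return list(zip(ITEM_THEMES, seq))


def score_cdst(items: ItemsLike, *, prorate_missing: bool = False) -> int:
    """Total CDST score: the unweighted sum of the 11 item values.

    Parameters
    ----------
    items
        An :class:`ItemResponses`, a length-11 sequence in theme order, or a
        mapping keyed by theme (or CSV column) name.  Values must be
        integers in ``{0, 1, 2, 3}``.
    prorate_missing
        By default any missing (``None``) value is an error.  When true, up
        to two missing items are tolerated: the sum of the answered items is
        rescaled to 11 items and rounded half-up, mirroring the proration
        rule common to symptom checklists.

    Returns
    -------
    int
        Total in ``[0, 33]``.
    """
    pairs = _coerce_items(items)
    answered: list[int] = []
    missing: list[str] = []
    for theme, value in pairs:
        if value is None:
            missing.append(theme)
        else:
            answered.append(_check_item_value(theme, value))
    if missing:
        if not prorate_missing:
            raise ItemValidationError(f"missing item '{missing[0]}'")
        if len(missing) > 2:
            raise ItemValidationError(
                f"cannot prorate {len(missing)} missing items (limit 2): "
                + ", ".join(missing)
            )
        raw = sum(answered) * N_ITEMS / len(answered)
        # round half-up, not banker's
        return min(MAX_SCORE, int(raw + 0.5))
    return sum(answered)


def classify(total_score: int, cutoff: int) -> ScreenResult:
    """Apply a cutoff: a child screens positive when ``total_score >= cutoff``.

    ``cutoff`` may range up to 34 so that "nobody positive" is expressible.
    """
    if not isinstance(total_score, int) or not 0 <= total_score <= MAX_SCORE:
        raise ScreenInputError(f"total_score {total_score!r} outside [0, {MAX_SCORE}]")
    if not isinstance(cutoff, int) or not 0 <= cutoff <= MAX_SCORE + 1:
        raise ScreenInputError(f"cutoff {cutoff!r} outside [0, {MAX_SCORE + 1}]")
    return ScreenResult(total_score=total_score, cutoff=cutoff,
                        positive=total_score >= cutoff)


def score_many(rows: Iterable[ItemsLike]) -> list[int]:
    """Score an iterable of item-response rows."""
    return [score_cdst(r) for r in rows]
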