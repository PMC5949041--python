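"""System Usability Scale (SUS) scoring.

The SUS questionnaire has ten statements answered on a 1-5 Likert scale,
alternating positively phrased (odd items) and negatively phrased (even
items).  A respondent's score on the 0-100 scale is

    2.5 * ( sum_odd (x_i - 1) + sum_even (5 - x_i) )

so all-5 odds with all-1 evens give 100 and the reverse gives 0.  Utilities
here score single responses, batches, and CSV files with columns
``a1..a10`` (one row per respondent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["SUSResponse", "sus_score", "sus_batch", "load_responses_csv"]

_COLUMNS = [f"a{i}" for i in range(1, 11)]


@dataclass(frozen=True)
class SUSResponse:
    """One respondent's ten item values, each an integer in 1..5."""

    items: tuple[int, ...]

    def __init__(self, items: Sequence[int]) -> None:
        vals = tuple(int(v) for v in items)
        if len(vals) != 10:
            raise ValueError("a SUS response has exactly 10 items")
        for i, v in enumerate(vals, start=1):
            if not 1 <= v <= 5:
                raise ValueError(f"item {i} value {v} outside 1..5")
        object.__setattr__(self, "items", vals)


def sus_score(response: SUSResponse | Sequence[int]) -> float:
    """Score one response on the 0-100 scale."""
    if not isinstance(response, SUSResponse):
        response = SUSResponse(response)
    odd = sum(response.items[i] - 1 for i in range(0, 10, 2))
    even = sum(5 - response.items[i] for i in range(1, 10, 2))
    return 2.5 * (odd + even)


def sus_batch(responses: Iterable[SUSResponse | Sequence[int]]) -> float:
    """Mean score over a non-empty batch of responses."""
    scores = [sus_score(r) for r in responses]
    if not scores:
        raise ValueError("need at least one response")
    return sum(scores) / len(scores)


def load_responses_csv(path) -> list[SUSResponse]:
    """Read responses from a CSV with columns ``a1..a10``."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing columns: {missing}")
    return [SUSResponse(row) for row in df[_COLUMNS].itertuples(index=False)]
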