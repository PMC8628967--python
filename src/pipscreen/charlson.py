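"""Charlson comorbidity index from coded comorbidities.

The plain (not age-adjusted) weighted sum over a patient's distinct
conditions, using the original 1987 weights; conditions absent from the
weight table score 0 unless strict mode is requested.  The age-adjusted
variant is deliberately not applied: in a cohort aged >=70 it would make a
score of 0 impossible, whereas the expected baseline distribution has a
large majority at 0.  The weight table is packaged as data so a variant can
be swapped in.

Scores are categorized 0 / 1 / >=2 for use as a model covariate.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = ["default_weights", "charlson_index", "charlson_category", "CHARLSON_CATEGORIES"]

CHARLSON_CATEGORIES = ("0", "1", ">=2")

_weights_cache: Optional[dict[str, int]] = None


def default_weights() -> dict[str, int]:
    """Packaged condition -> weight map (original 1987 index)."""
    global _weights_cache
    if _weights_cache is None:
        src = importlib.resources.files("pipscreen.data") / "charlson_weights.csv"
        with importlib.resources.as_file(src) as p:
            df = pd.read_csv(p)
        _weights_cache = dict(zip(df["condition"], df["weight"].astype(int)))
    return dict(_weights_cache)


def charlson_index(
    conditions: Iterable[str],
    weights: Optional[Mapping[str, int]] = None,
    *,
    strict: bool = False,
) -> int:
    """Weighted sum over the patient's *distinct* conditions.

    Duplicate labels count once; unknown labels score 0, or raise in strict
    mode.
    """
    w = default_weights() if weights is None else weights
    total = 0
    for c in set(conditions):
        if c not in w:
            if strict:
                raise KeyError(f"condition {c!r} missing from Charlson weight table")
            continue
        total += w[c]
    return total


def charlson_category(index: int) -> str:
    """Categorize a Charlson score as '0', '1' or '>=2'."""
    if index < 0:
        raise ValueError(f"Charlson index must be >= 0, got {index}")
    if index == 0:
        return "0"
    if index == 1:
        return "1"
    return ">=2"
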