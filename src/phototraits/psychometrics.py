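"""Scoring of the three self-report instruments.

All instruments are administered on a 5-point Likert scale and scored as
item means so every trait lives on the same 1–5 scale:

* narcissism — the nine narcissism items of the Short Dark Triad (SD3);
* life satisfaction — the Satisfaction With Life Scale (SWLS, 5 items);
* loneliness — the Social and Emotional Loneliness Scale for Adults,
  short form (SELSA-S), yielding family, social and romantic sub-scores
  (5 items each); total loneliness is the mean of the three sub-scores.

Reverse-keyed items are mapped v → 6 − v before averaging.  Item wording
is not reproduced here; the scoring key (item counts + reverse-key
indices) is configuration, with defaults following the published
instruments where known (SWLS has no reverse-keyed items) and a fixed
editable convention where the key is not public.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INSTRUMENTS",
    "TRAITS",
    "InstrumentKey",
    "DEFAULT_SCORING_KEY",
    "score_instrument",
    "total_loneliness",
    "score_survey",
    "load_scoring_key",
]

#: instrument id -> (column prefix in survey tables, trait column name)
INSTRUMENTS: dict[str, tuple[str, str]] = {
    "sd3_narcissism": ("sd3", "narcissism"),
    "swls": ("swls", "life_satisfaction"),
    "selsa_family": ("selsa_f", "loneliness_family"),
    "selsa_social": ("selsa_s", "loneliness_social"),
    "selsa_romantic": ("selsa_r", "loneliness_romantic"),
}

#: Trait columns produced by score_survey, in output order.
TRAITS = (
    "narcissism",
    "life_satisfaction",
    "loneliness_family",
    "loneliness_social",
    "loneliness_romantic",
    "loneliness_total",
)


@dataclass(frozen=True)
class InstrumentKey:
    """Item count and 1-based reverse-keyed item indices for one scale."""

    n_items: int
    reverse: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.n_items < 1:
            raise ValueError("instrument needs at least one item")
        bad = [i for i in self.reverse if not 1 <= i <= self.n_items]
        if bad:
            raise ValueError(f"reverse indices out of range: {bad}")


DEFAULT_SCORING_KEY: dict[str, InstrumentKey] = {
    "sd3_narcissism": InstrumentKey(9, frozenset({2, 6})),
    "swls": InstrumentKey(5, frozenset()),
    "selsa_family": InstrumentKey(5, frozenset({1, 4})),
    "selsa_social": InstrumentKey(5, frozenset({2, 5})),
    "selsa_romantic": InstrumentKey(5, frozenset({1, 3})),
}


def score_instrument(responses: Sequence[int], key: InstrumentKey) -> float:
    """Mean of (reverse-keyed where flagged) 1–5 item responses."""
    r = np.asarray(responses, dtype=float)
    if r.shape != (key.n_items,):
        raise ValueError(
            f"expected {key.n_items} responses, got {r.shape}"
        )
    if ((r < 1) | (r > 5)).any() or not np.equal(np.mod(r, 1), 0).all():
        raise ValueError("responses must be integers in 1..5")
    for i in key.reverse:
        r[i - 1] = 6.0 - r[i - 1]
    return float(r.mean())


def total_loneliness(family: float, social: float, romantic: float) -> float:
    """Total loneliness: the mean of the three sub-factor scores."""
    for v in (family, social, romantic):
        if not 1.0 <= v <= 5.0:
            raise ValueError("sub-factor scores must lie in [1, 5]")
    return (family + social + romantic) / 3.0


def score_survey(
    survey: pd.DataFrame,
    key: Mapping[str, InstrumentKey] | None = None,
) -> pd.DataFrame:
    """Score a survey table into per-user trait scores.

    ``survey`` holds one row per user: ``user_id`` plus item columns
    named ``<prefix>_<i>`` (sd3_1..sd3_9, swls_1..swls_5, selsa_f_1..,
    selsa_s_1.., selsa_r_1..).  Returns a table with user_id and the six
    trait columns, all on the 1–5 scale.
    """
    key = DEFAULT_SCORING_KEY if key is None else dict(key)
    out = {"user_id": survey["user_id"].to_numpy()}
    for inst, (prefix, trait) in INSTRUMENTS.items():
        k = key[inst]
        cols = [f"{prefix}_{i}" for i in range(1, k.n_items + 1)]
        missing = [c for c in cols if c not in survey.columns]
        if missing:
            raise ValueError(f"survey missing item columns: {missing}")
        items = survey[cols].to_numpy(dtype=float)
        if ((items < 1) | (items > 5)).any():
            raise ValueError(f"{inst}: responses outside 1..5")
        for i in k.reverse:
            items[:, i - 1] = 6.0 - items[:, i - 1]
        out[trait] = items.mean(axis=1)
    out["loneliness_total"] = (
        out["loneliness_family"]
        + out["loneliness_social"]
        + out["loneliness_romantic"]
    ) / 3.0
    return pd.DataFrame(out, columns=("user_id",) + TRAITS)


def load_scoring_key(path: str | Path) -> dict[str, InstrumentKey]:
    """Read a scoring key from YAML: ``{instrument: {n_items, reverse}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        inst: InstrumentKey(
            n_items=int(spec["n_items"]),
            reverse=frozenset(int(i) for i in spec.get("reverse", [])),
        )
        for inst, spec in raw.items()
    }
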