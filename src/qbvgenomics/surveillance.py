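"""Pooled mosquito-surveillance arithmetic.

Field collections are tallied per species/genus; virus screening is done on
pools of ~50-100 females, so prevalence is summarized as the fraction of
positive pools.  Only the plain composition and pool-positivity fractions
are computed here (no minimum-infection-rate estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._round import round_half_up


@dataclass
class CollectionTally:
    """Counts of collected individuals per species or genus label."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {label!r}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PoolSummary:
    n_pools: int
    n_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_pools):
            raise ValueError(
                f"need 0 <= n_positive ({self.n_positive}) <= n_pools ({self.n_pools})"
            )


def composition(
    tally: CollectionTally, total: int | None = None
) -> dict[str, float]:
    """Percentage of the collection per label, half-up to one decimal.

    ``total`` overrides the tally's own sum, e.g. to express one species
    against a whole-collection denominator.
    """
    denom = tally.total if total is None else total
    if denom <= 0:
        raise ValueError("composition undefined for an empty collection")
    return {
        label: round_half_up(100.0 * n / denom, 1) for label, n in tally.counts.items()
    }


def positivity_rate(pools: PoolSummary) -> float:
    """Percentage of virus-positive pools, half-up to one decimal."""
    if pools.n_pools <= 0:
        raise ValueError("positivity rate undefined with zero pools")
    return round_half_up(100.0 * pools.n_positive / pools.n_pools, 1)


def read_counts_csv(path: str | Path) -> CollectionTally:
    """Read a species,count CSV into a tally."""
    df = pd.read_csv(path)
    if not {"species", "count"}.issubset(df.columns):
        raise ValueError(f"counts CSV {path} needs columns species,count")
    return CollectionTally(counts=dict(zip(df["species"].astype(str), df["count"].astype(int))))


def read_pools_csv(path: str | Path) -> PoolSummary:
    """Read a pool table CSV with a boolean/0-1 ``positive`` column."""
    df = pd.read_csv(path)
    if "positive" not in df.columns:
        raise ValueError(f"pools CSV {path} needs a positive column")
    pos = df["positive"].astype(bool).sum()
    return PoolSummary(n_pools=len(df), n_positive=int(pos))


def composition_report(tally: CollectionTally) -> pd.DataFrame:
    pct = composition(tally)
    rows = sorted(tally.counts.items(), key=lambda kv: -kv[1])
    return pd.DataFrame(
        {
            "species": [k for k, _ in rows],
            "count": [v for _, v in rows],
            "percent": [pct[k] for k, _ in rows],
            "total": tally.total,
        }
    )
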