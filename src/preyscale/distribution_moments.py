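"""Descriptive statistics of prey-mass distributions.

All location/shape statistics are computed on log10(kg) values; the
kg-scale range of the corresponding raw column is reported alongside.
Skewness is the adjusted Fisher-Pearson sample skewness (bias-corrected
g1); kurtosis is reported both as excess (normal = 0) and raw
(normal = 3).  The "mode" of a continuous mass variable is the modal
log10-decade bin, with per-decade counts emitted so coarser groupings
can be formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import RAW_FOR_RESPONSE, RESPONSE_COLUMNS, TraitTable
from .errors import ValidationError

__all__ = ["MomentsSummary", "ModalBin", "moments", "modal_bin", "decade_counts",
           "prey_span", "moments_table"]

GROUPS = ("all", "terrestrial", "aquatic")


@dataclass
class MomentsSummary:
    group: str
    response: str
    n: int
    mean: float
    median: float
    min: float
    max: float
    range_log: float
    range_kg: float
    sd: float
    skewness: float | None
    excess_kurtosis: float | None
    raw_kurtosis: float | None

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class ModalBin:
    low_kg: float
    high_kg: float
    count: int
    tied: list[tuple[float, float]] = field(default_factory=list)

    @property
    def is_tie(self) -> bool:
        return len(self.tied) > 1


def _group_frame(table: TraitTable, group: str) -> pd.DataFrame:
    if group == "all":
        return table.df
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
    return table.df[table.df["environment"] == group]


def _values(table: TraitTable, group: str, response: str):
    df = _group_frame(table, group)
    col = RESPONSE_COLUMNS.get(response, response)
    logs = df[col].to_numpy(float)
    keep = np.isfinite(logs)
    raw = df[RAW_FOR_RESPONSE[col]].to_numpy(float)[keep]
    return logs[keep], raw


def moments(table: TraitTable, group: str, response: str) -> MomentsSummary:
    """Moments of one response for one group (log10 scale; range also in kg).

    With fewer than 3 values, skewness and kurtosis are undefined and
    reported as None.
    """
    logs, raw = _values(table, group, response)
    n = len(logs)
    if n == 0:
        raise ValidationError(f"group {group!r} is empty for response {response!r}")
    skew = exkurt = rawkurt = None
    if n >= 3:
        skew = float(stats.skew(logs, bias=False))
        exkurt = float(stats.kurtosis(logs, fisher=True, bias=False))
        rawkurt = exkurt + 3.0
    return MomentsSummary(
        group=group,
        response=response,
        n=n,
        mean=float(np.mean(logs)),
        median=float(np.median(logs)),
        min=float(np.min(logs)),
        max=float(np.max(logs)),
        range_log=float(np.max(logs) - np.min(logs)),
        range_kg=float(np.max(raw) - np.min(raw)),
        sd=float(np.std(logs, ddof=1)) if n >= 2 else float("nan"),
        skewness=skew,
        excess_kurtosis=exkurt,
        raw_kurtosis=rawkurt,
    )


def prey_span(table: TraitTable, group: str) -> float:
    """Group-level prey span in kg: max(prey_max) - min(prey_min)."""
    df = _group_frame(table, group)
    if df.empty:
        raise ValidationError(f"group {group!r} is empty")
    return float(df["prey_max"].max() - df["prey_min"].min())


def decade_counts(table: TraitTable, group: str, response: str) -> pd.DataFrame:
    """Histogram over log10-decade bins [10^d, 10^(d+1)) of the raw kg values."""
    _logs, raw = _values(table, group, response)
    if len(raw) == 0:
        raise ValidationError(f"group {group!r} is empty for response {response!r}")
    decades = np.floor(np.log10(raw)).astype(int)
    lo, hi = decades.min(), decades.max()
    rows = []
    for d in range(lo, hi + 1):
        rows.append(
            {
                "group": group,
                "response": response,
                "low_kg": 10.0 ** d,
                "high_kg": 10.0 ** (d + 1),
                "count": int((decades == d).sum()),
            }
        )
    return pd.DataFrame(rows)


def modal_bin(table: TraitTable, group: str, response: str) -> ModalBin:
    """The decade bin with the highest count; ties are reported explicitly."""
    counts = decade_counts(table, group, response)
    top = counts["count"].max()
    winners = counts[counts["count"] == top]
    tied = [(r.low_kg, r.high_kg) for r in winners.itertuples()]
    first = winners.iloc[0]
    return ModalBin(
        low_kg=float(first["low_kg"]),
        high_kg=float(first["high_kg"]),
        count=int(top),
        tied=tied,
    )


def moments_table(
    table: TraitTable,
    groups=GROUPS,
    responses=("min", "max", "range"),
) -> pd.DataFrame:
    """Long-format table of all moments (supplementary-table shape)."""
    rows = []
    for grp in groups:
        for resp in responses:
            rows.append(moments(table, grp, resp).to_dict())
    return pd.DataFrame(rows)
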