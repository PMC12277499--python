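"""Method-agreement summaries for paired SUV measurements.

Agreement between two measurement methods is summarized per organ as the
mean absolute per-patient difference with its population standard deviation
(divisor n — pinned by the published "mean ± sd" rows, which a sample sd
does not reproduce), and across organs as the unweighted mean of the
per-organ means with its range.  Reports round at 2 decimals, and the
cross-organ aggregate is computed from the rounded per-organ means, mirroring
how such summary rows are derived from a printed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import PairedMeasurementTable

__all__ = [
    "AgreementSummary",
    "abs_diff_summary",
    "grand_mean_of_organ_means",
    "agreement_report",
]


@dataclass(frozen=True)
class AgreementSummary:
    organ: str
    mean: float  # mean |a - b| over patients
    sd: float  # population sd (divisor n) of |a - b|
    n: int

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        return (round(self.mean, decimals), round(self.sd, decimals))


def abs_diff_summary(
    table: PairedMeasurementTable, method_a: str, method_b: str, organ: str
) -> AgreementSummary:
    """Mean and population sd of per-patient |a - b| for one organ."""
    pairs = table.paired(method_a, method_b, organ)
    diffs = np.abs(pairs["a"].to_numpy() - pairs["b"].to_numpy())
    return AgreementSummary(
        organ=organ,
        mean=float(diffs.mean()),
        sd=float(diffs.std(ddof=0)),
        n=len(diffs),
    )


def grand_mean_of_organ_means(means: Iterable[float]) -> tuple[float, float, float]:
    """Unweighted mean of per-organ mean differences, with its (min, max) range."""
    vals = np.asarray(list(means), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one organ summary")
    return (float(vals.mean()), float(vals.min()), float(vals.max()))


def agreement_report(
    table: PairedMeasurementTable,
    method_a: str,
    method_b: str,
    organs: Sequence[str] | None = None,
    decimals: int = 2,
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Per-organ agreement rows plus the cross-organ aggregate.

    Returns a DataFrame with one row per organ (``mean``, ``sd`` rounded at
    ``decimals``; raw values in ``mean_raw``/``sd_raw``) and the
    ``(grand mean, min, max)`` of the rounded per-organ means.
    """
    organs = list(organs) if organs is not None else list(table.organs)
    summaries = [abs_diff_summary(table, method_a, method_b, o) for o in organs]
    df = pd.DataFrame(
        {
            "organ": [s.organ for s in summaries],
            "mean": [round(s.mean, decimals) for s in summaries],
            "sd": [round(s.sd, decimals) for s in summaries],
            "mean_raw": [s.mean for s in summaries],
            "sd_raw": [s.sd for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
    aggregate = grand_mean_of_organ_means(df["mean"])
    return df, aggregate
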