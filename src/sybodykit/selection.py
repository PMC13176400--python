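"""Selection-round statistics: enrichment factors and conditional ELISA calls.

Enrichment across a panning round is the ratio of recovered particles
(phage titer or colony counts) between the target and control conditions.
Conformation-specific ELISA screening compares each clone's signal in the
calcium condition against the chelator (EDTA-EGTA) condition; a clone is
called positive when the ratio strictly exceeds the threshold (default 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CALCIUM, CHELATOR


class SelectionError(ValueError):
    pass


class NoBackgroundError(SelectionError):
    """Control count is zero: the enrichment ratio is undefined, not infinite."""


@dataclass(frozen=True)
class EnrichmentResult:
    experimental: float
    control: float
    factor: float


def enrichment_factor(experimental: float, control: float) -> EnrichmentResult:
    """Ratio of experimental to control recovery counts."""
    if experimental < 0 or control < 0:
        raise SelectionError("counts must be >= 0")
    if control == 0:
        raise NoBackgroundError(
            "control count is 0 (no background); enrichment factor undefined"
        )
    return EnrichmentResult(experimental, control, experimental / control)


@dataclass(frozen=True)
class RatioCall:
    clone: str
    ratio: float | None
    call: str                     # positive | negative | unevaluable


def elisa_calls(plate: pd.DataFrame, threshold: float = 1.5
                ) -> tuple[list[RatioCall], dict]:
    """Per-clone calcium/chelator ratios and positive calls.

    ``plate`` has columns clone, condition, signal with each clone present
    in both conditions.  Positivity is strict (ratio > threshold).  Clones
    with non-positive chelator signal are flagged unevaluable and excluded
    from the counts.  The summary carries the positive count/rate and the
    median and quartiles of the positive ratios.
    """
    required = {"clone", "condition", "signal"}
    if missing := required - set(plate.columns):
        raise SelectionError(f"plate table missing columns: {sorted(missing)}")
    wide = plate.pivot_table(index="clone", columns="condition",
                             values="signal", aggfunc="first")
    for cond in (CALCIUM, CHELATOR):
        if cond not in wide.columns or wide[cond].isna().any():
            bad = (list(wide.index[wide[cond].isna()])
                   if cond in wide.columns else list(wide.index))
            raise SelectionError(
                f"clones missing the {cond} condition: {bad[:5]}"
            )
    calls: list[RatioCall] = []
    for clone, row in wide.iterrows():
        if row[CHELATOR] <= 0:
            calls.append(RatioCall(str(clone), None, "unevaluable"))
            continue
        ratio = float(row[CALCIUM] / row[CHELATOR])
        call = "positive" if ratio > threshold else "negative"
        calls.append(RatioCall(str(clone), ratio, call))
    positives = [c.ratio for c in calls if c.call == "positive"]
    evaluable = [c for c in calls if c.call != "unevaluable"]
    summary = {
        "threshold": threshold,
        "n_clones": len(calls),
        "n_evaluable": len(evaluable),
        "n_unevaluable": len(calls) - len(evaluable),
        "n_positive": len(positives),
        "positive_rate": (len(positives) / len(evaluable)) if evaluable else 0.0,
        "positive_ratio_median": float(np.median(positives)) if positives else None,
        "positive_ratio_q25": float(np.percentile(positives, 25)) if positives else None,
        "positive_ratio_q75": float(np.percentile(positives, 75)) if positives else None,
    }
    return calls, summary


@dataclass(frozen=True)
class TwoSampleSummary:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]
    t_statistic: float
    p_value: float
    note: str = ""


def compare_positive_populations(group_a: Sequence[float],
                                 group_b: Sequence[float]) -> TwoSampleSummary:
    """Unpaired two-tailed t-test between two sets of positive ratios.

    A convenience hook, not a novel method.  Degenerate zero-variance input
    is handled explicitly: identical constant groups give t=0, p=1; constant
    groups with different means give p=0 with a note.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SelectionError("each group needs at least 2 values")

    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a.mean() == b.mean():
            t, p, note = 0.0, 1.0, "zero variance, equal means"
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p, note = 0.0, "zero variance, unequal means"
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p, note = float(t), float(p), ""
    qa = np.percentile(a, [25, 75])
    qb = np.percentile(b, [25, 75])
    return TwoSampleSummary(
        n_a=a.size, n_b=b.size,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        quartiles_a=(float(qa[0]), float(qa[1])),
        quartiles_b=(float(qb[0]), float(qb[1])),
        t_statistic=t, p_value=p, note=note,
    )


def load_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate table (TSV/CSV with clone, condition, signal columns)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)
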