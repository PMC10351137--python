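"""Dual-luciferase normalization and allelic comparison.

Each well's experimental (nano) reading is divided by its co-transfected
firefly reading — absorbing transfection efficiency, cell number and
cytotoxicity — and the ratio is further divided by the mean empty-backbone
ratio of the same condition, so the backbone construct normalizes to 1.
The allelic comparison between the risk- and non-risk-allele constructs
is a two-sided Student's t-test (pooled variance by default; Welch
behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (e.g. zero variance)."""


@dataclass
class NormalizedActivity:
    """Backbone-normalized nano/firefly ratios for one construct+condition."""

    construct: str
    condition: str
    values: np.ndarray
    mean: float
    sd: float


def normalize_wells(wells: pd.DataFrame, backbone: str = "backbone") -> list[NormalizedActivity]:
    """Per-well nano/firefly, divided by the condition's mean backbone ratio.

    ``wells`` needs columns construct, condition, replicate_id, nano,
    firefly (see :func:`snp2enhancer.io_formats.read_reporter_table`).
    Raises if any condition lacks backbone wells.
    """
    if (wells["nano"] <= 0).any() or (wells["firefly"] <= 0).any():
        raise ValueError("luciferase readings must be strictly positive")
    wells = wells.copy()
    wells["ratio"] = wells["nano"] / wells["firefly"]

    backbone_mean: dict[str, float] = {}
    for condition, grp in wells.groupby("condition"):
        bb = grp.loc[grp["construct"] == backbone, "ratio"]
        if bb.empty:
            raise DegenerateInputError(
                f"condition {condition!r} has no {backbone!r} wells to normalize against"
            )
        backbone_mean[condition] = float(bb.mean())

    out = []
    for (construct, condition), grp in wells.groupby(["construct", "condition"], sort=True):
        vals = (grp["ratio"] / backbone_mean[condition]).to_numpy(dtype=float)
        out.append(NormalizedActivity(
            construct=str(construct), condition=str(condition), values=vals,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        ))
    return out


def allelic_test(norm_a: np.ndarray, norm_b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test between two groups of normalized activities.

    Returns (t, p).  ``t`` is signed a-minus-b, so swapping the groups
    negates it.  Pooled-variance Student's t by default; ``welch=True``
    drops the equal-variance assumption.
    """
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("need >= 2 wells per group")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise DegenerateInputError("zero pooled variance: all wells identical")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_constructs(
    activities: list[NormalizedActivity],
    construct_a: str,
    construct_b: str,
    condition: str,
    welch: bool = False,
) -> dict:
    """Allelic t-test between two constructs within one condition."""
    by_key = {(na.construct, na.condition): na for na in activities}
    try:
        a = by_key[(construct_a, condition)]
        b = by_key[(construct_b, condition)]
    except KeyError as exc:
        raise KeyError(f"no normalized activity for construct {exc} in {condition!r}") from exc
    t, p = allelic_test(a.values, b.values, welch=welch)
    return {
        "construct_a": construct_a, "construct_b": construct_b,
        "condition": condition,
        "mean_a": a.mean, "mean_b": b.mean,
        "ratio_a_over_b": a.mean / b.mean if b.mean != 0 else np.inf,
        "t": t, "p": p,
    }
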