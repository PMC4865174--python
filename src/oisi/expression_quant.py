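"""Relative expression (2^-ΔΔCt), percent-of-control summaries, Student t.

Small quantification utilities used alongside the imaging readouts: relative
qPCR quantification of a target gene against a reference gene (GAPDH role)
normalized to a control group, percent-of-control normalization of
per-sample values (e.g. cell counts), and the classical pooled-variance
two-sample t-test used for pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCRMeasurement",
    "GroupSummary",
    "measurements_to_frame",
    "collapse_replicates",
    "fold_change_ddct",
    "relative_expression",
    "percent_of_control",
    "two_sample_t",
]


@dataclass
class QPCRMeasurement:
    """One technical replicate: target and reference threshold cycles."""

    sample: str
    group: str
    gene: str
    ct_target: float
    ct_reference: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"missing or non-finite {name} for sample {self.sample!r}")


@dataclass
class GroupSummary:
    """Per-group mean ± SEM of per-sample values."""

    group: str
    values: np.ndarray
    mean: float
    sem: Optional[float]  # absent when n = 1
    n: int


def measurements_to_frame(measurements: Iterable[QPCRMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": m.sample,
                "group": m.group,
                "gene": m.gene,
                "ct_target": m.ct_target,
                "ct_reference": m.ct_reference,
                "replicate": m.replicate,
            }
            for m in measurements
        ]
    )


def collapse_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates at the Ct level, per sample and gene."""
    required = {"sample", "group", "gene", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    return (
        df.groupby(["sample", "group", "gene"], as_index=False)[["ct_target", "ct_reference"]]
        .mean()
    )


def fold_change_ddct(delta_ct, control_mean_dct: float):
    """2^-ΔΔCt fold change for ΔCt = Ct_target − Ct_reference values.

    ΔΔCt = ΔCt − control_mean_dct; one cycle below the control mean doubles
    the reported expression, exactly.
    """
    delta_ct = np.asarray(delta_ct, dtype=float)
    if not np.all(np.isfinite(delta_ct)) or not math.isfinite(control_mean_dct):
        raise ValueError("ΔCt values must be finite")
    out = 2.0 ** (-(delta_ct - control_mean_dct))
    return float(out) if out.ndim == 0 else out


def relative_expression(df: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-sample 2^-ΔΔCt fold changes relative to ``control_group``, per gene.

    Technical replicates are collapsed at the Ct level first; the control
    reference for each gene is the control group's mean ΔCt.
    """
    collapsed = collapse_replicates(df)
    collapsed["delta_ct"] = collapsed["ct_target"] - collapsed["ct_reference"]
    out = []
    for gene, sub in collapsed.groupby("gene"):
        control = sub.loc[sub["group"] == control_group, "delta_ct"]
        if control.empty:
            raise ValueError(f"no control-group samples for gene {gene!r}")
        sub = sub.copy()
        sub["fold_change"] = fold_change_ddct(sub["delta_ct"].to_numpy(), control.mean())
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def _summary(group: str, values: np.ndarray) -> GroupSummary:
    n = len(values)
    sem = float(stats.sem(values, ddof=1)) if n > 1 else None
    return GroupSummary(group=group, values=values, mean=float(values.mean()), sem=sem, n=n)


def percent_of_control(
    values: Sequence[float], control_values: Sequence[float], group: str = ""
) -> GroupSummary:
    """Express per-sample values as a percentage of the control-group mean."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if values.size < 1 or control.size < 1:
        raise ValueError("need at least one value per group")
    cmean = control.mean()
    if cmean <= 0:
        raise ValueError("control mean must be > 0")
    return _summary(group, values * 100.0 / cmean)


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Classical pooled-variance Student t-test (two-sided).

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give an infinite statistic with the smallest positive float as p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), float(np.finfo(float).tiny)
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(max(p, np.finfo(float).tiny))
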