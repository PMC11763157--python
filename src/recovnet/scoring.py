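"""Fold changes, Efficiency-of-Recovery (EoR) scoring, and gene-set selection.

EoR quantifies, per gene, how completely a treatment restores the expression
shift induced by disease:

    EoR = 100 - |100 - 100 * FC(arm/model) / FC(sham/model)|

where the fold changes are linear ratios of group means.  EoR = 100 means
the treatment reproduces the sham/model contrast exactly; EoR <= 0 means no
movement toward sham, movement in the wrong direction, or an over-correction
past twice the disease shift.  Negative values are deliberately kept — they
carry over-correction information — and only the classification threshold
(default: recovered iff EoR > 0) is configurable.

Gene-set selections:

* *specific*: genes recovered by the combination but by no mono arm;
* *differential*: genes whose combination EoR exceeds each mono arm's EoR by
  more than a margin delta (default 0.2 on the fraction scale, i.e. 20 EoR
  points);
* *union*: specific ∪ differential.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_fold_changes",
    "eor",
    "eor_table",
    "RecoveryRate",
    "recovery_rate",
    "select_specific",
    "select_differential",
    "select_union",
]


def _group_means(expression: pd.DataFrame, sample_sheet: pd.DataFrame,
                 groups: Sequence[str]) -> dict[str, np.ndarray]:
    by_group = sample_sheet.groupby("group")["sample"].apply(list)
    means = {}
    for g in groups:
        if g not in by_group.index:
            raise ValueError(f"group {g!r} not present in the sample sheet")
        samples = by_group[g]
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has {len(samples)} sample(s); need >= 2")
        missing = [s for s in samples if s not in expression.columns]
        if missing:
            raise ValueError(f"samples {missing} of group {g!r} absent from the expression table")
        means[g] = expression[samples].to_numpy(dtype=float).mean(axis=1)
    return means


def compute_fold_changes(expression: pd.DataFrame, sample_sheet: pd.DataFrame, *,
                         sham: str = "sham", model: str = "model",
                         arms: Sequence[str] | None = None,
                         pseudo_count: float = 0.5) -> pd.DataFrame:
    """Linear fold changes of group means for the disease and treatment contrasts.

    Returns a DataFrame indexed by gene with a ``disease`` column
    (FC(sham/model)) and one column per treatment arm (FC(arm/model)); the
    arm order is kept in ``df.attrs["arms"]``.  Fold changes are plain
    ratios of arithmetic group means with a pseudo-count in numerator and
    denominator; no shrinkage is applied.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be >= 0")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    if arms is None:
        arms = [g for g in sample_sheet["group"].unique() if g not in (sham, model)]
    arms = list(arms)
    means = _group_means(expression, sample_sheet, [sham, model, *arms])

    denom = means[model] + pseudo_count
    if np.any(denom <= 0):
        raise ValueError("model-group mean + pseudo_count must be positive for every gene")
    out = {"disease": (means[sham] + pseudo_count) / denom}
    for arm in arms:
        out[arm] = (means[arm] + pseudo_count) / denom
    fc = pd.DataFrame(out, index=expression.index)
    fc.attrs["arms"] = arms
    return fc


def eor(fc_arm, fc_disease):
    """Efficiency of recovery (percent): 100 - |100 - 100 * fc_arm / fc_disease|.

    Accepts scalars or arrays.  Equals 100 iff the treatment fold change
    matches the disease fold change; can be negative (over-correction or
    movement away from sham).
    """
    fa = np.asarray(fc_arm, dtype=float)
    fd = np.asarray(fc_disease, dtype=float)
    if np.any(fa <= 0) or np.any(fd <= 0):
        raise ValueError("fold changes must be positive linear ratios")
    out = 100.0 - np.abs(100.0 - 100.0 * fa / fd)
    return float(out) if out.ndim == 0 else out


def eor_table(fold_changes: pd.DataFrame, arms: Sequence[str] | None = None) -> pd.DataFrame:
    """Per gene x arm EoR values from a fold-change table (``disease`` column + arms)."""
    if "disease" not in fold_changes.columns:
        raise ValueError("fold-change table needs a 'disease' column")
    if arms is None:
        arms = fold_changes.attrs.get("arms") or [c for c in fold_changes.columns if c != "disease"]
    fd = fold_changes["disease"]
    out = pd.DataFrame({arm: eor(fold_changes[arm], fd) for arm in arms},
                       index=fold_changes.index)
    out.attrs["arms"] = list(arms)
    return out


class RecoveryRate(NamedTuple):
    count: int
    total: int
    percent: float


def recovery_rate(eor_tab: pd.DataFrame, arm: str, threshold: float = 0.0) -> RecoveryRate:
    """Count and percentage of genes with EoR > threshold in the given arm.

    The percentage is rounded half-up to 2 decimals (e.g. 902 of 1447 ->
    62.34).
    """
    if arm not in eor_tab.columns:
        raise ValueError(f"arm {arm!r} not in EoR table")
    if len(eor_tab) == 0:
        raise ValueError("EoR table is empty")
    count = int((eor_tab[arm] > threshold).sum())
    total = len(eor_tab)
    percent = float((Decimal(count) * 100 / Decimal(total))
                    .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return RecoveryRate(count=count, total=total, percent=percent)


def _check_arms(eor_tab: pd.DataFrame, combo_arm: str, mono_arms: Sequence[str]) -> list[str]:
    mono_arms = list(mono_arms)
    if combo_arm in mono_arms:
        raise ValueError("the combination arm cannot be listed among the mono arms")
    for arm in (combo_arm, *mono_arms):
        if arm not in eor_tab.columns:
            raise ValueError(f"arm {arm!r} not in EoR table")
    if not mono_arms:
        raise ValueError("need at least one mono arm")
    return mono_arms


def select_specific(eor_tab: pd.DataFrame, combo_arm: str, mono_arms: Sequence[str],
                    threshold: float = 0.0) -> set[str]:
    """Genes recovered by the combination (EoR > threshold) and by no mono arm."""
    mono_arms = _check_arms(eor_tab, combo_arm, mono_arms)
    mask = eor_tab[combo_arm] > threshold
    for arm in mono_arms:
        mask &= eor_tab[arm] <= threshold
    return set(eor_tab.index[mask])


def select_differential(eor_tab: pd.DataFrame, combo_arm: str, mono_arms: Sequence[str],
                        delta: float = 0.2, delta_scale: str = "fraction",
                        mode: str = "all") -> set[str]:
    """Genes whose combination EoR exceeds the mono arms' EoR by more than delta.

    ``delta_scale="fraction"`` (default) reads delta on the 0-1 scale of a
    fraction-valued EoR, i.e. delta 0.2 demands a margin of 20 EoR points;
    ``"percent"`` reads delta directly in EoR points.  ``mode="all"``
    (default, conservative) demands the margin over every mono arm;
    ``"any"`` over at least one.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta_scale not in ("fraction", "percent"):
        raise ValueError("delta_scale must be 'fraction' or 'percent'")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    mono_arms = _check_arms(eor_tab, combo_arm, mono_arms)
    margin = delta * 100.0 if delta_scale == "fraction" else delta
    per_arm = [(eor_tab[combo_arm] - eor_tab[arm]) > margin for arm in mono_arms]
    mask = np.logical_and.reduce(per_arm) if mode == "all" else np.logical_or.reduce(per_arm)
    return set(eor_tab.index[mask])


def select_union(specific: Iterable[str], differential: Iterable[str]) -> set[str]:
    """Union of the two selections (duplicates eliminated)."""
    return set(specific) | set(differential)
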