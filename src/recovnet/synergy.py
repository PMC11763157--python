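"""Bliss-independence synergy analysis of plate-assay readouts.

Readouts (absorbances, viabilities, functional indices) are normalized to a
treatment effect E on the control/model window: the control group anchors
E = 1, the model group E = 0, and any arm scales linearly in between.  Two
mono-arm effects combine under Bliss independence as

    E_expected = E_a + E_b - E_a * E_b      (probabilistic independence)

and the combination index compares expectation with observation:

    CI = E_expected / E_observed(combination)

CI < 1 means the combination beats independence (synergy), CI > 1 falls
short of it (antagonism); a configurable tolerance band around 1 is labelled
additive.  An inhibition rate (percent of the assay window recovered) is
also provided for NO-release-style assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import child_rng

__all__ = [
    "EffectEstimate",
    "SynergyResult",
    "inhibition_rate",
    "normalize_effect",
    "bliss_expected",
    "combination_index",
    "bootstrap_ci",
    "analyze_synergy",
]


def inhibition_rate(mean_model: float, mean_treatment: float, mean_control: float) -> float:
    """Inhibition rate (percent): 100 * (model - treatment) / (model - control).

    100% when the treatment reaches the control level, 0% when it sits at the
    model level.
    """
    if mean_model == mean_control:
        raise ValueError("model and control means are equal: assay window collapsed")
    return 100.0 * (mean_model - mean_treatment) / (mean_model - mean_control)


@dataclass(frozen=True)
class EffectEstimate:
    """Normalized treatment effect for one arm.

    ``effect`` is clamped to [0, 1] as the Bliss model requires; ``raw``
    keeps the unclamped value (an arm can score worse than the model group),
    and ``replicate_effects`` the per-well normalized values for resampling.
    """

    arm: str
    effect: float
    raw: float
    replicate_effects: np.ndarray


def _means(readouts: pd.DataFrame, groups: Sequence[str]) -> dict[str, float]:
    if not {"group", "value"}.issubset(readouts.columns):
        raise ValueError("readout table needs 'group' and 'value' columns")
    by = readouts.groupby("group")["value"]
    out = {}
    for g in groups:
        if g not in by.groups:
            raise ValueError(f"group {g!r} not present in the readout table")
        vals = by.get_group(g)
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has {len(vals)} replicate(s); need >= 2")
        out[g] = float(vals.mean())
    return out


def normalize_effect(readouts: pd.DataFrame, arm: str, control: str = "control",
                     model: str = "model") -> EffectEstimate:
    """Normalize an arm's readouts to E = (arm - model) / (control - model), clamped to [0, 1]."""
    means = _means(readouts, [control, model, arm])
    window = means[control] - means[model]
    if window == 0:
        raise ValueError("control and model means are equal: assay window collapsed")
    raw = (means[arm] - means[model]) / window
    reps = readouts.loc[readouts["group"] == arm, "value"].to_numpy(dtype=float)
    rep_e = (reps - means[model]) / window
    return EffectEstimate(arm=arm, effect=float(np.clip(raw, 0.0, 1.0)), raw=float(raw),
                          replicate_effects=rep_e)


def bliss_expected(e_a: float, e_b: float) -> float:
    """Bliss-independence expected effect E_a + E_b - E_a*E_b; commutative, in [max(E_a,E_b), 1]."""
    for e in (e_a, e_b):
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"effects must lie in [0, 1], got {e}")
    return e_a + e_b - e_a * e_b


def combination_index(e_a: float, e_b: float, e_ab: float,
                      additive_tol: float = 0.05) -> tuple[float, str]:
    """Combination index CI = (E_a + E_b - E_a*E_b) / E_ab and its classification.

    Synergistic if CI < 1, antagonistic if CI > 1; |CI - 1| <= additive_tol
    is labelled additive.  E_ab must be positive (CI is undefined otherwise).
    """
    if e_ab <= 0:
        raise ValueError("combination effect must be > 0 for the CI to be defined")
    if additive_tol < 0:
        raise ValueError("additive_tol must be >= 0")
    ci = bliss_expected(e_a, e_b) / e_ab
    if abs(ci - 1.0) <= additive_tol:
        label = "additive"
    elif ci < 1.0:
        label = "synergistic"
    else:
        label = "antagonistic"
    return ci, label


def bootstrap_ci(readouts: pd.DataFrame, arms: tuple[str, str], combo: str,
                 n_boot: int = 2000, seed: int = 0, control: str = "control",
                 model: str = "model", alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap interval for the combination index.

    Wells are resampled with replacement within each group; draws whose
    resampled combination effect is non-positive (CI undefined) or whose
    control/model means coincide are discarded.  Requires >= 3 replicates
    per group.
    """
    groups = [control, model, *arms, combo]
    by = readouts.groupby("group")["value"]
    vals = {}
    for g in groups:
        if g not in by.groups:
            raise ValueError(f"group {g!r} not present in the readout table")
        v = by.get_group(g).to_numpy(dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {g!r} has {len(v)} replicates; bootstrap needs >= 3")
        vals[g] = v
    rng = child_rng(seed, "bootstrap-ci")
    cis = []
    for _ in range(n_boot):
        m = {g: v[rng.integers(0, len(v), len(v))].mean() for g, v in vals.items()}
        window = m[control] - m[model]
        if window == 0:
            continue
        e = {g: float(np.clip((m[g] - m[model]) / window, 0.0, 1.0)) for g in (*arms, combo)}
        if e[combo] <= 0:
            continue
        cis.append(bliss_expected(e[arms[0]], e[arms[1]]) / e[combo])
    if not cis:
        raise ValueError("no valid bootstrap draws (combination effect never positive)")
    lo, hi = np.percentile(cis, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class SynergyResult:
    """Full synergy report for one mono-arm pair and its combination."""

    effects: dict[str, EffectEstimate]
    combo: str
    e_expected: float
    ci: float
    classification: str
    ci_interval: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "effects": {a: {"E": e.effect, "raw": e.raw} for a, e in self.effects.items()},
            "combo": self.combo,
            "e_expected": self.e_expected,
            "ci": self.ci,
            "classification": self.classification,
            "ci_interval": list(self.ci_interval) if self.ci_interval else None,
        }


def analyze_synergy(readouts: pd.DataFrame, arms: tuple[str, str], combo: str,
                    control: str = "control", model: str = "model",
                    additive_tol: float = 0.05, n_boot: int = 0,
                    seed: int = 0) -> SynergyResult:
    """Normalize effects, apply the Bliss model, and classify the combination."""
    effects = {a: normalize_effect(readouts, a, control=control, model=model)
               for a in (*arms, combo)}
    e_a, e_b = effects[arms[0]].effect, effects[arms[1]].effect
    ci, label = combination_index(e_a, e_b, effects[combo].effect, additive_tol=additive_tol)
    interval = None
    if n_boot:
        interval = bootstrap_ci(readouts, arms, combo, n_boot=n_boot, seed=seed,
                                control=control, model=model)
    return SynergyResult(effects=effects, combo=combo, e_expected=bliss_expected(e_a, e_b),
                         ci=ci, classification=label, ci_interval=interval)
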