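"""Differential metabolite screening, restoration calls, and taxon-metabolite association.

The screen applies three independent gates per feature: a Welch two-sample
t-test p-value, an absolute log2 fold-change threshold, and a minimum
compound-annotation score (the confidence that the feature is a correctly
identified compound).  A feature is *restored* when it passes the screen in
both the disease contrast (model vs sham) and the treatment contrast
(treatment vs model) with opposite fold-change signs — the treatment moves
it back toward the sham level.

Taxon-metabolite association uses tie-corrected Spearman rank correlation
over shared samples, with optional Benjamini-Hochberg adjustment across all
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_screen",
    "restored_features",
    "AssociationMatrix",
    "spearman_matrix",
]


def _group_matrix(table: pd.DataFrame, sample_sheet: pd.DataFrame, group: str) -> np.ndarray:
    samples = sample_sheet.loc[sample_sheet["group"] == group, "sample"].tolist()
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has {len(samples)} sample(s); need >= 2")
    missing = [s for s in samples if s not in table.columns]
    if missing:
        raise ValueError(f"samples {missing} of group {group!r} absent from the feature table")
    return table[samples].to_numpy(dtype=float)


def differential_screen(table: pd.DataFrame, sample_sheet: pd.DataFrame,
                        group_a: str, group_b: str, *,
                        scores: pd.Series | None = None,
                        p_thresh: float | None = 0.05,
                        lfc_thresh: float | None = 0.2,
                        score_thresh: float | None = 38.1,
                        pseudo_count: float | None = None) -> pd.DataFrame:
    """Per-feature Welch t-test + fold-change + annotation-score screen.

    ``log2fc`` is log2 of the ratio of group means (A over B) with a
    pseudo-count (default: half the smallest non-zero abundance in the
    table).  Passing a threshold of ``None`` disables that gate; disabling a
    gate can only grow the passing set.  Features with zero variance in both
    groups get p = 1 if the means are equal and p = 0 otherwise, flagged in
    a ``degenerate`` column with a warning.

    Returns a DataFrame indexed like ``table`` with columns ``t``,
    ``p_value``, ``log2fc``, ``score``, ``degenerate`` and ``pass``.
    """
    a = _group_matrix(table, sample_sheet, group_a)
    b = _group_matrix(table, sample_sheet, group_b)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")
    if score_thresh is not None and scores is None:
        raise ValueError("score_thresh set but no annotation scores provided")

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)

    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} feature(s) constant in both groups; "
                      "p set by the exact-equality rule")
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        t = np.where(degenerate, 0.0, t)

    if pseudo_count is None:
        nonzero = table.to_numpy()[table.to_numpy() > 0]
        pseudo_count = float(nonzero.min()) / 2.0 if nonzero.size else 0.0
    lfc = np.log2((a.mean(axis=1) + pseudo_count) / (b.mean(axis=1) + pseudo_count))

    res = pd.DataFrame({"t": t, "p_value": p, "log2fc": lfc}, index=table.index)
    res["score"] = scores.reindex(table.index) if scores is not None else np.nan
    res["degenerate"] = degenerate
    passing = pd.Series(True, index=table.index)
    if p_thresh is not None:
        passing &= res["p_value"] < p_thresh
    if lfc_thresh is not None:
        passing &= res["log2fc"].abs() > lfc_thresh
    if score_thresh is not None:
        passing &= res["score"] >= score_thresh
    res["pass"] = passing
    return res


def restored_features(diff_disease: pd.DataFrame, diff_treatment: pd.DataFrame,
                      require_significance: bool = True,
                      mode: str = "opposite_sign") -> set[str]:
    """Features the treatment moves back toward the healthy (sham) level.

    ``diff_disease`` screens model vs sham and ``diff_treatment`` screens
    treatment vs model (same feature universe).  ``mode="opposite_sign"``
    (default) demands opposite log2 fold-change signs in the two contrasts;
    ``mode="toward_baseline"`` demands that the treatment shift brings the
    cumulative log2 fold change closer to zero.  With
    ``require_significance`` both contrasts must also pass the screen.
    Features with a zero fold change in either contrast are excluded.
    """
    if set(diff_disease.index) != set(diff_treatment.index):
        raise ValueError("the two screens must cover the same features")
    if mode not in ("opposite_sign", "toward_baseline"):
        raise ValueError("mode must be 'opposite_sign' or 'toward_baseline'")
    dt = diff_treatment.reindex(diff_disease.index)
    d_lfc = diff_disease["log2fc"]
    t_lfc = dt["log2fc"]

    mask = (d_lfc != 0) & (t_lfc != 0)
    if mode == "opposite_sign":
        mask &= np.sign(d_lfc) != np.sign(t_lfc)
    else:
        mask &= (d_lfc + t_lfc).abs() < d_lfc.abs()
    if require_significance:
        mask &= diff_disease["pass"] & dt["pass"]
    return set(diff_disease.index[mask])


@dataclass(frozen=True)
class AssociationMatrix:
    """Taxon x metabolite Spearman correlations with p-values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        long = self.rho.stack().rename("rho").to_frame()
        long["p"] = self.p.stack()
        if self.p_adj is not None:
            long["p_adj"] = self.p_adj.stack()
        long.index.names = ["taxon", "feature"]
        return long.reset_index()


def spearman_matrix(taxa_table: pd.DataFrame, metabolite_table: pd.DataFrame,
                    adjust: str | None = "fdr_bh") -> AssociationMatrix:
    """Pairwise Spearman correlation between every taxon and every metabolite.

    Computed over the samples shared by the two tables (>= 4 required), with
    tie-corrected ranks.  Constant features yield missing correlations with
    a warning.  ``adjust`` names a statsmodels multiple-testing method
    applied across all pairs (None to skip).
    """
    shared = [s for s in taxa_table.columns if s in set(metabolite_table.columns)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, found {len(shared)}")
    x = taxa_table[shared].to_numpy(dtype=float)
    y = metabolite_table[shared].to_numpy(dtype=float)
    n_t, n_m = len(x), len(y)

    const_t = x.std(axis=1) == 0
    const_m = y.std(axis=1) == 0
    if const_t.any() or const_m.any():
        warnings.warn(f"{int(const_t.sum())} taxa and {int(const_m.sum())} metabolite(s) are "
                      "constant; their correlations are reported as missing")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho_full, p_full = stats.spearmanr(np.vstack([x, y]), axis=1)
    if n_t + n_m == 2:  # scipy returns a scalar for exactly two variables
        rho_full = np.array([[1.0, rho_full], [rho_full, 1.0]])
        p_full = np.array([[0.0, p_full], [p_full, 0.0]])
    rho = np.asarray(rho_full)[:n_t, n_t:].copy()
    p = np.asarray(p_full)[:n_t, n_t:].copy()
    rho[const_t, :] = np.nan
    rho[:, const_m] = np.nan
    p[const_t, :] = np.nan
    p[:, const_m] = np.nan

    rho_df = pd.DataFrame(rho, index=taxa_table.index, columns=metabolite_table.index)
    p_df = pd.DataFrame(p, index=taxa_table.index, columns=metabolite_table.index)
    p_adj_df = None
    if adjust is not None:
        flat = p_df.to_numpy().ravel()
        finite = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if finite.any():
            adj[finite] = multipletests(flat[finite], method=adjust)[1]
        p_adj_df = pd.DataFrame(adj.reshape(p_df.shape), index=p_df.index, columns=p_df.columns)
    return AssociationMatrix(rho=rho_df, p=p_df, p_adj=p_adj_df)
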