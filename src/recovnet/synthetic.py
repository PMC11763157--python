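"""Synthetic study generators with planted ground truth.

Every pipeline input — the gene x sample expression table, the PPI edge
table, plate-assay readouts, and the paired metabolite/taxon tables — can be
generated here with a known, planted truth, so every downstream estimator
(fold change, EoR, combination index, Spearman rho) can be checked against
the value it should recover.

Randomness discipline: each generator derives an independent child stream
from ``(seed, stage-label)`` via :func:`child_rng`, so re-running a single
stage reproduces exactly what a full run would have produced for it.

Distributional choices (lognormal expression noise, Erdos-Renyi PPI wiring,
Gaussian-copula taxon/metabolite coupling) are stand-ins: no public data
accompany the study these tables emulate, so the generators aim for the
right estimator behaviour (positive abundances, rank-faithful correlations,
mean-faithful fold changes), not for realism of marginal distributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
import networkx as nx

__all__ = [
    "StudyDesign",
    "ExpressionTruth",
    "AssayTruth",
    "MetaboliteTruth",
    "OmicsTruth",
    "child_rng",
    "gen_expression_study",
    "gen_ppi",
    "gen_assay",
    "gen_paired_omics",
    "gen_metabolite_study",
    "gen_gene_universe",
    "demo_recovery_profile",
    "RECOVERY_BLOCKS",
]


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Derive a reproducible child generator from a master seed and a stage label.

    The label is hashed with CRC-32 and combined with the seed into a
    ``SeedSequence``, so streams for different stages are statistically
    independent yet individually re-derivable.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Expression study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Layout of a sham/model/treatment expression study.

    Parameters
    ----------
    genes : gene identifiers for the whole measured transcriptome.
    disease_genes : subset of ``genes`` dysregulated by disease induction.
    arms : treatment group names; the combination arm is simply one of them.
    arm_eor : planted target EoR (percent, <= 100) per arm, either a scalar
        applied to every disease gene or an array aligned with
        ``disease_genes``.  EoR = 100 means the arm restores the gene's
        fold change exactly; values <= 0 mean no recovery / wrong direction.
    disease_log2fc : either an array of per-disease-gene log2 fold changes
        (sham relative to model) or a ``(lo, hi)`` magnitude range to draw
        from with random sign.
    noise_cv : coefficient of variation of multiplicative lognormal
        measurement noise.  0 gives exact group means.
    """

    genes: tuple[str, ...]
    disease_genes: tuple[str, ...]
    arm_eor: Mapping[str, float | np.ndarray]
    sham: str = "sham"
    model: str = "model"
    arms: tuple[str, ...] = ("CF", "BBP", "CF+BBP")
    n_replicates: int = 3
    disease_log2fc: tuple[float, float] | np.ndarray = (0.5, 3.0)
    noise_cv: float = 0.2
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        groups = (self.sham, self.model, *self.arms)
        if len(set(groups)) != len(groups):
            raise ValueError(f"group names must be unique, got {groups}")
        if len(self.genes) == 0:
            raise ValueError("need at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        missing = set(self.disease_genes) - set(self.genes)
        if missing:
            raise ValueError(f"disease genes not in gene universe: {sorted(missing)[:5]} ...")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group (fold-change means undefined otherwise)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        missing_arms = set(self.arms) - set(self.arm_eor)
        if missing_arms:
            raise ValueError(f"arm_eor missing arms: {sorted(missing_arms)}")
        for arm in self.arms:
            e = np.atleast_1d(np.asarray(self.arm_eor[arm], dtype=float))
            if e.size not in (1, len(self.disease_genes)):
                raise ValueError(
                    f"arm_eor[{arm!r}] must be scalar or match the {len(self.disease_genes)} disease genes"
                )
            if np.any(e > 100):
                raise ValueError("planted EoR must be <= 100")

    @classmethod
    def from_counts(cls, n_genes: int, n_disease_genes: int, arm_eor: Mapping[str, float | np.ndarray],
                    **kwargs) -> "StudyDesign":
        """Build a design with auto-named genes; the first ``n_disease_genes`` are dysregulated."""
        if not (0 < n_disease_genes <= n_genes):
            raise ValueError("need 0 < n_disease_genes <= n_genes")
        genes = tuple(f"G{i:05d}" for i in range(n_genes))
        return cls(genes=genes, disease_genes=genes[:n_disease_genes], arm_eor=arm_eor, **kwargs)

    @property
    def groups(self) -> tuple[str, ...]:
        return (self.sham, self.model, *self.arms)


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted truth of an expression study.

    ``eor`` holds the planted EoR per gene x arm (non-disease genes carry the
    trivial value 100: their fold change is 1 in every contrast).
    ``branch`` records which inversion of the EoR formula realised each
    target: EoR is symmetric about a fold-change ratio of 1, so a target
    value corresponds to ratio ``eor/100`` ("under", between model and sham)
    or ``2 - eor/100`` ("over", past sham); non-positive targets force the
    "over" branch to keep fold changes positive.
    """

    fc_disease: pd.Series            # per gene, linear Foldchange(sham/model)
    fc_arm: pd.DataFrame             # per gene x arm, linear Foldchange(arm/model)
    eor: pd.DataFrame                # per gene x arm, planted EoR (percent)
    recovered: pd.DataFrame          # per gene x arm, planted EoR > 0
    branch: pd.DataFrame             # per gene x arm, "under" | "over"


def _eor_to_ratio(eor: np.ndarray, branch: str = "under") -> tuple[np.ndarray, np.ndarray]:
    """Invert EoR = 100 - |100 - 100 r| to the fold-change ratio r.

    Returns (ratio, branch_labels). Positive targets use the requested branch
    (default "under": r = eor/100 in (0, 1], i.e. partial movement from model
    toward sham); non-positive targets only admit the "over" branch
    r = 2 - eor/100 >= 2, since r must stay positive.
    """
    eor = np.asarray(eor, dtype=float)
    under = eor / 100.0
    over = 2.0 - eor / 100.0
    use_under = (eor > 0) & (branch == "under")
    ratio = np.where(use_under, under, over)
    labels = np.where(use_under, "under", "over")
    return ratio, labels


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-preserving multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=shape))


def gen_expression_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Generate a gene x sample expression table realising the planted design.

    Group means realise the planted fold changes exactly; noise is
    multiplicative lognormal with the design's CV applied on top, so at
    ``noise_cv = 0`` every downstream ratio-of-means estimator returns the
    planted value to floating-point precision.

    Returns ``(expression, sample_sheet, truth)`` where ``sample_sheet`` has
    columns ``sample`` and ``group``.
    """
    rng = child_rng(design.seed, "expression")
    genes = list(design.genes)
    n = len(genes)
    idx = pd.Index(genes, name="gene")
    pos = {g: i for i, g in enumerate(genes)}
    disease_idx = [pos[g] for g in design.disease_genes]

    baseline = 2.0 ** rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, n)

    # planted disease fold change (sham relative to model); 1 for unaffected genes
    fc_disease = np.ones(n)
    if isinstance(design.disease_log2fc, tuple):
        lo, hi = design.disease_log2fc
        mag = rng.uniform(lo, hi, len(disease_idx))
        sign = rng.choice([-1.0, 1.0], len(disease_idx))
        fc_disease[disease_idx] = 2.0 ** (sign * mag)
    else:
        l2 = np.asarray(design.disease_log2fc, dtype=float)
        if l2.shape != (len(disease_idx),):
            raise ValueError("disease_log2fc array must match disease_genes")
        fc_disease[disease_idx] = 2.0 ** l2

    sham_mean = baseline
    model_mean = baseline / fc_disease

    means = {design.sham: sham_mean, design.model: model_mean}
    fc_arm = pd.DataFrame(1.0, index=idx, columns=list(design.arms))
    eor_planted = pd.DataFrame(100.0, index=idx, columns=list(design.arms))
    branch = pd.DataFrame("under", index=idx, columns=list(design.arms))
    for arm in design.arms:
        target = np.broadcast_to(
            np.atleast_1d(np.asarray(design.arm_eor[arm], dtype=float)), (len(disease_idx),)
        )
        ratio, labels = _eor_to_ratio(target)
        fa = np.ones(n)
        # ratio = fc_arm / fc_disease  =>  arm mean = model mean * ratio * fc_disease
        fa[disease_idx] = ratio * fc_disease[disease_idx]
        means[arm] = model_mean * fa
        fc_arm[arm] = fa
        col = np.full(n, 100.0)
        col[disease_idx] = target
        eor_planted[arm] = col
        bcol = np.full(n, "under", dtype=object)
        bcol[disease_idx] = labels
        branch[arm] = bcol

    cols, data, rows = [], [], []
    for group in design.groups:
        noise = _lognormal_noise(rng, design.noise_cv, (n, design.n_replicates))
        block = means[group][:, None] * noise
        for r in range(design.n_replicates):
            name = f"{group}_{r + 1}"
            cols.append(name)
            rows.append((name, group))
            data.append(block[:, r])
    expression = pd.DataFrame(np.column_stack(data), index=idx, columns=cols)
    sample_sheet = pd.DataFrame(rows, columns=["sample", "group"])

    truth = ExpressionTruth(
        fc_disease=pd.Series(fc_disease, index=idx, name="fc_disease"),
        fc_arm=fc_arm,
        eor=eor_planted,
        recovered=eor_planted > 0,
        branch=branch,
    )
    return expression, sample_sheet, truth


# ---------------------------------------------------------------------------
# PPI edge table
# ---------------------------------------------------------------------------

def gen_ppi(genes: Sequence[str], mean_degree: float, seed: int = 0) -> pd.DataFrame:
    """Random PPI edge table: Erdos-Renyi wiring with the given expected mean degree.

    Returns a simple undirected edge table (``gene_a``, ``gene_b``,
    ``confidence``) with confidences uniform in [0, 1].  Degree-distribution
    realism is explicitly not attempted.
    """
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ValueError("need >= 2 genes to wire a PPI table")
    if mean_degree < 0:
        raise ValueError("mean_degree must be >= 0")
    if mean_degree > n - 1:
        raise ValueError(f"mean_degree {mean_degree} > n-1 = {n - 1}: denser than the complete graph")
    rng = child_rng(seed, "ppi")
    p = mean_degree / (n - 1)
    graph = nx.fast_gnp_random_graph(n, p, seed=rng)
    edges = np.array(list(graph.edges()), dtype=int).reshape(-1, 2)
    conf = rng.uniform(0.0, 1.0, len(edges))
    return pd.DataFrame({
        "gene_a": [genes[i] for i in edges[:, 0]],
        "gene_b": [genes[j] for j in edges[:, 1]],
        "confidence": conf,
    })


# ---------------------------------------------------------------------------
# Plate assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayTruth:
    """Planted truth of a plate assay: normalized effects and the implied Bliss CI."""

    effects: dict[str, float]        # per arm (and combination), E in [0, 1]
    group_means: dict[str, float]    # raw readout group means
    expected: float | None           # Bliss expectation for the planted mono pair
    ci: float | None                 # planted combination index, if a combo was named


def gen_assay(true_effects: Mapping[str, float], n_replicates: int = 3, noise_sd: float = 0.0,
              seed: int = 0, control: str = "control", model: str = "model",
              control_mean: float = 0.1, model_mean: float = 1.0,
              mono_arms: tuple[str, str] | None = None, combo: str | None = None,
              ) -> tuple[pd.DataFrame, AssayTruth]:
    """Emulate plate readouts (e.g. absorbances) realising planted normalized effects.

    The model group sits at ``model_mean`` and the control at ``control_mean``;
    an arm with planted effect E sits at ``model + E*(control - model)``, so at
    zero noise ``normalize_effect`` recovers E exactly (control -> 1, model -> 0).
    Gaussian noise of the given SD is added per well.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    if control_mean == model_mean:
        raise ValueError("control and model means must differ (assay window)")
    for arm, e in true_effects.items():
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"true effect for {arm!r} must be in [0, 1], got {e}")

    rng = child_rng(seed, "assay")
    means = {control: control_mean, model: model_mean}
    for arm, e in true_effects.items():
        means[arm] = model_mean + e * (control_mean - model_mean)

    rows = []
    for group, mu in means.items():
        vals = mu + rng.normal(0.0, noise_sd, n_replicates) if noise_sd else np.full(n_replicates, mu)
        for r, v in enumerate(vals):
            rows.append((f"{group}_{r + 1}", group, v))
    readouts = pd.DataFrame(rows, columns=["well", "group", "value"])

    expected = ci = None
    if mono_arms is not None:
        ea, eb = (true_effects[a] for a in mono_arms)
        expected = ea + eb - ea * eb
        if combo is not None:
            ci = expected / true_effects[combo]
    truth = AssayTruth(effects=dict(true_effects), group_means=means, expected=expected, ci=ci)
    return readouts, truth


# ---------------------------------------------------------------------------
# Metabolite study (screening / restoration fixtures)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteTruth:
    restored: tuple[str, ...]        # features shifted by disease and reversed by the combination
    disease_only: tuple[str, ...]    # shifted by disease, untouched by treatment
    null: tuple[str, ...]            # unshifted everywhere
    disease_log2fc: pd.Series        # planted log2 fc of model relative to sham


def gen_metabolite_study(n_restored: int = 70, n_disease_only: int = 40, n_null: int = 90,
                         n_per_group: int = 6, sham: str = "sham", model: str = "model",
                         restore_fraction: Mapping[str, float] | None = None,
                         lfc: float = 1.5, noise_sigma: float = 0.2,
                         score_high: tuple[float, float] = (45.0, 95.0),
                         score_low: tuple[float, float] = (5.0, 35.0),
                         seed: int = 0,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, MetaboliteTruth]:
    """Feature x sample abundance table with planted disease shifts and treatment reversal.

    Three planted classes: *restored* features shift by ±``lfc`` (log2) in the
    model and are pulled back toward sham by each treatment arm according to
    ``restore_fraction`` (the arm with fraction 1.0 restores them fully);
    *disease-only* features shift but no arm moves them; *null* features never
    move.  Restored features draw annotation scores from ``score_high`` and
    the rest from ``score_low``, emulating that the compounds of interest are
    the confidently identified ones.

    Returns ``(abundance, sample_sheet, scores, truth)``.
    """
    if n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    if min(n_restored, n_disease_only, n_null) < 0:
        raise ValueError("feature counts must be >= 0")
    if restore_fraction is None:
        restore_fraction = {"CF": 0.5, "BBP": 0.2, "CF+BBP": 1.0}
    rng = child_rng(seed, "metabolites")

    n_feat = n_restored + n_disease_only + n_null
    feats = [f"M{i:04d}" for i in range(n_feat)]
    restored = tuple(feats[:n_restored])
    disease_only = tuple(feats[n_restored:n_restored + n_disease_only])
    null = tuple(feats[n_restored + n_disease_only:])

    base_log2 = rng.uniform(8.0, 12.0, n_feat)
    shift = np.zeros(n_feat)
    n_shifted = n_restored + n_disease_only
    shift[:n_shifted] = rng.choice([-1.0, 1.0], n_shifted) * lfc

    groups = [sham, model, *restore_fraction]
    log2_means = {sham: base_log2, model: base_log2 + shift}
    for arm, frac in restore_fraction.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError("restore_fraction values must be in [0, 1]")
        arm_shift = shift.copy()
        arm_shift[:n_restored] = shift[:n_restored] * (1.0 - frac)
        log2_means[arm] = base_log2 + arm_shift

    cols, data, rows = [], [], []
    for group in groups:
        noise = rng.normal(0.0, noise_sigma, (n_feat, n_per_group))
        block = 2.0 ** (log2_means[group][:, None]) * np.exp(noise)
        for r in range(n_per_group):
            name = f"{group}_m{r + 1}"
            cols.append(name)
            rows.append((name, group))
            data.append(block[:, r])
    abundance = pd.DataFrame(np.column_stack(data), index=pd.Index(feats, name="feature"), columns=cols)
    sample_sheet = pd.DataFrame(rows, columns=["sample", "group"])

    scores = np.empty(n_feat)
    scores[:n_restored] = rng.uniform(*score_high, n_restored)
    scores[n_restored:] = rng.uniform(*score_low, n_feat - n_restored)
    scores = pd.Series(scores, index=abundance.index, name="score")

    truth = MetaboliteTruth(
        restored=restored, disease_only=disease_only, null=null,
        disease_log2fc=pd.Series(shift, index=abundance.index, name="disease_log2fc"),
    )
    return abundance, sample_sheet, scores, truth


# ---------------------------------------------------------------------------
# Paired taxon / metabolite tables (Gaussian copula)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmicsTruth:
    rho: pd.DataFrame                # planted Spearman taxon x metabolite matrix
    latent_pearson: pd.DataFrame     # Pearson correlations used in the copula


def gen_paired_omics(n_taxa: int, n_metabolites: int, n_samples: int,
                     rho: np.ndarray | pd.DataFrame, seed: int = 0,
                     taxa_names: Sequence[str] | None = None,
                     metabolite_names: Sequence[str] | None = None,
                     post_noise_sd: float = 0.0,
                     score_range: tuple[float, float] = (0.0, 100.0),
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, OmicsTruth]:
    """Paired taxon and metabolite tables with planted Spearman correlations.

    A Gaussian copula plants the correlations: latent normals get the Pearson
    correlation ``2 sin(pi rho_s / 6)`` that induces Spearman ``rho_s``, then
    strictly monotone (exponential) maps turn them into positive abundances,
    preserving ranks.  With ``post_noise_sd = 0`` a planted rho of ±1 is
    recovered exactly.  If the requested cross-correlations are jointly
    infeasible the latent covariance is projected to the nearest PSD matrix
    (eigenvalue clipping) with a warning.

    Metabolite features carry annotation scores uniform over ``score_range``.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if post_noise_sd < 0:
        raise ValueError("post_noise_sd must be >= 0")
    rho_arr = np.asarray(rho, dtype=float)
    if rho_arr.shape != (n_taxa, n_metabolites):
        raise ValueError(f"rho must be {n_taxa} x {n_metabolites}, got {rho_arr.shape}")
    if np.any(np.abs(rho_arr) > 1):
        raise ValueError("planted rho entries must lie in [-1, 1]")
    taxa_names = list(taxa_names) if taxa_names is not None else [f"T{i:03d}" for i in range(n_taxa)]
    metabolite_names = (list(metabolite_names) if metabolite_names is not None
                        else [f"M{i:03d}" for i in range(n_metabolites)])

    rng = child_rng(seed, "omics")
    cross = 2.0 * np.sin(np.pi * rho_arr / 6.0)
    dim = n_taxa + n_metabolites
    sigma = np.eye(dim)
    sigma[:n_taxa, n_taxa:] = cross
    sigma[n_taxa:, :n_taxa] = cross.T
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-10:
        warnings.warn("planted correlation matrix is not jointly feasible; "
                      "projecting latent covariance to the nearest PSD matrix")
        w = np.clip(w, 1e-10, None)
        sigma = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)

    z = rng.multivariate_normal(np.zeros(dim), sigma, size=n_samples, method="svd")
    if post_noise_sd:
        z = z + rng.normal(0.0, post_noise_sd, z.shape)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    # strictly monotone per-feature maps: ranks (hence Spearman) are inherited
    # from z.  A true compositional closure would divide by per-sample totals,
    # which is not rank-preserving; a fixed divisor keeps abundances fraction-like
    # without disturbing the planted correlations.
    taxa = pd.DataFrame(np.exp(z[:, :n_taxa]).T / (np.e * n_taxa),
                        index=pd.Index(taxa_names, name="taxon"), columns=samples)
    mets = pd.DataFrame(np.exp(4.0 + z[:, n_taxa:]).T,
                        index=pd.Index(metabolite_names, name="feature"), columns=samples)
    scores = pd.Series(rng.uniform(*score_range, n_metabolites), index=mets.index, name="score")

    truth = OmicsTruth(
        rho=pd.DataFrame(rho_arr, index=taxa.index, columns=mets.index),
        latent_pearson=pd.DataFrame(cross, index=taxa.index, columns=mets.index),
    )
    return taxa, mets, scores, truth


# ---------------------------------------------------------------------------
# Gene universe / reference list, and the bundled demo recovery profile
# ---------------------------------------------------------------------------

def gen_gene_universe(n_universe: int, n_reference: int, n_shared: int, seed: int = 0,
                      ) -> tuple[list[str], list[str]]:
    """A transcriptome gene universe and a disease reference list sharing ``n_shared`` ids.

    Reference-only genes get an ``X`` prefix so they can never collide with
    universe ids.
    """
    if n_shared > min(n_universe, n_reference):
        raise ValueError("n_shared cannot exceed either list size")
    rng = child_rng(seed, "universe")
    universe = [f"G{i:05d}" for i in range(n_universe)]
    shared = list(rng.choice(n_universe, size=n_shared, replace=False))
    reference = [universe[i] for i in shared] + [f"X{i:05d}" for i in range(n_reference - n_shared)]
    rng.shuffle(reference)
    return universe, reference


# Planted recovery structure over the disease-network genes, one row per block:
# (n_genes, EoR in combination arm, EoR in CF arm, EoR in BBP arm, wired into the PPI).
# The blocks jointly plant per-arm recovery counts of 902 / 804 / 437 (of the
# 1447 wired genes), a combination-specific set of 250, a differential-EoR set
# (margin > 20 EoR points over both mono arms) of 492 overlapping the specific
# set in 205 genes, hence a union of 537.  The 92 unwired genes never enter
# the network and are excluded from all counts.
RECOVERY_BLOCKS: tuple[tuple[int, float, float, float, bool], ...] = (
    (205, 80.0, -50.0, -50.0, True),   # specific AND differential
    (45, 10.0, -5.0, -5.0, True),      # specific, margins too small for differential
    (287, 90.0, 30.0, -40.0, True),    # differential, CF also recovers
    (365, 50.0, 40.0, -10.0, True),    # combo+CF recover, margins too small
    (152, -30.0, 20.0, 20.0, True),    # mono-only recovery
    (285, -40.0, -20.0, 25.0, True),   # BBP-only recovery
    (108, -60.0, -30.0, -35.0, True),  # recovered by nothing
    (92, 50.0, 50.0, 50.0, False),     # unwired: dropped from the network
)


def demo_recovery_profile(combo: str = "CF+BBP", arms: tuple[str, str] = ("CF", "BBP"),
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted per-gene EoR targets for the bundled demo study.

    Returns ``(eor_targets, wired)`` where ``eor_targets`` has one row per
    disease gene (unlabelled positional index) and one column per arm, and
    ``wired`` marks the genes that receive PPI edges.
    """
    n_total = sum(b[0] for b in RECOVERY_BLOCKS)
    targets = {combo: np.empty(n_total), arms[0]: np.empty(n_total), arms[1]: np.empty(n_total)}
    wired = np.empty(n_total, dtype=bool)
    pos = 0
    for n, e_combo, e_a, e_b, w in RECOVERY_BLOCKS:
        sl = slice(pos, pos + n)
        targets[combo][sl] = e_combo
        targets[arms[0]][sl] = e_a
        targets[arms[1]][sl] = e_b
        wired[sl] = w
        pos += n
    return pd.DataFrame(targets), wired
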