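"""End-to-end orchestration: simulate -> network -> EoR -> synergy -> metabolites -> report.

A single :class:`RunConfig` governs every stage; :func:`run_all` executes the
stages in dependency order, persists each stage's outputs as plain text
(TSV / JSON / GraphML) under an output directory, and writes a
machine-readable :class:`RunSummary` plus the resolved configuration for
provenance.  Every number in the summary is re-derivable from the persisted
stage outputs.

The bundled default configuration describes the demo study: a transcriptome
universe of 32,545 genes intersected with a 1641-gene disease reference list
(1539 shared), a PPI wiring that leaves 92 shared genes isolated (1447
network nodes, ~44.9k edges), a planted recovery structure giving per-arm
recovery counts of 902 / 804 / 437 and selection sets of 250 / 492 / 537
genes, an assay with planted effects (0.3, 0.4, 0.8) -> CI 0.725, a
metabolite study with 70 planted restored features, and a 4 taxon x 4
metabolite association block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metabolites as met_mod
from . import network as net_mod
from . import scoring as eor_mod
from . import synergy as syn_mod
from . import synthetic as sim_mod

__all__ = ["RunConfig", "RunSummary", "PipelineError", "validate_config", "run_all",
           "simulate_stage", "network_stage", "eor_stage", "synergy_stage",
           "metabolites_stage"]

log = logging.getLogger("recovnet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


_DEMO_RHO = (
    # taxa: a Lactobacillus-like genus associating positively with the restored
    # metabolites, three harmful genera negatively.  Magnitudes are capped so the
    # joint copula covariance stays positive semi-definite (cross-block spectral
    # norm < 1) — the planted values are then realisable exactly.
    (0.45, 0.45, 0.2, 0.0),    # Lactobacillus
    (-0.25, 0.0, -0.25, 0.0),  # Helicobacter
    (-0.25, -0.25, -0.25, 0.0),# Bilophila
    (-0.2, -0.2, 0.0, 0.0),    # Butyricimonas
)
_DEMO_TAXA = ("Lactobacillus", "Helicobacter", "Bilophila", "Butyricimonas")
_DEMO_METS = ("hemorphin-4", "glutamylalanine", "oleoylcholine", "isokobusone")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs. Defaults describe the bundled demo study."""

    seed: int = 0
    # --- study design / simulate stage -------------------------------------
    sham: str = "sham"
    model: str = "model"
    arms: tuple[str, str] = ("CF", "BBP")
    combo: str = "CF+BBP"
    n_replicates: int = 3
    noise_cv: float = 0.0
    n_universe: int = 32545
    n_reference: int = 1641
    n_shared: int = 1539
    mean_degree: float = 62.03  # 2 * 44879 / 1447: the density of the emulated network
    # --- network stage ------------------------------------------------------
    min_confidence: float = 0.0
    # --- EoR stage ----------------------------------------------------------
    pseudo_count: float = 0.0
    eor_threshold: float = 0.0
    delta: float = 0.2
    delta_scale: str = "fraction"
    mono_mode: str = "all"
    # --- synergy stage ------------------------------------------------------
    assay_effects: dict = field(default_factory=lambda: {"CF": 0.3, "BBP": 0.4, "CF+BBP": 0.8})
    assay_replicates: int = 3
    assay_noise_sd: float = 0.02
    additive_tol: float = 0.05
    n_boot: int = 0
    # --- metabolite stage ---------------------------------------------------
    n_restored: int = 70
    n_disease_only: int = 40
    n_null: int = 90
    met_samples_per_group: int = 6
    met_lfc: float = 1.5
    met_noise_sigma: float = 0.2
    p_thresh: float = 0.05
    lfc_thresh: float = 0.2
    score_thresh: float = 38.1
    restored_mode: str = "opposite_sign"
    restored_require_significance: bool = True
    # --- association stage --------------------------------------------------
    omics_samples: int = 30
    adjust_method: str = "fdr_bh"

    @property
    def all_arms(self) -> tuple[str, ...]:
        return (*self.arms, self.combo)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arms",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        return d

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Validate ranges and consistency; returns the full list of problems (empty if ok)."""
    errs = []

    def _range(name, lo, hi):
        v = getattr(config, name)
        if not (lo <= v <= hi):
            errs.append(f"{name}={v} outside [{lo}, {hi}]")

    groups = (config.sham, config.model, *config.arms, config.combo)
    if len(set(groups)) != len(groups):
        errs.append(f"group names not unique: {groups}")
    if config.n_replicates < 2:
        errs.append("n_replicates must be >= 2")
    if config.noise_cv < 0:
        errs.append("noise_cv must be >= 0")
    if not (0 < config.n_shared <= min(config.n_universe, config.n_reference)):
        errs.append("need 0 < n_shared <= min(n_universe, n_reference)")
    if not (0 <= config.mean_degree < config.n_shared - 1):
        errs.append("mean_degree must be in [0, n_shared - 1)")
    _range("min_confidence", 0.0, 1.0)
    if config.pseudo_count < 0:
        errs.append("pseudo_count must be >= 0")
    if config.delta < 0:
        errs.append("delta must be >= 0")
    if config.delta_scale not in ("fraction", "percent"):
        errs.append("delta_scale must be 'fraction' or 'percent'")
    if config.mono_mode not in ("all", "any"):
        errs.append("mono_mode must be 'all' or 'any'")
    for arm, e in config.assay_effects.items():
        if not (0.0 <= e <= 1.0):
            errs.append(f"assay effect for {arm!r} must be in [0, 1]")
    missing = {*config.arms, config.combo} - set(config.assay_effects)
    if missing:
        errs.append(f"assay_effects missing arms: {sorted(missing)}")
    if config.assay_noise_sd < 0:
        errs.append("assay_noise_sd must be >= 0")
    if config.additive_tol < 0:
        errs.append("additive_tol must be >= 0")
    if config.n_boot < 0:
        errs.append("n_boot must be >= 0")
    _range("p_thresh", 0.0, 1.0)
    if config.lfc_thresh < 0:
        errs.append("lfc_thresh must be >= 0")
    if config.met_samples_per_group < 2:
        errs.append("met_samples_per_group must be >= 2")
    if config.omics_samples < 4:
        errs.append("omics_samples must be >= 4")
    if config.restored_mode not in ("opposite_sign", "toward_baseline"):
        errs.append("restored_mode must be 'opposite_sign' or 'toward_baseline'")
    return errs


# ---------------------------------------------------------------------------
# Stages.  Each reads its inputs from, and persists its outputs to, `outdir`.
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig, outdir: Path) -> dict:
    """Generate every pipeline input with planted truth and persist as text files."""
    outdir.mkdir(parents=True, exist_ok=True)
    universe, reference = sim_mod.gen_gene_universe(
        config.n_universe, config.n_reference, config.n_shared, seed=config.seed)
    shared = sorted(set(universe) & set(reference))

    profile, wired = sim_mod.demo_recovery_profile(combo=config.combo, arms=config.arms)
    if len(profile) != len(shared):
        raise PipelineError(
            f"simulate: recovery profile covers {len(profile)} genes but {len(shared)} are shared; "
            "the demo profile requires n_shared = 1539")
    # assign profile rows to shared genes in a seed-determined order
    rng = sim_mod.child_rng(config.seed, "profile-assignment")
    order = rng.permutation(len(shared))
    assigned = [shared[i] for i in order]
    arm_eor = {arm: profile[arm].to_numpy() for arm in profile.columns}

    design = sim_mod.StudyDesign(
        genes=tuple(universe), disease_genes=tuple(assigned), arm_eor=arm_eor,
        sham=config.sham, model=config.model, arms=(*config.arms, config.combo),
        n_replicates=config.n_replicates, noise_cv=config.noise_cv, seed=config.seed)
    expression, sample_sheet, expr_truth = sim_mod.gen_expression_study(design)

    wired_genes = [g for g, w in zip(assigned, wired) if w]
    edges = sim_mod.gen_ppi(wired_genes, config.mean_degree, seed=config.seed)

    readouts, assay_truth = sim_mod.gen_assay(
        config.assay_effects, n_replicates=config.assay_replicates,
        noise_sd=config.assay_noise_sd, seed=config.seed,
        mono_arms=config.arms, combo=config.combo)

    met_table, met_samples, met_scores, met_truth = sim_mod.gen_metabolite_study(
        n_restored=config.n_restored, n_disease_only=config.n_disease_only,
        n_null=config.n_null, n_per_group=config.met_samples_per_group,
        sham=config.sham, model=config.model,
        restore_fraction={config.arms[0]: 0.5, config.arms[1]: 0.2, config.combo: 1.0},
        lfc=config.met_lfc, noise_sigma=config.met_noise_sigma, seed=config.seed)

    taxa, omics_mets, _, omics_truth = sim_mod.gen_paired_omics(
        len(_DEMO_TAXA), len(_DEMO_METS), config.omics_samples,
        rho=np.asarray(_DEMO_RHO), seed=config.seed,
        taxa_names=_DEMO_TAXA, metabolite_names=_DEMO_METS)

    expression.to_csv(outdir / "expression.tsv", sep="\t")
    sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    (outdir / "universe_genes.txt").write_text("\n".join(universe) + "\n")
    (outdir / "reference_genes.txt").write_text("\n".join(reference) + "\n")
    edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    readouts.to_csv(outdir / "assay_readouts.tsv", sep="\t", index=False)
    met_table.to_csv(outdir / "metabolite_abundance.tsv", sep="\t")
    met_samples.to_csv(outdir / "metabolite_samples.tsv", sep="\t", index=False)
    met_scores.to_csv(outdir / "metabolite_scores.tsv", sep="\t")
    taxa.to_csv(outdir / "taxon_abundance.tsv", sep="\t")
    omics_mets.to_csv(outdir / "omics_metabolites.tsv", sep="\t")

    truth = {
        "n_universe": len(universe), "n_reference": len(reference), "n_shared": len(shared),
        "n_wired": len(wired_genes),
        "planted_recovered": {arm: int((profile[arm].to_numpy()[wired] > 0).sum())
                              for arm in profile.columns},
        "planted_ci": assay_truth.ci,
        "planted_assay_effects": assay_truth.effects,
        "planted_restored_metabolites": len(met_truth.restored),
        "planted_rho": omics_truth.rho.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    log.info("simulate: %d genes, %d shared, %d wired, %d PPI edges",
             len(universe), len(shared), len(wired_genes), len(edges))
    return truth


def network_stage(config: RunConfig, outdir: Path) -> net_mod.DiseaseNetwork:
    """Intersect universes, build the disease network, and rank nodes."""
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    sample_sheet = pd.read_csv(outdir / "samples.tsv", sep="\t")
    reference = net_mod.ReferenceGeneSet(
        tuple((outdir / "reference_genes.txt").read_text().split()), source="synthetic reference")
    edges = pd.read_csv(outdir / "ppi_edges.tsv", sep="\t")

    shared = net_mod.intersect_universe(expression.index, reference)
    log.info("network: %d transcriptome genes ∩ %d reference genes -> %d shared",
             len(expression), len(reference), len(shared))
    try:
        network = net_mod.build_network(shared, edges, min_confidence=config.min_confidence)
    except net_mod.NetworkBuildError as exc:
        raise PipelineError(f"build-network: {exc}") from exc

    fc = eor_mod.compute_fold_changes(
        expression.loc[network.nodes], sample_sheet, sham=config.sham, model=config.model,
        arms=list(config.all_arms), pseudo_count=config.pseudo_count)
    net_mod.ntra_rank(network, np.log2(fc["disease"]))
    log.info("network: %d nodes, %d edges after min_confidence=%.2f (dropped %d isolated genes)",
             network.n_nodes, network.n_edges, config.min_confidence,
             len(shared) - network.n_nodes)
    network.to_graphml(outdir / "network.graphml")
    network.to_edge_tsv(outdir / "network_edges.tsv")
    network.node_table().to_csv(outdir / "network_nodes.tsv", sep="\t")
    (outdir / "shared_genes.txt").write_text("\n".join(shared) + "\n")
    return network


def eor_stage(config: RunConfig, outdir: Path) -> dict:
    """Score EoR over the network genes; compute recovery rates and gene selections."""
    expression = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    sample_sheet = pd.read_csv(outdir / "samples.tsv", sep="\t")
    nodes = pd.read_csv(outdir / "network_nodes.tsv", sep="\t")["gene"].tolist()

    fc = eor_mod.compute_fold_changes(
        expression.loc[nodes], sample_sheet, sham=config.sham, model=config.model,
        arms=list(config.all_arms), pseudo_count=config.pseudo_count)
    etab = eor_mod.eor_table(fc)
    etab.to_csv(outdir / "eor_table.tsv", sep="\t")

    rates = {arm: eor_mod.recovery_rate(etab, arm, threshold=config.eor_threshold)._asdict()
             for arm in config.all_arms}
    specific = eor_mod.select_specific(etab, config.combo, list(config.arms),
                                       threshold=config.eor_threshold)
    differential = eor_mod.select_differential(etab, config.combo, list(config.arms),
                                               delta=config.delta, delta_scale=config.delta_scale,
                                               mode=config.mono_mode)
    union = eor_mod.select_union(specific, differential)
    for name, ids in (("specific", specific), ("differential", differential), ("union", union)):
        (outdir / f"genes_{name}.txt").write_text("\n".join(sorted(ids)) + "\n")
    for arm, r in rates.items():
        log.info("eor: %s recovered %d / %d genes (%.2f%%)", arm, r["count"], r["total"],
                 r["percent"])
    log.info("eor: specific %d, differential %d, union %d genes",
             len(specific), len(differential), len(union))
    return {"recovery": rates,
            "selections": {"specific": len(specific), "differential": len(differential),
                           "union": len(union),
                           "overlap": len(specific & differential)}}


def synergy_stage(config: RunConfig, outdir: Path) -> dict:
    readouts = pd.read_csv(outdir / "assay_readouts.tsv", sep="\t")
    try:
        result = syn_mod.analyze_synergy(
            readouts, arms=config.arms, combo=config.combo,
            additive_tol=config.additive_tol, n_boot=config.n_boot, seed=config.seed)
    except ValueError as exc:
        raise PipelineError(f"synergy: {exc}") from exc
    (outdir / "synergy.json").write_text(json.dumps(result.to_dict(), indent=2))
    log.info("synergy: CI = %.4f (%s), E_expected = %.4f", result.ci, result.classification,
             result.e_expected)
    return result.to_dict()


def metabolites_stage(config: RunConfig, outdir: Path) -> dict:
    table = pd.read_csv(outdir / "metabolite_abundance.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(outdir / "metabolite_samples.tsv", sep="\t")
    scores = pd.read_csv(outdir / "metabolite_scores.tsv", sep="\t", index_col=0)["score"]

    gates = dict(p_thresh=config.p_thresh, lfc_thresh=config.lfc_thresh,
                 score_thresh=config.score_thresh)
    diff_disease = met_mod.differential_screen(table, samples, config.model, config.sham,
                                               scores=scores, **gates)
    diff_treatment = met_mod.differential_screen(table, samples, config.combo, config.model,
                                                 scores=scores, **gates)
    restored = met_mod.restored_features(diff_disease, diff_treatment,
                                         require_significance=config.restored_require_significance,
                                         mode=config.restored_mode)
    diff_disease.to_csv(outdir / "screen_disease.tsv", sep="\t")
    diff_treatment.to_csv(outdir / "screen_treatment.tsv", sep="\t")
    (outdir / "metabolites_restored.txt").write_text("\n".join(sorted(restored)) + "\n")

    taxa = pd.read_csv(outdir / "taxon_abundance.tsv", sep="\t", index_col=0)
    omics_mets = pd.read_csv(outdir / "omics_metabolites.tsv", sep="\t", index_col=0)
    assoc = met_mod.spearman_matrix(taxa, omics_mets, adjust=config.adjust_method)
    assoc.rho.to_csv(outdir / "association_rho.tsv", sep="\t")
    assoc.to_long().to_csv(outdir / "association_long.tsv", sep="\t", index=False)

    log.info("metabolites: %d/%d pass disease screen, %d/%d pass treatment screen, %d restored",
             int(diff_disease["pass"].sum()), len(diff_disease),
             int(diff_treatment["pass"].sum()), len(diff_treatment), len(restored))
    strongest = assoc.rho.abs().stack().idxmax()
    return {"n_features": len(table),
            "n_pass_disease": int(diff_disease["pass"].sum()),
            "n_pass_treatment": int(diff_treatment["pass"].sum()),
            "n_restored": len(restored),
            "association": {"n_taxa": len(taxa), "n_metabolites": len(omics_mets),
                            "strongest_pair": list(strongest),
                            "strongest_rho": float(assoc.rho.loc[strongest])}}


@dataclass
class RunSummary:
    """Machine-readable result of a full run; serialized to summary.json."""

    seed: int
    version: str
    config_hash: str
    n_universe_genes: int
    n_shared_genes: int
    n_network_nodes: int
    n_network_edges: int
    recovery: dict
    selections: dict
    synergy: dict
    metabolites: dict

    def to_dict(self) -> dict:
        return asdict(self)


def run_all(config: RunConfig, outdir) -> RunSummary:
    """Execute every stage in dependency order and write summary.json.

    Raises :class:`PipelineError` before any computation if the
    configuration does not validate, and aborts on the first failing stage
    with the stage name in the message.
    """
    errors = validate_config(config)
    if errors:
        raise PipelineError("invalid configuration: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.resolved_yaml())

    def _run(name, fn):
        try:
            return fn(config, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"{name}: {exc}") from exc

    _run("simulate", simulate_stage)
    network = _run("build-network", network_stage)
    eor_out = _run("score-eor", eor_stage)
    synergy_out = _run("synergy", synergy_stage)
    met_out = _run("metabolites", metabolites_stage)

    try:
        pkg_version = _pkg_version("recovnet")
    except Exception:
        pkg_version = "unknown"
    summary = RunSummary(
        seed=config.seed, version=pkg_version, config_hash=config.config_hash(),
        n_universe_genes=config.n_universe,
        n_shared_genes=len((outdir / "shared_genes.txt").read_text().split()),
        n_network_nodes=network.n_nodes, n_network_edges=network.n_edges,
        recovery=eor_out["recovery"], selections=eor_out["selections"],
        synergy=synergy_out, metabolites=met_out)
    (outdir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    return summary
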