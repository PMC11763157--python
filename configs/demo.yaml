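# Bundled demo study: a planted five-group design whose ground truth mirrors
# the published analysis it emulates (gene universe 32,545; disease reference
# 1641 with 1539 shared; 1447-node disease network; per-arm recovery counts
# 902 / 804 / 437; selection sets 250 / 492 / 537; 70 restored metabolites;
# assay effects 0.3 / 0.4 / 0.8 giving a Bliss CI of 0.725).
# These values are also the RunConfig defaults; the file exists so that the
# study conditions are visible and editable in one place.

seed: 0

sham: sham
model: model
arms: [CF, BBP]
combo: CF+BBP
n_replicates: 3
noise_cv: 0.0            # planted fixture: group means realise fold changes exactly

n_universe: 32545
n_reference: 1641
n_shared: 1539
mean_degree: 62.03       # 2 * 44879 / 1447
min_confidence: 0.0      # synthetic confidences are uniform [0,1]; the planted
                         # wiring (not the threshold) defines the 1447-node network

pseudo_count: 0.0
eor_threshold: 0.0
delta: 0.2
delta_scale: fraction    # 0.2 on the fraction scale = 20 EoR percentage points
mono_mode: all

assay_effects: {CF: 0.3, BBP: 0.4, CF+BBP: 0.8}
assay_replicates: 3
assay_noise_sd: 0.02
additive_tol: 0.05
n_boot: 0

n_restored: 70
n_disease_only: 40
n_null: 90
met_samples_per_group: 6
met_lfc: 1.5
met_noise_sigma: 0.2
p_thresh: 0.05
lfc_thresh: 0.2
score_thresh: 38.1
restored_mode: opposite_sign
restored_require_significance: true

omics_samples: 30
adjust_method: fdr_bh
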