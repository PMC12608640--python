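"""Score UDR panels and search for the optimal marker combination.

The UDR (up-down ratio) of a sample is the mean linear expression of a
panel's up-regulated members divided by that of its down-regulated
members.  Starting from the markers validated in example 03, this script
enumerates every up/down subset combination, evaluates each panel's ROC
AUC on the early-stage-vs-benign contrast, and ranks the parsimonious
near-best panels (within 0.02 AUC of the maximum, smallest first).
"""

from udrpanel import (
    PanelAssignment,
    RunConfig,
    assign_directions,
    delta_ct_to_linear,
    enumerate_panels,
    evaluate_panel,
    gen_qpcr_cohort,
    normalize_delta_ct,
    optimize_panels,
    udr_score,
    validate_candidates,
    validation_study_design,
)

config = RunConfig(seed=7, n_boot=500)
design = validation_study_design(seed=7)
ct, meta = gen_qpcr_cohort(design)
delta_ct = normalize_delta_ct(ct, config.spike_in_id)
table, validated = validate_candidates(
    delta_ct, meta, delta_ct.feature_ids, config.stage_grouping["early"], config
)

up, down = assign_directions(table.set_index("feature_id").loc[validated].reset_index())
print(f"validated markers: up={sorted(up)}, down={sorted(down)}")
print(f"panel space: {len(enumerate_panels(up, down))} combinations "
      f"= (2^{len(up)}-1) x (2^{len(down)}-1)")

expr = delta_ct_to_linear(delta_ct)  # UDR needs strictly positive values
sample = meta[0].sample_id
full_panel = PanelAssignment(up, down)
print(f"\nUDR of sample {sample} on the full panel: "
      f"{udr_score(expr, full_panel, sample):.3g} "
      "(mean up-member expression / mean down-member expression)")

evaluations, optimal = optimize_panels(
    expr, meta, up, down, config, config.stage_grouping["early"], "validation"
)
full_auc = evaluate_panel(expr, meta, full_panel, config.stage_grouping["early"]).auc
print(f"\nfull {full_panel.size}-marker panel AUC: {full_auc:.3f}")
print(f"parsimonious near-best panels (within {config.parsimony_epsilon} AUC of best):")
for e in optimal[:5]:
    print(f"  {e.panel.size}-marker  AUC {e.auc:.3f} "
          f"[{e.roc.ci_low:.3f}-{e.roc.ci_high:.3f}]  {e.panel.label()}")
# Smaller panels with near-best AUC rank first: a compact panel is cheaper
# to assay and less prone to overfitting than the full marker set.
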