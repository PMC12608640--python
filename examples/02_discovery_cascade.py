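"""Run the discovery cascade on a synthetic NGS cohort.

Prevalence filtering (zero fraction > 0.50, then > 0.45), CPM
normalization, dual differential testing of early-stage NSCLC vs benign
(exact conditional negative-binomial test on counts; rank-sum test on
log-CPM), intersection of the hit lists, the stage-consistency
exclusion, and literature injection.  Prints the feature counts after
every step -- the audit trail of the candidate-selection funnel.
"""

import logging

from udrpanel import (
    RunConfig,
    discovery_de,
    discovery_study_design,
    gen_ngs_cohort,
    hit_sets,
    prevalence_filter,
    select_candidates,
    stagewise_pvalues,
)

logging.basicConfig(level=logging.INFO, format="%(message)s")

config = RunConfig(seed=7)
counts, meta = gen_ngs_cohort(discovery_study_design(seed=7, n_features=2656))
print(f"input: {counts.n_features} features x {counts.n_samples} samples")

stage1 = prevalence_filter(counts, config.prevalence_stage1)
stage2 = prevalence_filter(stage1, config.prevalence_stage2)
print(f"prevalence cascade: {counts.n_features} -> {stage1.n_features} -> {stage2.n_features}")

table_nb, table_mw = discovery_de(stage2, meta, config.stage_grouping["early"], config)
nb_hits, mw_hits = hit_sets(table_nb, table_mw, config)
print(f"exact-NB hits (|log2 FC| > {config.edge_fc_min}, p < {config.edge_p_max}): {len(nb_hits)}")
print(f"rank-sum hits (p < {config.mw_p_max}): {len(mw_hits)}")
print(f"common to both tests: {len(nb_hits & mw_hits)}")

stagewise = stagewise_pvalues(stage2, meta, config)
candidates = select_candidates(
    nb_hits, mw_hits, stagewise, config.literature, config, universe=stage2.feature_ids
)
print(f"\ncandidates ({len(candidates.members)} = common - stage-inconsistent + literature):")
for member in candidates.members:
    print(f"  {member:24s} [{candidates.provenance[member]}]")
for feature, reason in candidates.excluded.items():
    print(f"  excluded {feature}: {reason}")
# The candidate list feeds the qPCR validation stage (example 03).
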