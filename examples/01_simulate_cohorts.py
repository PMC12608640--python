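"""Generate the two synthetic serum cohorts the pipeline consumes.

Builds (a) a qPCR validation cohort (35 benign / 10 per NSCLC stage, the
15 candidate markers planted at their published fold changes) and (b) an
NGS discovery cohort (16 benign / 60 NSCLC, 2656 features with tiered
zero inflation), and prints the structural properties that matter
downstream: cohort sizes, spike-in row, and the zero-count sparsity the
prevalence filters will act on.
"""

from udrpanel import (
    discovery_study_design,
    gen_ngs_cohort,
    gen_qpcr_cohort,
    validation_study_design,
)

qpcr_design = validation_study_design(seed=7)
ct, qpcr_meta = gen_qpcr_cohort(qpcr_design)
print(f"qPCR cohort: {ct.n_features} rows (incl. spike-in) x {ct.n_samples} samples")
print(f"  spike-in {qpcr_design.spike_in_id!r} constant at Ct "
      f"{ct.data.loc[qpcr_design.spike_in_id].iloc[0]:.1f}")
print(f"  benign: {sum(r.group == 'benign' for r in qpcr_meta)}, "
      f"NSCLC: {sum(r.group == 'nsclc' for r in qpcr_meta)}")

ngs_design = discovery_study_design(seed=7)
counts, ngs_meta = gen_ngs_cohort(ngs_design)
zero_frac = (counts.data == 0).mean(axis=1)
print(f"\nNGS cohort: {counts.n_features} features x {counts.n_samples} samples")
print(f"  library sizes {counts.data.sum(axis=0).min():.0f}..{counts.data.sum(axis=0).max():.0f} reads")
print(f"  features with zero-count fraction > 0.50: {(zero_frac > 0.50).sum()} "
      "(these fall to the first prevalence filter)")
print(f"  features with zero-count fraction > 0.45: {(zero_frac > 0.45).sum()}")
# Both generators are deterministic given the design seed, so every run of
# this script prints exactly the same numbers.
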