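"""Promoter-window p53 target analysis with a shuffled background.

Simulates a paired vehicle/treated expression cohort in which a designated
target-gene set carries a +0.5 log2 fold-change shift, places ChIP-seq-like
peaks in the 5,000 bp upstream windows of those targets, and compares the
log2 fold-change distribution of recovered targets against an equal-size
random background with a two-sample KS test.
"""

import numpy as np

from neurotoxiscore import genomics as gn
from neurotoxiscore import synthetic as syn

sim = syn.make_expression_dataset(
    syn.ExpressionSimSpec(seed=5, delta_log2fc=0.5))
peaks, _ = syn.make_peaks(syn.PeakSimSpec(seed=5), sim.annotation,
                          sim.target_genes)
print(f"{sim.table.counts.shape[0]} genes, "
      f"{sim.table.counts.shape[1]} samples, {len(peaks)} peaks")

results = gn.target_vs_background_analysis(
    sim.table, sim.annotation, peaks, seed=17)
for group, res in results.items():
    shift = res.target_log2fc.median() - res.background_log2fc.median()
    print(f"{group}: n={res.ks.n_target} targets | KS D={res.ks.statistic:.3f}"
          f" p={res.ks.p_value:.2e} | median log2FC shift {shift:+.3f}")
# Targets are recovered from the peak/window intersection restricted to the
# expressed-gene universe (mean RPKM > 0.5); the right-shifted target ECDF
# yields a highly significant KS statistic in both groups.
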