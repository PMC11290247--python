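"""Sperm-competition statistics: P2 estimates with exact CIs, Fisher's exact
test between genotypes, and the competition-gradient expression summary."""

import numpy as np
import pandas as pd

import orphanforge as of

# offense assay: focal males mate second; P2 = het offspring fraction
gt, _ = of.synth_mating_and_qpcr(true_p2=0.25, n_offspring=300, seed=8,
                                 assay="offense")
counts = [of.GenotypeCounts(int(r.n_het), int(r.n_wt), r.assay)
          for r in gt.df.itertuples()]
pooled = of.p2_pooled(counts)
print(f"P2 (offense, pooled over {len(counts)} females): "
      f"{pooled.value:.3f}  95% CI [{pooled.ci_low:.3f}, {pooled.ci_high:.3f}]")

# is paternity distribution different between two male genotypes?
fisher = of.fisher_exact_2x2([[sum(c.n_het for c in counts),
                               sum(c.n_wt for c in counts)], [150, 150]])
print(f"Fisher's exact vs a 50:50 rival: p = {fisher['p']:.2e}")

print(f"retention ratio 200 -> 73 bundles: "
      f"{of.retention_ratio(200, 73).ratio:.3f}")

# expression response to competition intensity (none / low / high males)
rng = np.random.default_rng(9)
rows = [{"competition": c, "time": t, "value": v}
        for t in ("12h", "24h", "36h")
        for c, mu in (("none", 1.0), ("low", 2.1), ("high", 0.7))
        for v in rng.normal(mu, 0.15, 4)]
summary = of.competition_gradient_summary(pd.DataFrame(rows))
print("\ncompetition gradient (pairwise Student's t):")
print(summary.round(4).to_string(index=False))
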