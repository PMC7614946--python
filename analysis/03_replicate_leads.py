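"""Replicate credible-set leads in the independent cohort.

A lead replicates when the refitted joint model gives a directionally
concordant effect that passes the Bonferroni threshold (alpha divided by
the number of retained leads in this study).
"""

import pandas as pd

from _common import RESULTS, ensure_study

study = ensure_study()

rep = pd.read_csv(study / "replication.tsv", sep="\t")
rep.to_csv(RESULTS / "replication.tsv", sep="\t", index=False)

print("Replication of retained credible-set leads:")
if len(rep):
    n_rep = int(rep["replicated"].sum())
    print(f"  {n_rep} of {len(rep)} leads replicated "
          f"(concordant direction AND Bonferroni-significant)")
    r = rep[["beta_disc", "beta_rep"]].corr().iloc[0, 1]
    print(f"  discovery-replication effect correlation r = {r:.3f}")
    for row in rep.itertuples(index=False):
        print(f"    {row.protein} lead {row.lead_index}: beta_disc {row.beta_disc:+.3f}, "
              f"beta_rep {row.beta_rep:+.3f}, p_rep {row.p_rep:.2e} -> "
              f"{'replicated' if row.replicated else 'not replicated'}")
else:
    print("  no leads to test")
print(f"\nWrote {RESULTS / 'replication.tsv'}")
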