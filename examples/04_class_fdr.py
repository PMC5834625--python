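"""Class-specific FDR from separate target and decoy score lists.

Simulates a PSM score mixture with a known fraction of incorrect targets,
estimates FDR by decoy counting and compares against the ground truth.
"""

import numpy as np

from ipaw.fdr_engine import class_fdr
from ipaw.synthetic_fixtures import make_score_mixture

df = make_score_mixture(n_correct=4500, n_incorrect=500, n_decoy=500, seed=0)
targets = df[~df.is_decoy][["psm_id", "peptide", "score"]]
decoys = df[df.is_decoy][["psm_id", "peptide", "score"]]
result = class_fdr(
    list(targets.itertuples(index=False)), list(decoys.itertuples(index=False))
)

n_at_1pct = result.n_accepted(0.01)
print(f"{n_at_1pct} target peptides at 1% class-specific FDR")

table = result.table.merge(df[["psm_id", "truth"]], on="psm_id")
accepted = table[(~table.is_decoy) & (table.q_value <= 0.01)]
true_fdp = (accepted.truth == "incorrect").mean()
print(f"true false-discovery proportion among them: {true_fdp:.3f}")
# The decoy-based estimate controls the truth because incorrect targets and
# decoys draw from the same null score distribution.
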