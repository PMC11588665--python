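"""Call malignant cells and clones from inferred copy-number profiles.

Expression is smoothed in 101-gene windows along the genome, centered on a
benign reference, and each cell is scored by its mean squared deviation.
Cells above the reference mean + 3 s.d. are malignant; their CNV profiles
are clustered into clones.  Each clone should map to one donor and carry
that donor's dominant TCR clonotype.
"""

import pandas as pd

from skintx import CohortConfig, call_malignant, dominant_clonotype, order_genes, simulate_cohort, smooth_windows

adata, truth = simulate_cohort(CohortConfig(seed=0))
reference = list(truth.cells.index[~truth.cells["malignant"]])

cnv = smooth_windows(adata, order_genes(adata.var), reference)
call = call_malignant(cnv)
pred = call.calls["label"] == "malignant"
actual = truth.cells["malignant"].reindex(call.calls.index)
tp = int((pred & actual).sum())
print(f"malignancy threshold (score units): {call.threshold:.4f}")
print(f"called {int(pred.sum())} malignant of {int(actual.sum())} planted "
      f"(precision {tp / pred.sum():.3f}, recall {tp / actual.sum():.3f})")

print("clones vs donors (rows = called clone, cols = planted clone):")
print(pd.crosstab(call.calls.loc[pred, "clone"],
                  truth.cells.loc[call.calls.index[pred], "clone_id"]))

# each called clone is dominated by a single TCR clonotype
for clone, grp in call.calls[pred].groupby("clone"):
    res = dominant_clonotype(adata.obs.loc[grp.index, "clonotype"])
    print(f"{clone}: dominant clonotype {res.clonotype} "
          f"({res.fraction:.1%} of clonotyped cells)")
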