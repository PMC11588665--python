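"""Extract intratumor expression programs and cluster them into metaprograms.

Per tumor: log-normalize malignant cells, pick highly variable genes, scale
with the mitochondrial fraction regressed out, zero the negatives and run
NMF at rank 10.  Each factor's top-30 genes define a program (programs with
score s.d. <= 0.1 are discarded).  Programs from all tumors are clustered
on pairwise Jaccard similarity; clusters spanning >= 2 tumors are
metaprograms.  The generator plants one 30-gene activity program shared by
every donor, which should come back as a metaprogram.
"""

from skintx import CohortConfig, intratumor_programs, metaprogram_cluster, simulate_cohort

adata, truth = simulate_cohort(CohortConfig(seed=0))
planted = set(truth.programs[0]["genes"])

programs = []
for donor in adata.obs["donor"].unique():
    mal = truth.cells.index[truth.cells["malignant"] & (adata.obs["donor"] == donor)]
    sub = adata[mal]
    progs = intratumor_programs(sub, sub.obs["mito_frac"].to_numpy(), donor)
    programs.extend(progs)
    print(f"{donor}: {len(progs)} programs pass the s.d. > 0.1 filter")

metas = metaprogram_cluster(programs, j_min=0.25)
print(f"\n{len(programs)} programs -> {len(metas)} metaprogram(s)")
for i, m in enumerate(metas, 1):
    top = set(m.consensus.index[:30])
    overlap = len(top & planted) / len(planted)
    print(f"metaprogram {i}: {m.n_members} programs from {len(m.tumors)} tumors, "
          f"planted-gene overlap {overlap:.0%}")
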