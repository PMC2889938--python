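"""Reconstruct TF activities from a time-series expression matrix by NCA.

Builds a synthetic 54-gene / 3-TF / 3-dose instance with known ground
truth, fits the support-constrained decomposition E = S A, and reports
the reconstruction residual, the recovered NF-κB activity peak per dose,
and the strongest NF-κB target genes.
"""

import numpy as np

from nfkblink import fit_nca, gene_tf_correlation, influence_ranking
from nfkblink.synthetic import SyntheticSpec, gen_nca_instance

spec = SyntheticSpec(seed=0, noise_sigma=0.1)  # 54 genes, 77 edges, 3 doses
expr, net, S_true, A_true = gen_nca_instance(spec)
print(f"expression matrix: {expr.n_genes} genes x {expr.n_columns} columns "
      f"({len(expr.conditions)} doses x {len(spec.grid)} times)")

res = fit_nca(expr, net, seed=0)
print(f"relative reconstruction error ||E - SA||/||E|| = {res.residual:.4f} "
      f"({res.n_iter} iterations)")
# the residual reflects the injected measurement noise, not model misfit

a = res.activity("NFKB")
for cond in expr.conditions:
    seg = a[expr.condition_slice(cond)]
    t = expr.grids[cond].times
    print(f"  {cond}: NF-kB activity peaks at {t[int(np.argmax(seg))]:g} h, "
          f"relative amplitude {seg.max():.2f}")
# activities are normalized to a global maximum of 1; per-dose amplitudes
# keep their relative scale, mirroring a dose-dependent activation strength

print("top 5 influence strengths (|s_ik|, NF-kB regulon):")
corr = gene_tf_correlation(expr, res, "NFKB")
for gene, s in influence_ranking(res, "NFKB", top_n=5):
    print(f"  {gene}: strength {s:+.2f}, expression-activity r = "
          f"{corr[gene]:+.2f}")
# strongly coupled genes track the TF activity closely (high |r|)
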