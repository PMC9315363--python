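"""Population structure: standardized GRM, PCA, VanRaden kinship, Rogers
distance and a neighbor-joining tree.

Run examples/01_simulate_panel.py first.
"""

import numpy as np

from eigensel import (
    neighbor_joining,
    pca,
    qc_filter,
    read_vcf,
    rogers_distance,
    standardized_grm,
    vanraden_kinship,
)

matrix, _ = qc_filter(read_vcf("scratch/example_panel/panel.vcf",
                               "scratch/example_panel/panel.meta.tsv"))

grm = standardized_grm(matrix)
res = pca(grm, k=10)
print("variance explained by EV1/EV2: "
      f"{100 * res.variance_explained[0]:.2f}% / {100 * res.variance_explained[1]:.2f}%")
print("weak structure: the leading eigenvector captures only a few percent, "
      "as in diverse breeding panels")

kin = vanraden_kinship(matrix)
off = kin.values[~np.eye(matrix.n_samples, dtype=bool)]
print(f"kinship off-diagonals: {100 * (off == 0).mean():.0f}% clamped at zero, "
      f"max {off.max():.2f}")

rog = rogers_distance(matrix)
print(f"Rogers distance: mean {rog.off_diagonal().mean():.3f}, "
      f"range {rog.off_diagonal().min():.3f}-{rog.off_diagonal().max():.3f}")

tree = neighbor_joining(rog)
newick = tree.to_newick()
print(f"NJ tree over {len(tree.leaves())} accessions "
      f"({len(newick)} characters of Newick)")
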