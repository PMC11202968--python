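"""Screen a synthetic two-cohort study: MAF, Fst, LD blocks, Tajima's D.

Generates a cohort with the default two-block haplotype structure, computes
per-SNP divergence between ancestry groups, detects LD blocks among the
divergent SNPs, and shows the neutrality statistic on stylized haplotype
samples.
"""

import numpy as np

from haplobiva import (
    CohortSpec, compute_fst, compute_maf, detect_blocks, generate_study,
    tajimas_d,
)
from haplobiva.genomics_io import GenotypeMatrix
from haplobiva.synthetic_data import generate_neutral_region

study = generate_study(CohortSpec(seed=7))
matrix = study.matrix
groups = study.subjects.set_index("id")["ancestry"].reindex(matrix.samples).to_numpy()

print("rsID          MAF    Fst(WC)")
divergent = []
for j, v in enumerate(matrix.variants):
    d = matrix.dosages[:, j]
    fst = compute_fst(d, groups)
    print(f"{v.id:<12}  {compute_maf(d):.3f}  {fst.fst: .3f}  ({fst.classify()})")
    if fst.fst > 0.15:
        divergent.append(j)

sub = GenotypeMatrix(
    [matrix.variants[j] for j in divergent], matrix.samples,
    matrix.dosages[:, divergent],
)
print("\nLD blocks among divergent SNPs (D' and r2 > 0.75):")
for block in detect_blocks(sub):
    ids = ",".join(v.id for v in block.variants)
    print(f"  {block.interval.chrom}:{block.interval.start}-{block.interval.end}"
          f"  {block.n_snps} SNPs: {ids}")

balanced = generate_neutral_region(40, 20, "balanced_two_class", seed=7)
star = generate_neutral_region(10, 15, "singleton_excess", seed=7)
print(f"\nTajima's D, two balanced haplotype classes: {tajimas_d(balanced).d:+.2f}")
print(f"Tajima's D, all-singleton sample:           {tajimas_d(star).d:+.2f}")
print("\nStrongly positive D marks an excess of intermediate-frequency variants")
print("(balancing selection or contraction); negative D an excess of rare ones.")
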