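"""Call diplotypes from unphased genotypes under the same-phase assumption.

Each subject's genotypes at a block's tag SNPs are matched against the
unordered pairs of defined haplotypes; with the shipped TRPV1 H1 (a/b/c) and
H2 (a/b) definitions every full genotype resolves uniquely.
"""

from collections import Counter

from haplobiva import CohortSpec, call_diplotypes, generate_study, group_diplotypes
from haplobiva.haplotyping import load_block_definitions

study = generate_study(CohortSpec(seed=5))
blocks = load_block_definitions()

for name, block in blocks.items():
    calls = call_diplotypes(study.allele_table, block)
    counts = Counter(c.label for c in calls)
    print(f"block {name} ({', '.join(block.snp_ids)})")
    print(f"  diplotype counts: {dict(sorted(counts.items()))}")
    resolved = [c for c in calls if c.resolved]
    carrier = Counter(group_diplotypes(resolved, "carrier_vs_aa").values())
    print(f"  aa vs b-carrier:  {dict(sorted(carrier.items()))}")

truth = study.truth.set_index("subject_id")
calls = call_diplotypes(study.allele_table, blocks["H2"])
agree = sum(c.label == truth.loc[c.subject_id, "H2_pair"] for c in calls)
print(f"\nH2 calls matching the generator's ground truth: {agree}/{len(calls)}")
print("With zero genotyping error the same-phase call is exact by construction.")
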