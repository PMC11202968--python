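"""Synthetic two-cohort studies with known ground truth.

The generator emulates the data structure of a two-population candidate-gene
study of the TRPV1 haplotype blocks: an African-ancestry cohort in which the
non-reference block haplotypes segregate at intermediate frequency and a
European-ancestry cohort in which they are essentially absent; sex- and
ancestry-structured bivariate (Rsp, Xcsp) bioimpedance distributions; an
optional female-restricted additive effect of non-reference haplotype copies
on the bioelectrical vector; and ordinal capsaicin-threshold / PROP-intensity
phenotypes. Raw (R, Xc) readings are produced by inverting the specific
standardization from the sampled (Rsp, Xcsp) and sampled anthropometry, so a
synthetic study is indistinguishable from real input at the file interface.

Defaults encode the study conditions: cohort sizes 34/12 African and 20/25
Italian males/females, block-haplotype frequencies ~0.43 (H1-b) and ~0.44
(H2-b) in the African-like group and 0 in the European-like group, and
female b-carriers shifted toward a longer vector (higher Zsp) with a smaller
phase angle. Effect magnitudes are configuration, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics_io import GenotypeMatrix, VariantInfo, write_genotypes
from .haplotyping import HaplotypeBlock, load_block_definitions

__all__ = [
    "CohortSpec", "SyntheticStudy", "generate_study", "generate_neutral_region",
    "write_study", "DEFAULT_GROUP_BIVA", "NONBLOCK_SNPS",
]


class SyntheticDataError(Exception):
    pass


# Non-block SNPs of the two amplicons: (rsid, chrom, pos, ref, alt,
# alt-frequency by ancestry). Frequencies are the observed cohort values.
NONBLOCK_SNPS = (
    ("rs73303327", "17", 3596528, "G", "A", {"SSA": 0.378, "ITA": 0.033}),
    ("rs161383", "17", 3596724, "A", "G", {"SSA": 0.044, "ITA": 0.189}),
    ("rs114890125", "17", 3596764, "C", "T", {"SSA": 0.043, "ITA": 0.000}),
    ("rs877610", "17", 3572196, "C", "T", {"SSA": 0.122, "ITA": 0.011}),
    ("rs877611", "17", 3572271, "T", "C", {"SSA": 0.122, "ITA": 0.322}),
    ("rs877612", "17", 3572292, "C", "T", {"SSA": 0.122, "ITA": 0.011}),
)

# GRCh38 reference alleles at the block tag SNPs are the *b*-state alleles
# (the European-fixed allele is the alternate), so VCF dosage counts a-copies.
BLOCK_SNP_REF_ALT = {
    "rs10491215": ("C", "G"), "rs73303323": ("C", "T"), "rs73303325": ("T", "C"),
    "rs7211511": ("T", "C"), "rs7211517": ("G", "C"),
    "rs224548": ("T", "G"), "rs224549": ("C", "T"), "rs224550": ("C", "T"),
}

# Baseline bivariate (Rsp, Xcsp) means/SDs (ohm*cm) and correlation by
# (ancestry, sex); these are aa-diplotype baselines, the female effect shifts
# b-carriers on top. Female values are anchored to the printed cohort
# summaries (vector length ~407 vs ~502 ohm*cm, phase angle ~5.7 vs ~6.2
# degrees); male values are unprinted and set to plausible shorter-vector,
# larger-angle BIVA positions.
DEFAULT_GROUP_BIVA = {
    ("ITA", "F"): ((405.0, 40.2), (70.0, 8.0), 0.65),
    ("SSA", "F"): ((455.0, 51.0), (95.0, 11.0), 0.65),
    ("ITA", "M"): ((350.0, 42.0), (55.0, 8.0), 0.65),
    ("SSA", "M"): ((365.0, 45.0), (60.0, 9.0), 0.65),
}

# Anthropometry: sex-specific normal (mean, sd); exercises the A/L pipeline,
# no claim of anthropometric realism beyond plausible adult ranges.
_ANTHRO = {
    "M": {"height_cm": (176.0, 7.0), "weight_kg": (76.0, 10.0),
          "arm_circ_cm": (31.0, 3.0), "waist_circ_cm": (88.0, 9.0),
          "calf_circ_cm": (37.0, 2.5)},
    "F": {"height_cm": (162.0, 6.0), "weight_kg": (62.0, 9.0),
          "arm_circ_cm": (28.0, 2.5), "waist_circ_cm": (78.0, 9.0),
          "calf_circ_cm": (35.0, 2.5)},
}

_AGE = {("SSA", "M"): (33.0, 12.0), ("SSA", "F"): (29.0, 9.0),
        ("ITA", "M"): (26.0, 6.0), ("ITA", "F"): (26.0, 3.0)}

# Capsaicin threshold distribution over swabs 1..10: frequency drops after
# swab 5 and is zero from swab 9 on.
_THRESHOLD_PROBS = (0.14, 0.20, 0.17, 0.15, 0.14, 0.09, 0.06, 0.05, 0.0, 0.0)


def _default_counts() -> dict:
    return {("SSA", "M"): 34, ("SSA", "F"): 12, ("ITA", "M"): 20, ("ITA", "F"): 25}


def _default_freqs() -> dict:
    return {
        "H1": {"SSA": {"a": 0.545, "b": 0.433, "c": 0.022}, "ITA": {"a": 1.0}},
        "H2": {"SSA": {"a": 0.556, "b": 0.444}, "ITA": {"a": 1.0}},
    }


def _default_effect() -> dict:
    # per-b-copy additive shift (delta_rsp, delta_xcsp) in females only;
    # lengthens the vector and reduces the phase angle
    return {"H2": (45.0, 3.0)}


@dataclass
class CohortSpec:
    """Full parameterization of one synthetic study."""

    n_per_group: dict = field(default_factory=_default_counts)
    haplotype_freqs: dict = field(default_factory=_default_freqs)
    group_biva: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_BIVA))
    female_effect: dict = field(default_factory=_default_effect)
    genotyping_error: float = 0.0
    nonblock_snps: tuple = NONBLOCK_SNPS
    threshold_probs: tuple = _THRESHOLD_PROBS
    prop_lms: tuple = (63.0, 18.0)
    capsaicin_lms: tuple = (40.0, 20.0)
    seed: int = 0

    def validate(self) -> None:
        for block, by_anc in self.haplotype_freqs.items():
            for anc, freqs in by_anc.items():
                total = sum(freqs.values())
                if any(f < 0 or f > 1 for f in freqs.values()) or total > 1 + 1e-9:
                    raise SyntheticDataError(
                        f"{block}/{anc}: haplotype frequencies invalid: {freqs}"
                    )
        if not 0 <= self.genotyping_error < 1:
            raise SyntheticDataError(
                f"genotyping_error must be in [0, 1), got {self.genotyping_error}"
            )
        for key, (_, sds, corr) in self.group_biva.items():
            if min(sds) <= 0 or not -1 < corr < 1:
                raise SyntheticDataError(f"group {key}: invalid biva parameters")
        if abs(sum(self.threshold_probs) - 1.0) > 1e-9:
            raise SyntheticDataError("threshold_probs must sum to 1")


@dataclass
class SyntheticStudy:
    """Generated study plus the ground truth needed to score every stage."""

    matrix: GenotypeMatrix
    allele_table: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def _draw_haplotype(rng, freqs: dict) -> str:
    labels = sorted(freqs)
    probs = np.array([freqs[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), p=probs)]


def _mvn(rng, mean, sds, corr) -> np.ndarray:
    cov = np.array(
        [[sds[0] ** 2, corr * sds[0] * sds[1]],
         [corr * sds[0] * sds[1], sds[1] ** 2]]
    )
    return rng.multivariate_normal(np.asarray(mean, float), cov)


def generate_study(spec: CohortSpec | None = None, blocks: dict | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study, deterministic under ``spec.seed``.

    Haplotype pairs are drawn independently per block from ancestry-specific
    frequencies; block-SNP alleles are emitted from the defined haplotype
    states with an optional per-allele flip error; non-block SNPs are drawn
    independently at their ancestry-specific frequencies. Raw (R, Xc) come
    from inverting the A/L standardization against sampled anthropometry.
    """
    from .biva import derive_geometry

    spec = spec or CohortSpec()
    spec.validate()
    blocks = blocks or load_block_definitions()
    rng = np.random.default_rng(spec.seed)

    subjects, truth_rows = [], []
    allele_rows: dict[str, dict] = {}
    idx = 0
    for (ancestry, sex), count in sorted(spec.n_per_group.items()):
        for _ in range(count):
            idx += 1
            sid = f"S{idx:04d}"
            pairs = {
                name: tuple(sorted(
                    _draw_haplotype(rng, spec.haplotype_freqs[name][ancestry])
                    for _ in range(2)
                ))
                for name in blocks
            }
            # genotypes at block tag SNPs from the haplotype states
            geno: dict[str, tuple] = {}
            for name, block in blocks.items():
                h1, h2 = (block.haplotypes[l] for l in pairs[name])
                for rs in block.snp_ids:
                    alleles = [h1.allele(rs), h2.allele(rs)]
                    if spec.genotyping_error > 0:
                        site_alleles = sorted(
                            {h.allele(rs) for h in block.haplotypes.values()}
                            | set(BLOCK_SNP_REF_ALT.get(rs, ()))
                        )
                        for k in range(2):
                            if rng.random() < spec.genotyping_error:
                                others = [a for a in site_alleles if a != alleles[k]]
                                alleles[k] = others[int(rng.integers(len(others)))]
                    geno[rs] = tuple(sorted(alleles))
            for rsid, _, _, ref, alt, freqs in spec.nonblock_snps:
                dose = rng.binomial(2, freqs[ancestry])
                geno[rsid] = tuple(sorted([alt] * dose + [ref] * (2 - dose)))
            allele_rows[sid] = geno

            # rounded at draw time so the written table reproduces A/L exactly
            anthro = {
                k: float(np.round(max(rng.normal(*v), 0.5 * v[0]), 1))
                for k, v in _ANTHRO[sex].items()
            }
            geom = derive_geometry(
                anthro["height_cm"], anthro["weight_kg"], anthro["arm_circ_cm"],
                anthro["waist_circ_cm"], anthro["calf_circ_cm"],
            )
            mean, sds, corr = spec.group_biva[(ancestry, sex)]
            rsp, xcsp = _mvn(rng, mean, sds, corr)
            if sex == "F":
                for block_name, (d_rsp, d_xcsp) in spec.female_effect.items():
                    copies = sum(1 for h in pairs[block_name] if h != "a")
                    rsp += copies * d_rsp
                    xcsp += copies * d_xcsp
            rsp, xcsp = max(rsp, 1.0), max(xcsp, 0.5)
            k = geom.correction
            threshold = 1 + int(
                rng.choice(len(spec.threshold_probs), p=spec.threshold_probs)
            )
            subjects.append({
                "id": sid, "sex": sex, "ancestry": ancestry,
                "age": float(np.round(max(rng.normal(*_AGE[(ancestry, sex)]), 18.0), 1)),
                **{k2: float(np.round(v, 1)) for k2, v in anthro.items()},
                "R_ohm": rsp / k, "Xc_ohm": xcsp / k,
                "capsaicin_threshold": threshold,
                "prop_score": float(np.clip(rng.normal(*spec.prop_lms), 0.0, 100.0)),
            })
            truth_rows.append({
                "subject_id": sid, "ancestry": ancestry, "sex": sex,
                **{f"{name}_pair": "".join(pairs[name]) for name in blocks},
                **{
                    f"{name}_b_copies": sum(1 for h in pairs[name] if h != "a")
                    for name in blocks
                },
                "true_rsp": rsp, "true_xcsp": xcsp,
            })

    sample_ids = [s["id"] for s in subjects]
    variants, columns, n_skipped = [], [], 0
    site_defs = [
        (rs, blocks[name].chrom, blocks[name].snp_positions[rs], *BLOCK_SNP_REF_ALT[rs])
        for name in blocks for rs in blocks[name].snp_ids
    ] + [(rsid, chrom, pos, ref, alt) for rsid, chrom, pos, ref, alt, _ in spec.nonblock_snps]
    for rsid, chrom, pos, ref, alt in site_defs:
        col = np.empty(len(sample_ids), dtype=np.int8)
        foreign = False
        for i, sid in enumerate(sample_ids):
            alleles = allele_rows[sid][rsid]
            if any(a not in (ref, alt) for a in alleles):
                foreign = True
                break
            col[i] = sum(a == alt for a in alleles)
        if foreign:  # e.g. the third (c-state) allele makes the site triallelic
            n_skipped += 1
            continue
        variants.append(VariantInfo(chrom, pos, rsid, ref, alt))
        columns.append(col)
    order = sorted(range(len(variants)), key=lambda j: (variants[j].chrom, variants[j].pos))
    matrix = GenotypeMatrix(
        [variants[j] for j in order], sample_ids,
        np.stack([columns[j] for j in order], axis=1),
        n_skipped_records=n_skipped,
    )

    all_rsids = [rs for rs, *_ in site_defs]
    allele_table = pd.DataFrame(
        {rs: [allele_rows[sid][rs] for sid in sample_ids] for rs in all_rsids},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticStudy(
        matrix=matrix, allele_table=allele_table,
        subjects=pd.DataFrame(subjects), truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study through the standard file interfaces (VCF, allele-pair
    TSV, subject CSV, truth CSV). Returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "tsv": os.path.join(outdir, "genotypes.tsv"),
        "subjects": os.path.join(outdir, "subjects.csv"),
        "truth": os.path.join(outdir, "truth.csv"),
    }
    write_genotypes(study.matrix, paths["vcf"], format="vcf")
    # allele-pair TSV covers ALL sites, including any triallelic one; the
    # metadata lines declare each site's biallelic ref/alt so the dosage
    # reader can skip sites carrying a third allele.
    blocks = load_block_definitions()
    site_meta = {
        rs: (block.chrom, block.snp_positions[rs], *BLOCK_SNP_REF_ALT[rs])
        for block in blocks.values() for rs in block.snp_ids
    }
    site_meta.update({
        rsid: (chrom, pos, ref, alt)
        for rsid, chrom, pos, ref, alt, _ in study.spec.nonblock_snps
    })
    with open(paths["tsv"], "w") as fh:
        for rs in study.allele_table.columns:
            chrom, pos, ref, alt = site_meta[rs]
            fh.write(
                f"## variant={rs} chrom={chrom} pos={pos} ref={ref} alt={alt}\n"
            )
        cols = list(study.allele_table.columns)
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for sid, row in study.allele_table.iterrows():
            fh.write(
                str(sid) + "\t" + "\t".join("/".join(row[c]) for c in cols) + "\n"
            )
    study.subjects.to_csv(paths["subjects"], index=False)
    study.truth.to_csv(paths["truth"], index=False)
    return paths


NEUTRAL_MODELS = ("singleton_excess", "balanced_two_class", "binomial_neutral")


def generate_neutral_region(
    n_sequences: int, n_sites: int, model: str = "binomial_neutral",
    seed: int = 0, class_freq: float = 0.5,
) -> np.ndarray:
    """Generate an (n_sequences x n_sites) 0/1 haplotype matrix under a
    stylized scenario for the neutrality statistic.

    * ``singleton_excess`` — every variant is carried by exactly one
      (random) sequence: an excess of rare variants, driving D negative.
    * ``balanced_two_class`` — two haplotype classes differing at every
      site, the derived class at ``class_freq``: an excess of
      intermediate-frequency variants, driving D positive.
    * ``binomial_neutral`` — per-site derived-allele counts drawn from the
      neutral frequency spectrum (P(i) proportional to 1/i), placed on random
      sequences; E[pi] = E[theta_w] so D is centered near zero.
    """
    if n_sequences < 4:
        raise SyntheticDataError(f"need >= 4 sequences, got {n_sequences}")
    rng = np.random.default_rng(seed)
    m = np.zeros((n_sequences, n_sites), dtype=np.int8)
    if model == "singleton_excess":
        carriers = rng.integers(n_sequences, size=n_sites)
        m[carriers, np.arange(n_sites)] = 1
    elif model == "balanced_two_class":
        n_derived = int(round(class_freq * n_sequences))
        if not 1 <= n_derived <= n_sequences - 1:
            raise SyntheticDataError("class_freq leaves no segregating class")
        m[:n_derived, :] = 1
    elif model == "binomial_neutral":
        i = np.arange(1, n_sequences)
        probs = (1.0 / i) / np.sum(1.0 / i)
        counts = 1 + rng.choice(n_sequences - 1, size=n_sites, p=probs)
        for j, c in enumerate(counts):
            m[rng.choice(n_sequences, size=c, replace=False), j] = 1
    else:
        raise SyntheticDataError(f"unknown model {model!r}; use one of {NEUTRAL_MODELS}")
    return m
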