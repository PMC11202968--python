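"""Screening statistics for biallelic SNVs: MAF, two-group Fst, pairwise LD,
LD-block detection, and Tajima's neutrality statistic.

Conventions
-----------
* Genotypes are unphased alt-allele dosages in {0, 1, 2}, missing < 0.
* Missing data handling is per-statistic: per-site complete cases for
  MAF/Fst, pairwise-complete genotypes for LD.
* Two Fst estimators are exposed. ``weir_cockerham`` is the Weir & Cockerham
  (1984) theta-hat with the full a/b/c variance components including observed
  heterozygosity — the estimator behind PLINK's per-SNP --fst, which is what
  a typical screening run actually computes even when described with Wright's
  symbols. ``hudson`` is the uncorrected 1 - Hw/Hb form, which is exactly 0
  for identical allele frequencies and exactly 1 for a fixed difference.
* Negative Fst estimates are reported as computed (flagged), never clipped;
  downstream classification against the 0.15 / 0.25 descriptive thresholds
  is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomics_io import MISSING, GenomicInterval, GenotypeMatrix, VariantInfo

__all__ = [
    "compute_maf", "compute_fst", "compute_ld", "detect_blocks", "tajimas_d",
    "FstResult", "LDPair", "LDBlock", "TajimaComponents", "PopgenError",
    "UndefinedStatisticError", "genotypes_to_allele_counts",
]


class PopgenError(Exception):
    pass


class UndefinedStatisticError(PopgenError):
    """Raised when a statistic is undefined for the given data (e.g. all
    genotypes missing, or a monomorphic site where LD has no meaning)."""


def _clean(dosages) -> np.ndarray:
    d = np.asarray(dosages)
    return d[(d >= 0) & (d <= 2)].astype(float)


def compute_maf(dosages) -> float:
    """Minor allele frequency at one site, excluding missing genotypes."""
    d = _clean(dosages)
    if d.size == 0:
        raise UndefinedStatisticError("all genotypes missing at site")
    p_alt = d.sum() / (2.0 * d.size)
    return float(min(p_alt, 1.0 - p_alt))


# ---------------------------------------------------------------------------
# Fst


@dataclass
class FstResult:
    variant: VariantInfo | None
    subpop_freqs: dict
    subpop_sizes: dict  # allele counts (2 x non-missing diploids)
    fst: float
    estimator: str
    negative: bool = False

    def classify(self, moderate: float = 0.15, high: float = 0.25) -> str:
        """Descriptive divergence class using fixed screening thresholds."""
        if self.fst > high:
            return "high"
        if self.fst > moderate:
            return "moderate"
        return "low"


def _wc_theta(p: np.ndarray, het: np.ndarray, n: np.ndarray) -> float:
    """Weir & Cockerham (1984) single-locus theta-hat for r subpopulations.

    p: per-group alt frequency; het: per-group observed heterozygote
    proportion; n: per-group diploid sample size.
    """
    r = len(p)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * het).sum() / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        raise UndefinedStatisticError("Weir-Cockerham denominator is zero (monomorphic)")
    return float(a / denom)


def compute_fst(
    dosages, group_labels, estimator: str = "weir_cockerham",
    variant: VariantInfo | None = None,
) -> FstResult:
    """Per-SNP fixation index between exactly two groups.

    ``hudson`` is 1 - Hw/Hb with Hw = p1(1-p1) + p2(1-p2) and
    Hb = p1(1-p2) + p2(1-p1) (equivalently (p1-p2)^2 / Hb);
    ``weir_cockerham`` is the WC84 theta-hat (default). Negative estimates
    are reported as computed with ``negative=True``.
    """
    d = np.asarray(dosages)
    labels = np.asarray(group_labels)
    if d.shape != labels.shape:
        raise PopgenError("dosages and group_labels must align")
    groups = [g for g in dict.fromkeys(labels.tolist())]
    if len(groups) != 2:
        raise PopgenError(f"exactly two groups required, got {groups}")
    p, het, n = {}, {}, {}
    for g in groups:
        dg = d[labels == g]
        dg = dg[(dg >= 0) & (dg <= 2)]
        if dg.size == 0:
            raise UndefinedStatisticError(f"group {g!r} entirely missing at site")
        p[g] = dg.sum() / (2.0 * dg.size)
        het[g] = float(np.mean(dg == 1))
        n[g] = dg.size
    g1, g2 = groups
    if estimator == "hudson":
        # 1 - Hw/Hb with Hw and Hb both summed over the two orderings, so
        # that Hb - Hw = (p1 - p2)^2 and Fst is 0 at equal frequencies and
        # 1 at a fixed difference.
        hw = p[g1] * (1 - p[g1]) + p[g2] * (1 - p[g2])
        hb = p[g1] * (1 - p[g2]) + p[g2] * (1 - p[g1])
        if hb == 0:
            raise UndefinedStatisticError("both groups monomorphic for the same allele")
        fst = 1.0 - hw / hb
    elif estimator == "weir_cockerham":
        fst = _wc_theta(
            np.array([p[g1], p[g2]]),
            np.array([het[g1], het[g2]]),
            np.array([float(n[g1]), float(n[g2])]),
        )
    else:
        raise PopgenError(f"unknown estimator {estimator!r}")
    return FstResult(
        variant=variant,
        subpop_freqs={g1: p[g1], g2: p[g2]},
        subpop_sizes={g1: 2 * n[g1], g2: 2 * n[g2]},
        fst=float(fst),
        estimator=estimator,
        negative=fst < 0,
    )


# ---------------------------------------------------------------------------
# Two-locus LD via EM over the double-heterozygote ambiguity


@dataclass
class LDPair:
    variant_a: VariantInfo | None
    variant_b: VariantInfo | None
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float
    n: int  # pairwise-complete diploid count


def _em_haplotype_freq(
    d_a: np.ndarray, d_b: np.ndarray, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[float, float, float]:
    """EM estimate of the alt-alt haplotype frequency from unphased dosages.

    Returns (p_ab, p_a, p_b). Dosage pairs other than the double heterozygote
    determine their haplotypes exactly; (1, 1) splits between cis (alt-alt /
    ref-ref) and trans configurations in proportion to the current haplotype
    frequencies.
    """
    n = d_a.size
    p_a = d_a.sum() / (2 * n)
    p_b = d_b.sum() / (2 * n)
    n_dh = int(np.sum((d_a == 1) & (d_b == 1)))
    # alt-alt haplotype count contributed by each unambiguous dosage pair
    table = {
        (0, 0): 0, (0, 1): 0, (0, 2): 0,
        (1, 0): 0, (2, 0): 0,
        (1, 2): 1, (2, 1): 1, (2, 2): 2,
    }
    fixed = sum(
        table[(int(a), int(b))] for a, b in zip(d_a, d_b) if (a, b) != (1, 1)
    )
    p_ab = p_a * p_b if p_a * p_b > 0 else 0.25  # start at linkage equilibrium
    p_ab = min(max(p_ab, 1e-9), min(p_a, p_b))
    for _ in range(max_iter):
        # P(cis | double het) under current estimate
        f_ab = p_ab
        f_Ab = p_a - p_ab
        f_aB = p_b - p_ab
        f_AB0 = 1 - p_a - p_b + p_ab
        cis = f_ab * f_AB0
        trans = f_Ab * f_aB
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = (fixed + n_dh * w) / (2 * n)
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    return float(p_ab), float(p_a), float(p_b)


def compute_ld(
    dosages_a, dosages_b,
    variant_a: VariantInfo | None = None, variant_b: VariantInfo | None = None,
) -> LDPair:
    """Pairwise linkage disequilibrium (D, D', r^2) between two sites.

    Haplotype frequencies are estimated by EM over the double-heterozygote
    phase ambiguity on pairwise-complete genotypes.
    """
    a = np.asarray(dosages_a)
    b = np.asarray(dosages_b)
    keep = (a >= 0) & (a <= 2) & (b >= 0) & (b <= 2)
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size < 2:
        raise UndefinedStatisticError("fewer than 2 pairwise-complete genotypes")
    p_ab, p_a, p_b = _em_haplotype_freq(a, b)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedStatisticError("monomorphic site: LD undefined")
    d = p_ab - p_a * p_b
    if d > 0:
        dmax = min(p_a * (1 - p_b), p_b * (1 - p_a))
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDPair(
        variant_a=variant_a, variant_b=variant_b,
        p_a=p_a, p_b=p_b, p_ab=p_ab, d=float(d),
        d_prime=float(min(d_prime, 1.0)), r2=float(min(r2, 1.0)), n=int(a.size),
    )


# ---------------------------------------------------------------------------
# LD-block detection


@dataclass
class LDBlock:
    variants: list[VariantInfo]
    interval: GenomicInterval

    @property
    def n_snps(self) -> int:
        return len(self.variants)


def detect_blocks(
    matrix: GenotypeMatrix, d_prime_min: float = 0.75, r2_min: float = 0.75
) -> list[LDBlock]:
    """Maximal runs of consecutive variants that are all in strong mutual LD.

    A block is a maximal run of >= 2 position-consecutive variants in which
    EVERY within-run pair satisfies D' > d_prime_min and r^2 > r2_min.
    Sites where LD is undefined (monomorphic) break any run. Singletons are
    not reported.
    """
    m = matrix.n_variants

    cache: dict[tuple[int, int], bool] = {}

    def strong(i: int, j: int) -> bool:
        key = (i, j)
        if key not in cache:
            try:
                ld = compute_ld(matrix.dosages[:, i], matrix.dosages[:, j])
                cache[key] = ld.d_prime > d_prime_min and ld.r2 > r2_min
            except UndefinedStatisticError:
                cache[key] = False
        return cache[key]

    blocks: list[LDBlock] = []
    start = 0
    while start < m:
        end = start  # run is [start, end] inclusive
        while end + 1 < m and all(strong(i, end + 1) for i in range(start, end + 1)):
            end += 1
        if end > start:
            members = matrix.variants[start:end + 1]
            blocks.append(
                LDBlock(
                    variants=list(members),
                    interval=GenomicInterval(
                        members[0].chrom, members[0].pos, members[-1].pos
                    ),
                )
            )
            start = end + 1
        else:
            start += 1
    return blocks


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaComponents:
    n: int
    s: int
    pi: float
    theta_w: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    d: float | None  # None when undefined (s == 0)


def _tajima_constants(n: int) -> tuple[float, ...]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def genotypes_to_allele_counts(dosages: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-site alt-allele counts and the (uniform) allele total from unphased
    diploid dosages with no missingness."""
    d = np.asarray(dosages)
    if (d < 0).any():
        raise PopgenError("missing genotypes not supported for Tajima input")
    return d.sum(axis=0).astype(int), 2 * d.shape[0]


def tajimas_d(matrix, input_type: str = "haplotypes") -> TajimaComponents:
    """Tajima's neutrality statistic over a region.

    Parameters
    ----------
    matrix
        ``haplotypes``: an (n_sequences x n_sites) 0/1 array, one row per
        sequence. ``genotypes``: an (n_diploids x n_sites) dosage array; each
        diploid contributes two sequences and the mean pairwise difference is
        computed from allele frequencies with the unbiased n/(n-1) factor —
        exact when sites are treated independently, an approximation to the
        haplotype-level statistic only in its ignorance of phase (which pi
        does not use anyway).

    D is ``(pi - theta_w) / sqrt(e1*s + e2*s*(s-1))`` with the standard
    constants; undefined (``d=None``) when there are no segregating sites.
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise PopgenError("matrix must be 2-dimensional")
    if input_type == "haplotypes":
        if not np.isin(m, (0, 1)).all():
            raise PopgenError("haplotype matrix must be 0/1")
        counts = m.sum(axis=0).astype(int)
        n = m.shape[0]
    elif input_type == "genotypes":
        counts, n = genotypes_to_allele_counts(m)
    else:
        raise PopgenError(f"unknown input_type {input_type!r}")
    if n < 4:
        raise PopgenError(f"need >= 4 sequences, got {n}")
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    # mean pairwise differences: sum over sites of 2*i*(n-i)/(n*(n-1))
    i_counts = counts[seg].astype(float)
    pi = float(np.sum(2.0 * i_counts * (n - i_counts)) / (n * (n - 1)))
    a1, a2, b1, b2, c1, c2, e1, e2 = _tajima_constants(n)
    theta_w = s / a1
    if s == 0:
        d = None
    else:
        var = e1 * s + e2 * s * (s - 1)
        d = float((pi - theta_w) / np.sqrt(var)) if var > 0 else None
    return TajimaComponents(
        n=n, s=s, pi=pi, theta_w=float(theta_w),
        a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2, d=d,
    )
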