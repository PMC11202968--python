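"""Genotype and subject-metadata I/O with 1-based inclusive genomic intervals.

All coordinates are 1-based and inclusive on both ends, matching VCF POS and
the convention used when amplicon lengths are reported as ``end - start + 1``.
Genotypes are stored as unphased alt-allele dosages; any phase separator in a
VCF is ignored. Only biallelic single-nucleotide variants enter the matrix —
multiallelic records and indels are skipped with a logged count, because the
downstream screening statistics (MAF, Fst, two-locus LD) are defined for
biallelic loci. Sanger-style allele-pair genotype tables (one column per
rsID holding e.g. ``G/C``) are supported as a separate, allele-typed table
because per-amplicon genotyping can legitimately observe a third allele at a
site that the biallelic matrix cannot represent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel dosage for a missing genotype

_BASES = frozenset("ACGT")


class GenomicsIOError(Exception):
    """Base error for malformed genomic inputs."""


class InvalidIntervalError(GenomicsIOError):
    pass


class SchemaError(GenomicsIOError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval on a chromosome, 1-based on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InvalidIntervalError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InvalidIntervalError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (e.g. ``17:3596108-3596806``)."""
        try:
            chrom, rng = text.split(":")
            start_s, end_s = rng.split("-")
            return cls(chrom, int(start_s), int(end_s))
        except (ValueError, TypeError) as exc:
            raise InvalidIntervalError(f"cannot parse interval {text!r}") from exc


def interval_length(iv: GenomicInterval) -> int:
    """Number of base pairs spanned by a closed interval."""
    return len(iv)


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic single-nucleotide variant."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenomicsIOError(f"position must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if len(a) != 1 or a.upper() not in _BASES:
                raise GenomicsIOError(f"{name}={a!r} is not a single A/C/G/T base")
        if self.ref_allele == self.alt_allele:
            raise GenomicsIOError(f"ref and alt alleles are both {self.ref_allele!r}")


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of unphased alt-allele dosages.

    ``dosages[i, j]`` is the number of alternate alleles (0, 1, 2) carried by
    ``samples[i]`` at ``variants[j]``, or :data:`MISSING`.
    """

    variants: list[VariantInfo]
    samples: list[str]
    dosages: np.ndarray
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise GenomicsIOError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            raise GenomicsIOError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, rsid: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == rsid:
                return j
        raise KeyError(rsid)

    def site_dosages(self, rsid: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(rsid)]

    def allele_pairs(self) -> pd.DataFrame:
        """Dosages rendered as unordered allele pairs, e.g. ``G/C``.

        Heterozygotes are written ref-first; missing genotypes become ``./.``.
        """
        cols = {}
        for j, v in enumerate(self.variants):
            mapping = {
                0: f"{v.ref_allele}/{v.ref_allele}",
                1: f"{v.ref_allele}/{v.alt_allele}",
                2: f"{v.alt_allele}/{v.alt_allele}",
                MISSING: "./.",
            }
            cols[v.id] = [mapping[int(d)] for d in self.dosages[:, j]]
        return pd.DataFrame(cols, index=pd.Index(self.samples, name="sample_id"))


@dataclass
class SubjectRecord:
    """One study participant: identity, anthropometry, bioimpedance, perception."""

    id: str
    sex: str
    ancestry: str | None = None
    age: float | None = None
    height_cm: float | None = None
    weight_kg: float | None = None
    arm_circ_cm: float | None = None
    waist_circ_cm: float | None = None
    calf_circ_cm: float | None = None
    R_ohm: float | None = None
    Xc_ohm: float | None = None
    capsaicin_threshold: int | None = None
    prop_score: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# VCF / TSV genotype input


def _sort_and_build(
    variants: list[VariantInfo], samples: list[str], columns: list[np.ndarray],
    n_skipped: int,
) -> GenotypeMatrix:
    order = sorted(range(len(variants)), key=lambda j: (variants[j].chrom, variants[j].pos))
    variants = [variants[j] for j in order]
    if columns:
        dosages = np.stack([columns[j] for j in order], axis=1)
    else:
        dosages = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(variants, samples, dosages, n_skipped_records=n_skipped)


def _read_vcf(path: str, region: GenomicInterval | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if region is not None and not region.contains(
            rec.CHROM.removeprefix("chr"), rec.POS
        ) and not region.contains(rec.CHROM, rec.POS):
            continue
        alts = rec.ALT
        if (
            len(alts) != 1
            or len(rec.REF) != 1
            or len(alts[0]) != 1
            or rec.REF.upper() not in _BASES
            or alts[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantInfo(rec.CHROM, rec.POS, vid, rec.REF, alts[0]))
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (with gts012), 3=unknown
        gts = rec.gt_types
        col = np.where(gts == 3, MISSING, gts).astype(np.int8)
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV record(s) in %s", n_skipped, path)
    if not variants:
        logger.warning("no biallelic SNVs found in %s (region=%s)", path, region)
    return _sort_and_build(variants, samples, columns, n_skipped)


def _read_tsv(path: str, region: GenomicInterval | None) -> GenotypeMatrix:
    """Read the Sanger-style allele-pair TSV dialect.

    Layout: comment lines ``## variant=<id> chrom=<c> pos=<p> ref=<R> alt=<A>``
    declaring each biallelic site, then a header ``sample_id<TAB>rsid...`` and
    one row per sample with allele pairs like ``G/C``. Sites whose observed
    alleles fall outside {ref, alt} are skipped with a logged count, mirroring
    the multiallelic rule of the VCF path.
    """
    meta: dict[str, VariantInfo] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                fields = dict(
                    kv.split("=", 1) for kv in line[2:].strip().split() if "=" in kv
                )
                try:
                    v = VariantInfo(
                        fields["chrom"], int(fields["pos"]), fields["variant"],
                        fields["ref"], fields["alt"],
                    )
                except (KeyError, ValueError) as exc:
                    raise GenomicsIOError(
                        f"{path}:{lineno}: malformed variant metadata line"
                    ) from exc
                meta[v.id] = v
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[0] != "sample_id":
                    raise GenomicsIOError(
                        f"{path}:{lineno}: first column must be 'sample_id'"
                    )
                missing_meta = [c for c in header[1:] if c not in meta]
                if missing_meta:
                    raise GenomicsIOError(
                        f"{path}: no '## variant=' metadata for {missing_meta}"
                    )
                continue
            if len(parts) != len(header):
                raise GenomicsIOError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            rows.append(parts)
    if header is None:
        raise GenomicsIOError(f"{path}: empty genotype table")
    samples = [r[0] for r in rows]
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for j, rsid in enumerate(header[1:], start=1):
        v = meta[rsid]
        if region is not None and not region.contains(v.chrom, v.pos):
            continue
        col = np.empty(len(rows), dtype=np.int8)
        foreign = False
        for i, r in enumerate(rows):
            cell = r[j]
            if cell in (".", "./.", ""):
                col[i] = MISSING
                continue
            alleles = cell.replace("|", "/").split("/")
            if len(alleles) != 2:
                raise GenomicsIOError(f"{path}: bad genotype {cell!r} at {rsid}")
            if any(a not in (v.ref_allele, v.alt_allele) for a in alleles):
                foreign = True
                break
            col[i] = sum(a == v.alt_allele for a in alleles)
        if foreign:
            n_skipped += 1
            logger.info("site %s carries a third allele; skipped", rsid)
            continue
        variants.append(v)
        columns.append(col)
    if not variants:
        logger.warning("no usable sites in %s (region=%s)", path, region)
    return _sort_and_build(variants, samples, columns, n_skipped)


def read_genotypes(
    path: str, format: str = "vcf", region: GenomicInterval | None = None
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or allele-pair TSV file.

    Variants are returned sorted by (chrom, pos); the region filter is
    inclusive of both endpoints. Records that are not biallelic SNVs are
    skipped and counted in ``n_skipped_records``.
    """
    if format == "vcf":
        return _read_vcf(path, region)
    if format == "tsv":
        return _read_tsv(path, region)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str, format: str = "vcf") -> None:
    """Write a genotype matrix as minimal VCF v4.2 or the allele-pair TSV."""
    if format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(matrix.samples) + "\n"
            )
            gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, v in enumerate(matrix.variants):
                gts = "\t".join(gt_of[int(d)] for d in matrix.dosages[:, j])
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )
    elif format == "tsv":
        pairs = matrix.allele_pairs()
        with open(path, "w") as fh:
            for v in matrix.variants:
                fh.write(
                    f"## variant={v.id} chrom={v.chrom} pos={v.pos} "
                    f"ref={v.ref_allele} alt={v.alt_allele}\n"
                )
            fh.write("sample_id\t" + "\t".join(v.id for v in matrix.variants) + "\n")
            for sid in matrix.samples:
                fh.write(sid + "\t" + "\t".join(pairs.loc[sid, v.id] for v in matrix.variants) + "\n")
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_allele_table(path: str) -> pd.DataFrame:
    """Read an allele-pair genotype table without the biallelic restriction.

    Returns a DataFrame indexed by sample_id with one column per rsID holding
    sorted allele tuples, e.g. ``("C", "G")``; missing genotypes become None.
    Used by diplotype calling, where a per-amplicon Sanger call may carry an
    allele outside the biallelic ref/alt pair.
    """
    header: list[str] | None = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[0] != "sample_id":
                    raise GenomicsIOError(f"{path}: first column must be 'sample_id'")
                continue
            rows.append(parts)
    if header is None:
        raise GenomicsIOError(f"{path}: empty genotype table")

    def parse_cell(cell: str):
        if cell in (".", "./.", ""):
            return None
        alleles = cell.replace("|", "/").split("/")
        if len(alleles) != 2:
            raise GenomicsIOError(f"{path}: bad genotype {cell!r}")
        return tuple(sorted(alleles))

    data = {
        h: [parse_cell(r[j]) for r in rows] for j, h in enumerate(header) if j > 0
    }
    return pd.DataFrame(data, index=pd.Index([r[0] for r in rows], name="sample_id"))


# ---------------------------------------------------------------------------
# Subject metadata

_NUMERIC_FIELDS = (
    "age", "height_cm", "weight_kg", "arm_circ_cm", "waist_circ_cm",
    "calf_circ_cm", "R_ohm", "Xc_ohm", "prop_score",
)


def read_subjects(path: str) -> list[SubjectRecord]:
    """Read subject metadata from CSV into typed records.

    Mandatory columns: ``id`` and ``sex`` (M/F). Unparseable numeric cells
    become missing with a logged warning; duplicate subject IDs are an error.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "sex"):
        if col not in df.columns:
            raise SchemaError(f"{path}: mandatory column {col!r} missing")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicated subject ID(s): {sorted(set(dup))}")
    records = []
    for _, row in df.iterrows():
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            raise SchemaError(f"{path}: subject {row['id']}: sex must be M or F, got {row['sex']!r}")
        rec = SubjectRecord(id=str(row["id"]), sex=sex)
        if "ancestry" in df.columns and pd.notna(row.get("ancestry")):
            rec.ancestry = str(row["ancestry"])
        for fieldname in _NUMERIC_FIELDS:
            if fieldname in df.columns:
                raw = row[fieldname]
                if pd.isna(raw) or str(raw).strip() == "":
                    continue
                try:
                    setattr(rec, fieldname, float(raw))
                except ValueError:
                    logger.warning(
                        "subject %s: unparseable %s=%r treated as missing",
                        rec.id, fieldname, raw,
                    )
        if "capsaicin_threshold" in df.columns:
            raw = row["capsaicin_threshold"]
            if pd.notna(raw) and str(raw).strip() != "":
                try:
                    rec.capsaicin_threshold = int(float(raw))
                except ValueError:
                    logger.warning(
                        "subject %s: unparseable capsaicin_threshold=%r", rec.id, raw
                    )
        known = {"id", "sex", "ancestry", "capsaicin_threshold", *_NUMERIC_FIELDS}
        rec.extra = {
            c: row[c] for c in df.columns if c not in known and pd.notna(row[c])
        }
        records.append(rec)
    return records


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of subject records (one row per subject)."""
    cols = ["id", "sex", "ancestry", "age", "height_cm", "weight_kg",
            "arm_circ_cm", "waist_circ_cm", "calf_circ_cm", "R_ohm", "Xc_ohm",
            "capsaicin_threshold", "prop_score"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])
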