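"""End-to-end pipeline: screen -> blocks -> diplotypes -> BIVA -> association.

Ties the stages together behind a single config object, writing TSV tables
(each with a header row and a provenance comment), optional plots, and a
machine-readable JSON run summary with versions, seed, and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    BIOELECTRIC_PHENOTYPES, fit_diplotype_regression, group_tests_to_frame,
    groupwise_tests, sex_zscore,
)
from .biva import derive_geometry, hotelling_two_sample, specific_vector
from .genomics_io import (
    GenomicsIOError, read_allele_table, read_genotypes, read_subjects,
    subjects_to_frame,
)
from .haplotyping import b_copy_count, call_diplotypes, calls_to_frame, \
    group_diplotypes, load_block_definitions
from .popgen import UndefinedStatisticError, compute_fst, compute_ld, \
    compute_maf, detect_blocks

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class PipelineError(Exception):
    exit_code = EXIT_DATA_ERROR


class ConfigError(PipelineError):
    exit_code = EXIT_CONFIG_ERROR


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    genotype_path: str
    subject_path: str
    genotype_format: str = "vcf"
    allele_table_path: str | None = None  # defaults to genotype_path when TSV
    block_definitions_path: str | None = None  # None -> shipped TRPV1 blocks
    group_column: str = "ancestry"
    fst_moderate: float = 0.15
    fst_high: float = 0.25
    ld_threshold: float = 0.75
    alpha: float = 0.05
    prop_cut: float = 50.0
    grouping_scheme: str = "merge_c_into_b"
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_moderate", "fst_high", "ld_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key in {path}: {exc}") from exc

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# haplobiva {__version__} | config={config.content_hash()} | "
            f"coordinates 1-based inclusive\n"
        )
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class RunReport:
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.output_dir``.

    Raises :class:`PipelineError` (exit code 3) on data problems and
    :class:`ConfigError` (exit code 2) on configuration problems; any stage
    failure names its stage.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    summary: dict = {
        "tool": "haplobiva", "version": __version__, "seed": config.seed,
        "config_hash": config.content_hash(), "stages": {},
    }
    out = lambda name: os.path.join(config.output_dir, name)

    # --- stage: input -----------------------------------------------------
    stage = "input"
    try:
        if not os.path.exists(config.genotype_path):
            raise PipelineError(f"genotype file not found: {config.genotype_path}")
        if not os.path.exists(config.subject_path):
            raise PipelineError(f"subject file not found: {config.subject_path}")
        matrix = read_genotypes(config.genotype_path, format=config.genotype_format)
        subjects = subjects_to_frame(read_subjects(config.subject_path))
        blocks = load_block_definitions(config.block_definitions_path)
        allele_path = config.allele_table_path or (
            config.genotype_path if config.genotype_format == "tsv" else None
        )
        allele_table = (
            read_allele_table(allele_path) if allele_path else matrix.allele_pairs()
        )
    except (GenomicsIOError, OSError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc
    summary["stages"][stage] = {
        "n_samples": matrix.n_samples, "n_variants": matrix.n_variants,
        "n_skipped_records": matrix.n_skipped_records,
        "n_subjects": len(subjects),
    }

    # --- stage: screen (MAF / Fst) ---------------------------------------
    stage = "screen"
    groups = subjects.set_index("id")[config.group_column].reindex(matrix.samples)
    if groups.isna().any():
        raise PipelineError(
            f"stage {stage}: samples without {config.group_column!r} metadata: "
            f"{list(groups.index[groups.isna()])[:5]}"
        )
    rows = []
    for j, v in enumerate(matrix.variants):
        d = matrix.dosages[:, j]
        row = {"chrom": v.chrom, "pos": v.pos, "rsid": v.id,
               "ref": v.ref_allele, "alt": v.alt_allele}
        try:
            row["maf"] = round(compute_maf(d), 6)
        except UndefinedStatisticError:
            row["maf"] = "NA"
        try:
            fst = compute_fst(d, groups.to_numpy())
            row["fst_wc"] = round(fst.fst, 6)
            row["fst_class"] = fst.classify(config.fst_moderate, config.fst_high)
        except UndefinedStatisticError:
            row["fst_wc"], row["fst_class"] = "NA", "NA"
        rows.append(row)
    screen_df = pd.DataFrame(rows)
    _write_table(screen_df, out("screen.tsv"), config)
    summary["stages"][stage] = {
        "n_sites": len(rows),
        "n_fst_high": int((screen_df["fst_class"] == "high").sum()),
        "n_fst_moderate": int((screen_df["fst_class"] == "moderate").sum()),
    }

    # --- stage: blocks ----------------------------------------------------
    # Block detection runs on the screened SNP set (between-group Fst above
    # the moderate threshold): screening precedes block-finding in the
    # two-stage procedure, and weakly divergent SNPs interleaved inside an
    # amplicon would otherwise split a block under the contiguous-run rule.
    stage = "blocks"
    divergent = [
        j for j, row in enumerate(rows)
        if isinstance(row["fst_wc"], float) and row["fst_wc"] > config.fst_moderate
    ]
    if divergent:
        from .genomics_io import GenotypeMatrix as _GM

        sub = _GM(
            [matrix.variants[j] for j in divergent], matrix.samples,
            matrix.dosages[:, divergent],
        )
    else:
        sub = matrix
    found = detect_blocks(sub, config.ld_threshold, config.ld_threshold)
    block_rows = [
        {"chrom": b.interval.chrom, "start": b.interval.start,
         "end": b.interval.end, "n_snps": b.n_snps,
         "members": ",".join(v.id for v in b.variants)}
        for b in found
    ]
    _write_table(pd.DataFrame(
        block_rows, columns=["chrom", "start", "end", "n_snps", "members"]
    ), out("blocks.tsv"), config)
    # pairwise LD table for the record
    ld_rows = []
    for i in range(matrix.n_variants):
        for j in range(i + 1, matrix.n_variants):
            try:
                ld = compute_ld(matrix.dosages[:, i], matrix.dosages[:, j])
            except UndefinedStatisticError:
                continue
            ld_rows.append({
                "rsid_a": matrix.variants[i].id, "rsid_b": matrix.variants[j].id,
                "d_prime": round(ld.d_prime, 4), "r2": round(ld.r2, 4),
            })
    _write_table(pd.DataFrame(
        ld_rows, columns=["rsid_a", "rsid_b", "d_prime", "r2"]
    ), out("ld_pairs.tsv"), config)
    summary["stages"][stage] = {"n_blocks": len(found)}

    # --- stage: diplotype -------------------------------------------------
    stage = "diplotype"
    calls_by_block = {
        name: call_diplotypes(allele_table, block) for name, block in blocks.items()
    }
    calls_df = calls_to_frame(calls_by_block).reset_index()
    _write_table(calls_df, out("diplotypes.tsv"), config)
    n_unresolved = {
        name: sum(0 if c.resolved else 1 for c in calls)
        for name, calls in calls_by_block.items()
    }
    summary["stages"][stage] = {
        "blocks_called": list(blocks), "n_unresolved": n_unresolved,
    }

    # --- stage: biva ------------------------------------------------------
    stage = "biva"
    anthro_cols = ["height_cm", "weight_kg", "arm_circ_cm", "waist_circ_cm",
                   "calf_circ_cm", "R_ohm", "Xc_ohm"]
    complete = subjects.dropna(subset=anthro_cols).copy()
    vectors = []
    for _, row in complete.iterrows():
        geom = derive_geometry(
            row["height_cm"], row["weight_kg"], row["arm_circ_cm"],
            row["waist_circ_cm"], row["calf_circ_cm"],
        )
        bv = specific_vector(row["R_ohm"], row["Xc_ohm"], geom)
        vectors.append({
            "id": row["id"], "sex": row["sex"],
            config.group_column: row[config.group_column],
            "bmi": round(geom.bmi, 2),
            "rsp": bv.rsp, "xcsp": bv.xcsp, "zsp": bv.zsp, "pha": bv.pha,
        })
    biva_df = pd.DataFrame(vectors)
    _write_table(
        biva_df.assign(**{c: biva_df[c].round(2) for c in ("rsp", "xcsp", "zsp", "pha")}),
        out("biva_vectors.tsv"), config,
    )
    comparisons = []
    grouping = biva_df[config.group_column]
    levels = list(pd.unique(grouping))
    if len(levels) == 2:
        pairs_to_test = [
            (f"{levels[0]} vs {levels[1]}", grouping == levels[0], grouping == levels[1]),
            ("M vs F", biva_df["sex"] == "M", biva_df["sex"] == "F"),
        ]
        for name, mask_a, mask_b in pairs_to_test:
            a = biva_df.loc[mask_a, ["rsp", "xcsp"]].to_numpy()
            b = biva_df.loc[mask_b, ["rsp", "xcsp"]].to_numpy()
            if len(a) >= 3 and len(b) >= 3:
                h = hotelling_two_sample(a, b)
                comparisons.append({
                    "comparison": name, "n1": h.n1, "n2": h.n2,
                    "t2": round(h.t2, 2), "f": round(h.f_stat, 2),
                    "p": round(h.p_value, 5), "d": round(h.mahalanobis_d, 2),
                    "significant": h.p_value < config.alpha,
                })
    _write_table(pd.DataFrame(
        comparisons,
        columns=["comparison", "n1", "n2", "t2", "f", "p", "d", "significant"],
    ), out("hotelling.tsv"), config)
    summary["stages"][stage] = {
        "n_vectors": len(biva_df), "n_comparisons": len(comparisons),
    }

    # --- stage: association ----------------------------------------------
    stage = "association"
    assoc_rows, ttest_frames = [], []
    merged = biva_df.set_index("id")
    for name in blocks:
        calls = [c for c in calls_by_block[name] if c.resolved]
        copies = pd.Series(
            {c.subject_id: b_copy_count(c) for c in calls}, name="b_copies"
        )
        frame = merged.join(copies, how="inner").dropna(subset=["b_copies"])
        if len(frame) < 5 or frame["b_copies"].nunique() < 2:
            logger.info("block %s: not enough diplotype variation to test", name)
            continue
        for pheno in BIOELECTRIC_PHENOTYPES:
            try:
                fit = fit_diplotype_regression(
                    frame[pheno], frame["b_copies"], frame["sex"], coding="additive"
                )
            except Exception as exc:  # rank deficiency etc.
                logger.warning("block %s pheno %s: %s", name, pheno, exc)
                continue
            term = fit.term("genotype")
            assoc_rows.append({
                "block": name, "phenotype": pheno, "beta": round(term["beta"], 4),
                "t": round(term["t"], 4), "p": round(term["p"], 5),
                "n_used": fit.n_used,
            })
        # aa vs b-carrier t tests per sex stratum, on sex-standardized values
        groups_map = group_diplotypes(calls, scheme="carrier_vs_aa")
        tframe = frame.assign(group=[groups_map[i] for i in frame.index])
        if tframe["group"].nunique() == 2:
            zframe = tframe.copy()
            for pheno in BIOELECTRIC_PHENOTYPES:
                try:
                    zframe[pheno] = sex_zscore(tframe[pheno], tframe["sex"])
                except Exception:
                    pass
            results = groupwise_tests(zframe, "group", stratify_by_sex=True)
            tdf = group_tests_to_frame(results)
            tdf.insert(0, "block", name)
            ttest_frames.append(tdf)
    _write_table(pd.DataFrame(
        assoc_rows, columns=["block", "phenotype", "beta", "t", "p", "n_used"]
    ), out("association.tsv"), config)
    _write_table(
        pd.concat(ttest_frames, ignore_index=True) if ttest_frames
        else pd.DataFrame(columns=["block", "stratum", "variable", "n1", "n2", "t", "p"]),
        out("group_tests.tsv"), config,
    )
    summary["stages"][stage] = {
        "n_regressions": len(assoc_rows),
        "n_significant": sum(1 for r in assoc_rows if r["p"] < config.alpha),
    }

    report = RunReport(summary=summary)
    report.to_json(out("run_summary.json"))
    return report
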