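"""Named haplotype blocks and diplotype calling from unphased genotypes.

A haplotype block is a short run of tag SNPs over which two (or three) named
allele-state vectors segregate. Because the tag SNPs sit within a few hundred
base pairs and the observed genotype frequencies match the haplotype
frequencies of large reference panels, per-subject genotypes are resolved
into haplotype pairs under a same-phase assumption: the call is the unordered
pair of defined haplotypes whose site-wise allele union reproduces the
observed genotype at every tag SNP. No frequency-weighted guessing is done —
if several pairs fit the call is AMBIGUOUS, if none fits it is INCONSISTENT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations_with_replacement

import yaml

AMBIGUOUS = "AMBIGUOUS"
INCONSISTENT = "INCONSISTENT"


class HaplotypingError(Exception):
    pass


class ConfigurationError(HaplotypingError):
    pass


@dataclass(frozen=True)
class HaplotypeDefinition:
    """One named haplotype of a block: an ordered rsID -> allele map."""

    block_name: str
    label: str
    allele_states: dict  # rsID -> single-character allele, ordered by position

    def allele(self, rsid: str) -> str:
        return self.allele_states[rsid]


@dataclass
class HaplotypeBlock:
    """A block: its tag-SNP order and the haplotypes defined over it."""

    name: str
    chrom: str
    snp_ids: list[str]
    snp_positions: dict
    haplotypes: dict = field(default_factory=dict)  # label -> HaplotypeDefinition

    def __post_init__(self) -> None:
        for label, h in self.haplotypes.items():
            if set(h.allele_states) != set(self.snp_ids):
                raise ConfigurationError(
                    f"haplotype {self.name}-{label} does not cover the block's "
                    f"rsID set {self.snp_ids}"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.haplotypes)


@dataclass(frozen=True)
class DiplotypeCall:
    """Per-subject unordered haplotype-label pair for one block.

    ``pair`` is an alphabetically sorted 2-tuple like ("a", "b"), or the
    sentinel AMBIGUOUS / INCONSISTENT with candidates listing any pairs that
    fit.
    """

    subject_id: str
    block_name: str
    pair: tuple | str
    candidates: tuple = ()

    @property
    def resolved(self) -> bool:
        return isinstance(self.pair, tuple)

    @property
    def label(self) -> str:
        """Compact genotype label, e.g. ``ab``; sentinels pass through."""
        return "".join(self.pair) if self.resolved else self.pair


def load_block_definitions(path: str | None = None) -> dict:
    """Load block definitions from YAML; with no path, the TRPV1 H1/H2
    definitions shipped with the package."""
    if path is None:
        text = (
            resources.files("haplobiva").joinpath("data/trpv1_blocks.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    blocks = {}
    for name, spec in raw["blocks"].items():
        snp_ids = [s["id"] for s in spec["snps"]]
        positions = {s["id"]: int(s["pos"]) for s in spec["snps"]}
        haps = {
            label: HaplotypeDefinition(
                block_name=name, label=label,
                allele_states={rs: str(states[rs]) for rs in snp_ids},
            )
            for label, states in spec["haplotypes"].items()
        }
        blocks[name] = HaplotypeBlock(
            name=name, chrom=str(spec.get("chrom", "?")),
            snp_ids=snp_ids, snp_positions=positions, haplotypes=haps,
        )
    return blocks


def call_diplotype(
    subject_id: str, genotypes: dict, block: HaplotypeBlock
) -> DiplotypeCall:
    """Resolve one subject's unphased genotypes at a block into a haplotype pair.

    ``genotypes`` maps rsID -> unordered allele pair (2-tuple of characters)
    or None for missing. A missing tag SNP yields AMBIGUOUS with all pairs
    compatible at the observed sites as candidates.
    """
    for rsid in genotypes:
        if rsid not in block.snp_ids:
            raise ConfigurationError(
                f"rsID {rsid} is not a tag SNP of block {block.name}"
            )
    observed = {rs: genotypes.get(rs) for rs in block.snp_ids}
    has_missing = any(v is None for v in observed.values())

    def fits(h1: HaplotypeDefinition, h2: HaplotypeDefinition) -> bool:
        for rs, gt in observed.items():
            if gt is None:
                continue
            if tuple(sorted((h1.allele(rs), h2.allele(rs)))) != tuple(sorted(gt)):
                return False
        return True

    matches = tuple(
        tuple(sorted((l1, l2)))
        for l1, l2 in combinations_with_replacement(sorted(block.labels), 2)
        if fits(block.haplotypes[l1], block.haplotypes[l2])
    )
    if not matches:
        return DiplotypeCall(subject_id, block.name, INCONSISTENT)
    if len(matches) > 1 or has_missing:
        return DiplotypeCall(subject_id, block.name, AMBIGUOUS, candidates=matches)
    return DiplotypeCall(subject_id, block.name, matches[0])


def call_diplotypes(allele_table, block: HaplotypeBlock) -> list[DiplotypeCall]:
    """Call every subject in an allele-pair table (see
    :func:`haplobiva.genomics_io.read_allele_table`) at one block. Tag SNPs
    absent from the table count as missing for every subject."""
    calls = []
    for sid, row in allele_table.iterrows():
        genotypes = {
            rs: (tuple(row[rs]) if rs in allele_table.columns and row[rs] is not None else None)
            for rs in block.snp_ids
        }
        calls.append(call_diplotype(str(sid), genotypes, block))
    return calls


GROUPING_SCHEMES = ("raw", "merge_c_into_b", "carrier_vs_aa")


def group_diplotypes(calls, scheme: str = "raw") -> dict:
    """Map resolved diplotype calls to analysis group labels.

    * ``raw`` — the diplotype label itself (aa, ab, bb, ...).
    * ``merge_c_into_b`` — relabel any c haplotype as b before pairing, so a
      rare third haplotype is pooled with its near-identical sibling.
    * ``carrier_vs_aa`` — binary split: aa homozygotes vs. carriers of any
      non-a haplotype.

    Unresolved calls (AMBIGUOUS / INCONSISTENT) raise; exclude them first.
    """
    if scheme not in GROUPING_SCHEMES:
        raise HaplotypingError(f"unknown grouping scheme {scheme!r}")
    out = {}
    for call in calls:
        if not call.resolved:
            raise HaplotypingError(
                f"subject {call.subject_id}: cannot group unresolved call {call.pair}"
            )
        pair = call.pair
        if scheme == "raw":
            label = "".join(pair)
        elif scheme == "merge_c_into_b":
            label = "".join(sorted("b" if h == "c" else h for h in pair))
        else:  # carrier_vs_aa
            label = "aa" if all(h == "a" for h in pair) else "b-carrier"
        out[call.subject_id] = label
    return out


def b_copy_count(call: DiplotypeCall) -> int:
    """Copies of any non-a haplotype (additive genotype coding, c counted
    with b)."""
    if not call.resolved:
        raise HaplotypingError(f"unresolved call for {call.subject_id}")
    return sum(1 for h in call.pair if h != "a")


def calls_to_frame(calls_by_block: dict):
    """Tabulate calls as a DataFrame: subject_id, then one column per block."""
    import pandas as pd

    frames = {}
    for block_name, calls in calls_by_block.items():
        frames[block_name] = pd.Series(
            {c.subject_id: c.label for c in calls}, name=block_name
        )
    df = pd.DataFrame(frames)
    df.index.name = "subject_id"
    return df
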