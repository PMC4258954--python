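"""Exome variant prioritization for a dominant family disease.

The cascade takes annotated exome variants and applies, in order:

1. a functional filter keeping protein-affecting classes (non-synonymous,
   stop gain/loss, splicing SNVs; frameshift and non-frameshift indels);
2. two independent rarity branches — *novel* (absent from dbSNP and 1000
   Genomes) and *rare* (panel MAF up to 2%, inclusive; an unrecorded MAF
   qualifies) — whose survivors are unioned, not chained;
3. intersection with the linkage regions (1-based inclusive bp);
4. a co-segregation constraint: carried by every affected sample (het or
   hom-alt; a missing genotype in an affected sample disqualifies the
   variant), absent from every unaffected sample, with unconfirmed samples
   ignored.

Per-sample stage counts use carried-variant semantics: a variant counts for
a sample only when that sample's genotype is non-reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "GT_REF",
    "GT_HET",
    "GT_HOM",
    "GT_MISSING",
    "FUNCTIONAL_SNV_CLASSES",
    "INDEL_CLASSES",
    "VARIANT_CLASSES",
    "AnnotatedVariant",
    "CohortDesign",
    "CascadeReport",
    "Candidate",
    "functional_filter",
    "novelty_branch",
    "rarity_branch",
    "region_filter",
    "segregation_filter",
    "run_cascade",
    "read_variant_tables",
    "write_variant_tables",
]

GT_REF = "ref/ref"
GT_HET = "ref/alt"
GT_HOM = "alt/alt"
GT_MISSING = "missing"
_GENOTYPES = {GT_REF, GT_HET, GT_HOM, GT_MISSING}
CARRIER_GENOTYPES = {GT_HET, GT_HOM}

FUNCTIONAL_SNV_CLASSES = frozenset(
    {"nonsynonymous_SNV", "stopgain", "stoploss", "splicing"}
)
INDEL_CLASSES = frozenset({"frameshift_indel", "nonframeshift_indel"})
VARIANT_CLASSES = FUNCTIONAL_SNV_CLASSES | INDEL_CLASSES | {
    "synonymous_SNV",
    "other",
}

# Table-style stage labels
STAGE_TOTAL = "Total (Exonic, Splicing)"
STAGE_FUNCTIONAL = "SNVs (NS, SC), INDELs (FS, non-FS)"
STAGE_NOVEL = "Not in dbSNP or 1000 Genomes"
STAGE_RARE = "Up to 2% in 1000 Genomes"
STAGE_REGION = "Within linkage region"
STAGE_SHARED = "Shared by all AFFECTED"


@dataclass
class AnnotatedVariant:
    """One annotated exome variant with per-sample genotypes.

    ``maf`` maps population-panel labels to minor allele frequencies (None
    when the variant is unrecorded in that panel); ``scores`` carries
    pass-through annotations (GERP, SIFT, PolyPhen-2).
    """

    chromosome: str
    position_bp: int
    ref: str
    alt: str
    gene: str
    func_class: str
    dbsnp_id: str | None = None
    in_thousand_genomes: bool = False
    maf: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.func_class not in VARIANT_CLASSES:
            raise ParameterError(
                f"{self.key}: unknown functional class {self.func_class!r}"
            )
        if self.is_indel and self.func_class == "nonsynonymous_SNV":
            raise ParameterError(f"{self.key}: an indel cannot be a nonsynonymous SNV")
        for panel, f in self.maf.items():
            if f is not None and not 0.0 <= f <= 1.0:
                raise ParameterError(f"{self.key}: MAF[{panel}]={f} outside [0, 1]")
        for s, g in self.genotypes.items():
            if g not in _GENOTYPES:
                raise ParameterError(f"{self.key}: bad genotype {g!r} for sample {s}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position_bp}:{self.ref}:{self.alt}"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_novel(self) -> bool:
        return self.dbsnp_id is None and not self.in_thousand_genomes

    def carried_by(self, sample_id: str) -> bool:
        return self.genotypes.get(sample_id, GT_MISSING) in CARRIER_GENOTYPES


@dataclass(frozen=True)
class CohortDesign:
    """Affected / unaffected / unconfirmed sample groups (disjoint)."""

    affected: tuple
    unaffected: tuple = ()
    unconfirmed: tuple = ()

    def __post_init__(self):
        groups = [set(self.affected), set(self.unaffected), set(self.unconfirmed)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ParameterError("cohort design groups must be disjoint")

    @property
    def all_samples(self) -> tuple:
        return tuple(self.affected) + tuple(self.unaffected) + tuple(self.unconfirmed)


@dataclass
class CascadeReport:
    """Per-sample surviving carried-variant counts after each cascade stage."""

    branch: str  # "novel" or "rare"
    stages: list
    counts: dict  # stage -> {sample: count}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {stage: self.counts[stage] for stage in self.stages}
        ).T[list(self.counts[self.stages[0]])]

    def to_tsv(self) -> str:
        df = self.to_frame()
        df.index.name = "Criteria for variants filtering"
        return df.to_csv(sep="\t")

    def to_json(self) -> str:
        return json.dumps(
            {"branch": self.branch, "stages": self.stages, "counts": self.counts},
            indent=2,
        )

    def is_monotone(self) -> bool:
        """True when every sample's counts are non-increasing stage over stage."""
        samples = self.counts[self.stages[0]].keys()
        for s in samples:
            seq = [self.counts[st][s] for st in self.stages]
            if any(b > a for a, b in zip(seq, seq[1:])):
                return False
        return True


@dataclass(frozen=True)
class Candidate:
    """A cascade survivor tagged with the branch(es) that admitted it."""

    variant: AnnotatedVariant
    branches: tuple


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Tabular view of cascade survivors (one row per candidate variant)."""
    rows = []
    for c in candidates:
        v = c.variant
        rows.append(
            {
                "variant_key": v.key,
                "gene": v.gene,
                "func_class": v.func_class,
                "dbsnp_id": v.dbsnp_id,
                "branches": "+".join(c.branches),
                **{f"maf_{p}": f for p, f in v.maf.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# filters


def functional_filter(variants):
    """Split into protein-affecting SNVs and indels; drop the rest.

    Returns ``(snv_list, indel_list)`` preserving input order.
    """
    snvs = [v for v in variants if v.func_class in FUNCTIONAL_SNV_CLASSES]
    indels = [v for v in variants if v.func_class in INDEL_CLASSES]
    return snvs, indels


def novelty_branch(variants):
    """Variants absent from both dbSNP and 1000 Genomes."""
    return [v for v in variants if v.is_novel]


def _check_panel(variants, panel):
    panels = set()
    for v in variants:
        panels.update(v.maf.keys())
    if variants and panels and panel not in panels:
        raise ConfigurationError(
            f"unknown MAF panel {panel!r}; available: {sorted(panels)}"
        )


def rarity_branch(variants, panel: str, maf_max: float = 0.02):
    """Variants with panel MAF <= maf_max (inclusive); unrecorded MAF qualifies.

    An absent frequency can only mean the variant is at most as common as a
    novel one, so None passes.
    """
    variants = list(variants)
    _check_panel(variants, panel)
    out = []
    for v in variants:
        f = v.maf.get(panel)
        if f is None or f <= maf_max:
            out.append(v)
    return out


def _as_intervals(regions):
    out = []
    for r in regions:
        if hasattr(r, "start_bp"):
            out.append((str(r.chromosome), int(r.start_bp), int(r.end_bp)))
        else:
            chrom, start, end = r
            out.append((str(chrom), int(start), int(end)))
    return out


def region_filter(variants, regions):
    """Variants inside any region (1-based inclusive on both ends)."""
    intervals = _as_intervals(regions)
    return [
        v
        for v in variants
        if any(
            str(v.chromosome) == chrom and start <= v.position_bp <= end
            for chrom, start, end in intervals
        )
    ]


def segregation_filter(variants, design: CohortDesign):
    """Variants carried by every affected sample and absent from unaffected.

    Affected: genotype must be het or hom-alt; missing disqualifies the
    variant (fail-closed). Unaffected: a non-reference genotype disqualifies;
    missing does not (absence cannot be asserted from a no-call).
    Unconfirmed samples are ignored.
    """
    variants = list(variants)
    for v in variants:
        absent = [s for s in design.all_samples if s not in v.genotypes]
        if absent:
            raise ConfigurationError(
                f"{v.key}: cohort samples missing from genotype mapping: {absent}"
            )
    out = []
    for v in variants:
        if any(v.genotypes[s] not in CARRIER_GENOTYPES for s in design.affected):
            continue
        if any(v.genotypes[s] in CARRIER_GENOTYPES for s in design.unaffected):
            continue
        out.append(v)
    return out


def _carried_counts(variants, samples):
    return {s: sum(1 for v in variants if v.carried_by(s)) for s in samples}


def run_cascade(
    variants,
    design: CohortDesign,
    regions,
    panel: str,
    maf_max: float = 0.02,
):
    """Run the full two-branch cascade.

    Returns ``(candidates, (novel_report, rare_report))`` where candidates
    is the union of both branches' survivors, each tagged with the branch(es)
    that admitted it, and the reports carry per-sample carried-variant counts
    at every stage.
    """
    variants = list(variants)
    samples = design.all_samples
    snvs, indels = functional_filter(variants)
    functional = snvs + indels

    reports = []
    survivors = {}
    for branch, rarity_stage, selected in (
        ("novel", STAGE_NOVEL, novelty_branch(functional)),
        ("rare", STAGE_RARE, rarity_branch(functional, panel, maf_max)),
    ):
        in_region = region_filter(selected, regions)
        shared = segregation_filter(in_region, design)
        stages = [STAGE_TOTAL, STAGE_FUNCTIONAL, rarity_stage, STAGE_REGION, STAGE_SHARED]
        counts = {
            STAGE_TOTAL: _carried_counts(variants, samples),
            STAGE_FUNCTIONAL: _carried_counts(functional, samples),
            rarity_stage: _carried_counts(selected, samples),
            STAGE_REGION: _carried_counts(in_region, samples),
            STAGE_SHARED: _carried_counts(shared, samples),
        }
        reports.append(CascadeReport(branch, stages, counts))
        for v in shared:
            survivors.setdefault(v.key, (v, []))[1].append(branch)

    candidates = [
        Candidate(v, tuple(branches)) for v, branches in survivors.values()
    ]
    return candidates, tuple(reports)


# ---------------------------------------------------------------------------
# I/O: VCF (genotypes) + annotation TSV


def write_variant_tables(variants, vcf_path, tsv_path, sample_order=None):
    """Write variants as a plain-text VCF 4.2 plus an annotation TSV.

    The TSV is keyed by chrom:pos:ref:alt and carries gene, func_class,
    dbsnp_id, kg_flag, maf_<panel> columns and the pass-through scores.
    """
    variants = list(variants)
    if sample_order is None:
        seen: dict[str, None] = {}
        for v in variants:
            for s in v.genotypes:
                seen.setdefault(s)
        sample_order = list(seen)
    gt_code = {GT_REF: "0/0", GT_HET: "0/1", GT_HOM: "1/1", GT_MISSING: "./."}

    lines = [
        "##fileformat=VCFv4.2",
        "##source=pedlink",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_order),
    ]
    for v in variants:
        gts = "\t".join(
            gt_code[v.genotypes.get(s, GT_MISSING)] for s in sample_order
        )
        lines.append(
            f"{v.chromosome}\t{v.position_bp}\t{v.dbsnp_id or '.'}\t{v.ref}\t"
            f"{v.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    panels = sorted({p for v in variants for p in v.maf})
    score_cols = sorted({s for v in variants for s in v.scores})
    rows = []
    for v in variants:
        row = {
            "variant_key": v.key,
            "gene": v.gene,
            "func_class": v.func_class,
            "dbsnp_id": v.dbsnp_id if v.dbsnp_id is not None else ".",
            "kg_flag": int(v.in_thousand_genomes),
        }
        for p in panels:
            row[f"maf_{p}"] = v.maf.get(p)
        for s in score_cols:
            row[s] = v.scores.get(s)
        rows.append(row)
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_variant_tables(vcf_path, tsv_path):
    """Read a VCF + annotation TSV pair back into AnnotatedVariant objects."""
    from cyvcf2 import VCF

    ann = pd.read_csv(tsv_path, sep="\t", dtype={"dbsnp_id": str})
    ann = ann.set_index("variant_key")

    panels = [c[4:] for c in ann.columns if c.startswith("maf_")]
    score_cols = [
        c
        for c in ann.columns
        if c not in {"gene", "func_class", "dbsnp_id", "kg_flag"}
        and not c.startswith("maf_")
    ]
    gt_name = {0: GT_REF, 1: GT_HET, 2: GT_MISSING, 3: GT_HOM}

    out = []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
        if key not in ann.index:
            raise ParameterError(f"variant {key} has no annotation row")
        row = ann.loc[key]
        maf = {}
        for p in panels:
            val = row[f"maf_{p}"]
            maf[p] = None if pd.isna(val) else float(val)
        dbsnp = row["dbsnp_id"]
        dbsnp = None if (pd.isna(dbsnp) or dbsnp == ".") else str(dbsnp)
        genotypes = {
            s: gt_name[int(t)] for s, t in zip(samples, rec.gt_types)
        }
        out.append(
            AnnotatedVariant(
                chromosome=str(rec.CHROM),
                position_bp=int(rec.POS),
                ref=rec.REF,
                alt=alt,
                gene=str(row["gene"]),
                func_class=str(row["func_class"]),
                dbsnp_id=dbsnp,
                in_thousand_genomes=bool(int(row["kg_flag"])),
                maf=maf,
                genotypes=genotypes,
                scores={
                    c: float(row[c]) for c in score_cols if not pd.isna(row[c])
                },
            )
        )
    vcf.close()
    return out
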