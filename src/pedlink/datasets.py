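"""Worked-example data from the motivating splenic epidermoid cyst study.

A three-generation family segregating splenic epidermoid cyst as a rare
dominant trait led, through linkage plus exome filtering, to a rare *HMCN1*
missense variant (R5205H); four unrelated cases from Kosovo were then
screened for novel or rare protein-affecting variants in the same gene.
These small tables reproduce that endpoint so the followup operations have
a concrete, hand-checkable example.

Physical positions of the *HMCN1* variants are representative coordinates
inside the gene body (hg19), not confirmed per-variant coordinates; they do
not affect any followup computation.
"""

from __future__ import annotations

from .followup import CARRIER, MISSING, NONCARRIER
from .pedigree import AFFECTED, UNAFFECTED, UNCONFIRMED
from .variants import GT_HET, GT_REF, AnnotatedVariant

__all__ = [
    "kosovo_replication_cohort",
    "family_r5205h_genotypes",
    "family_affection",
]

_KOSOVO_SAMPLES = ("Kos-1", "Kos-2", "Kos-3", "Kos-4")


def _kos_genotypes(carrier_sample):
    return {
        s: (GT_HET if s == carrier_sample else GT_REF) for s in _KOSOVO_SAMPLES
    }


def kosovo_replication_cohort():
    """Exome-derived *HMCN1* variants of the four unrelated Kosovo cases.

    Three of the four samples carry a very rare missense variant in
    *HMCN1* (A4704V, T5004I, H5244Q; European-panel MAF 0.001 / 0.008 /
    0.005); the fourth (Kos-1) carries only a common, catalogued variant
    that fails the novel-or-rare criterion. GERP / SIFT / PolyPhen-2 scores
    are pass-through annotations.

    Returns ``(variants, sample_ids)``.
    """
    variants = [
        AnnotatedVariant(
            chromosome="1",
            position_bp=185914000,
            ref="C",
            alt="T",
            gene="HMCN1",
            func_class="nonsynonymous_SNV",
            dbsnp_id="rs41317503",
            in_thousand_genomes=True,
            maf={"European": 0.001, "Japanese": None},
            genotypes=_kos_genotypes("Kos-4"),
            scores={"gerp": 5.47, "sift": 0.04, "polyphen2": 0.774},
        ),
        AnnotatedVariant(
            chromosome="1",
            position_bp=185947000,
            ref="C",
            alt="T",
            gene="HMCN1",
            func_class="nonsynonymous_SNV",
            dbsnp_id="rs114629728",
            in_thousand_genomes=True,
            maf={"European": 0.008, "Japanese": None},
            genotypes=_kos_genotypes("Kos-2"),
            scores={"gerp": 2.56, "sift": 0.29, "polyphen2": 0.175},
        ),
        AnnotatedVariant(
            chromosome="1",
            position_bp=186005000,
            ref="C",
            alt="G",
            gene="HMCN1",
            func_class="nonsynonymous_SNV",
            dbsnp_id="rs75161007",
            in_thousand_genomes=True,
            maf={"European": 0.005, "Japanese": None},
            genotypes=_kos_genotypes("Kos-3"),
            scores={"gerp": 0.69, "sift": 0.60, "polyphen2": 0.010},
        ),
        # common catalogued HMCN1 variant carried by Kos-1: fails novel-or-rare
        AnnotatedVariant(
            chromosome="1",
            position_bp=185890000,
            ref="G",
            alt="A",
            gene="HMCN1",
            func_class="nonsynonymous_SNV",
            dbsnp_id="rs2787336",
            in_thousand_genomes=True,
            maf={"European": 0.31, "Japanese": 0.27},
            genotypes=_kos_genotypes("Kos-1"),
            scores={},
        ),
    ]
    return variants, list(_KOSOVO_SAMPLES)


def family_r5205h_genotypes():
    """Confirmatory (Sanger-style) R5205H carrier calls across the family.

    The variant co-segregates with affection except for two unaffected
    heterozygous carriers, III:3 (father of the affected child IV:6) and
    III:4 — the pattern expected under incomplete penetrance. IV:1's
    genotype is recorded as missing: it is known to be exceptional but its
    carrier state is not recoverable from the published account, so it is
    deliberately left untyped here.
    """
    return {
        "II:1": NONCARRIER,
        "II:2": CARRIER,
        "II:3": NONCARRIER,
        "II:4": NONCARRIER,
        "II:5": NONCARRIER,
        "II:6": CARRIER,
        "III:1": NONCARRIER,
        "III:2": CARRIER,
        "III:3": CARRIER,
        "III:4": CARRIER,
        "III:5": NONCARRIER,
        "IV:1": MISSING,
        "IV:2": NONCARRIER,
        "IV:3": CARRIER,
        "IV:4": CARRIER,
        "IV:5": NONCARRIER,
        "IV:6": CARRIER,
    }


def family_affection():
    """Affection statuses of the seventeen family members.

    Six affected; II:1, II:3 and II:5 are unconfirmed (clinical examination
    only), which collapses to unknown in every computation.
    """
    return {
        "II:1": UNCONFIRMED,
        "II:2": AFFECTED,
        "II:3": UNCONFIRMED,
        "II:4": UNAFFECTED,
        "II:5": UNCONFIRMED,
        "II:6": AFFECTED,
        "III:1": UNAFFECTED,
        "III:2": AFFECTED,
        "III:3": UNAFFECTED,
        "III:4": UNAFFECTED,
        "III:5": UNAFFECTED,
        "IV:1": UNAFFECTED,
        "IV:2": UNAFFECTED,
        "IV:3": AFFECTED,
        "IV:4": AFFECTED,
        "IV:5": UNAFFECTED,
        "IV:6": AFFECTED,
    }
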