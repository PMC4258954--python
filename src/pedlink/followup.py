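"""Post-cascade evidence: family co-segregation and gene-level replication.

After the cascade names candidate variants, two further checks are applied:

* **Co-segregation** across the whole family using confirmatory
  (Sanger-style) carrier genotypes. Under a fully penetrant dominant model
  carrier status and affection should coincide; *strict* mode flags every
  exception, while ``allow_unaffected_carriers`` mode tolerates unaffected
  carriers as expected under incomplete penetrance and flags only affected
  non-carriers (phenocopy candidates aside).

* **Replication** in unrelated cases: a candidate gene gains support from
  each unrelated sample carrying at least one qualifying (novel or rare,
  protein-affecting) variant anywhere in the same gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .exceptions import ParameterError
from .pedigree import AFFECTED, UNAFFECTED
from .variants import FUNCTIONAL_SNV_CLASSES, rarity_branch

__all__ = [
    "CARRIER",
    "NONCARRIER",
    "MISSING",
    "CosegregationResult",
    "GeneReplicationResult",
    "cosegregation",
    "replicate_genes",
    "read_carrier_tsv",
    "DEFAULT_REPLICATION_CLASSES",
]

CARRIER = "carrier"
NONCARRIER = "noncarrier"
MISSING = "missing"
_CARRIER_STATES = {CARRIER, NONCARRIER, MISSING}

STRICT = "strict"
LENIENT = "allow_unaffected_carriers"

DEFAULT_REPLICATION_CLASSES = frozenset(FUNCTIONAL_SNV_CLASSES | {"frameshift_indel"})


@dataclass
class CosegregationResult:
    """Partition of family members by concordance with a dominant variant."""

    variant_id: str
    concordant: list = field(default_factory=list)
    discordant: dict = field(default_factory=dict)  # id -> tag
    untyped: list = field(default_factory=list)

    @property
    def unaffected_carriers(self):
        return sorted(
            m for m, tag in self.discordant.items() if tag == "unaffected_carrier"
        )

    @property
    def affected_noncarriers(self):
        return sorted(
            m for m, tag in self.discordant.items() if tag == "affected_noncarrier"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant_id": self.variant_id,
                "concordant": sorted(self.concordant),
                "discordant": dict(sorted(self.discordant.items())),
                "untyped": sorted(self.untyped),
            },
            indent=2,
        )


def cosegregation(genotypes, affection, mode=STRICT, variant_id=""):
    """Classify family members by carrier/affection concordance.

    Parameters
    ----------
    genotypes : mapping member_id -> {carrier, noncarrier, missing}
        Confirmatory genotypes (e.g. Sanger calls) for one variant.
    affection : mapping member_id -> affection status
        Statuses as in the pedigree module; unconfirmed collapses to
        unknown. Members with affection but no genotype entry are untyped.
    mode : {"strict", "allow_unaffected_carriers"}
        Strict flags both unaffected carriers and affected non-carriers;
        the lenient mode treats unaffected carriers as concordant-enough
        under incomplete penetrance and flags only affected non-carriers.

    The member universe is the union of both mappings; the concordant /
    discordant / untyped sets partition it.
    """
    if mode not in (STRICT, LENIENT):
        raise ParameterError(f"unknown cosegregation mode {mode!r}")
    result = CosegregationResult(variant_id)
    members = sorted(set(genotypes) | set(affection))
    for m in members:
        g = genotypes.get(m, MISSING)
        if g not in _CARRIER_STATES:
            raise ParameterError(f"member {m}: bad carrier state {g!r}")
        if g == MISSING:
            result.untyped.append(m)
            continue
        status = affection.get(m, "unknown")
        if status == "unconfirmed":
            status = "unknown"
        if status == AFFECTED and g == NONCARRIER:
            result.discordant[m] = "affected_noncarrier"
        elif status == UNAFFECTED and g == CARRIER and mode == STRICT:
            result.discordant[m] = "unaffected_carrier"
        else:
            result.concordant.append(m)
    return result


def read_carrier_tsv(source):
    """Read confirmatory genotypes from TSV rows (member_id, variant_id, status).

    Returns ``{variant_id: {member_id: status}}`` with statuses in
    {carrier, noncarrier, missing}, ready for :func:`cosegregation`.
    """
    from .pedigree import _as_lines

    out: dict[str, dict[str, str]] = {}
    for lineno, ln in enumerate(_as_lines(source), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 3:
            raise ParameterError(
                f"line {lineno}: carrier TSV expects member_id, variant_id, status"
            )
        member, variant, status = parts
        if status not in _CARRIER_STATES:
            raise ParameterError(f"line {lineno}: bad carrier status {status!r}")
        out.setdefault(variant, {})[member] = status
    return out


@dataclass
class GeneReplicationResult:
    """Per-gene support among unrelated samples.

    ``support`` maps gene -> {sample -> [qualifying variant keys]}; a
    sample counts once per gene however many qualifying variants it
    carries.
    """

    support: dict = field(default_factory=dict)

    def samples_for(self, gene: str):
        return sorted(self.support.get(gene, {}))

    def support_count(self, gene: str) -> int:
        return len(self.support.get(gene, {}))

    def to_json(self) -> str:
        return json.dumps(self.support, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = []
        for gene in sorted(self.support):
            carriers = self.support[gene]
            lines.append(f"{gene}: supported by {len(carriers)} sample(s)")
            for sample in sorted(carriers):
                lines.append(f"  {sample}: " + ", ".join(carriers[sample]))
        return "\n".join(lines) if lines else "(no replication support)"


def replicate_genes(
    cohort_variants,
    candidate_genes,
    panel: str,
    maf_max: float = 0.02,
    classes=DEFAULT_REPLICATION_CLASSES,
) -> GeneReplicationResult:
    """Gene-level replication in an unrelated cohort.

    For each candidate gene, collects every cohort sample that carries at
    least one variant in the gene passing the class filter and the
    novel-or-rare criterion (novelty always qualifies; otherwise panel MAF
    <= maf_max). Support is counted in samples, not variants.
    """
    genes = set(candidate_genes)
    in_genes = [v for v in cohort_variants if v.gene in genes]
    by_class = [v for v in in_genes if v.func_class in classes]
    qualifying = set(
        v.key for v in rarity_branch(by_class, panel, maf_max)
    ) | {v.key for v in by_class if v.is_novel}

    result = GeneReplicationResult()
    for v in by_class:
        if v.key not in qualifying:
            continue
        for sample, g in v.genotypes.items():
            if v.carried_by(sample):
                result.support.setdefault(v.gene, {}).setdefault(sample, []).append(
                    v.key
                )
    return result
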