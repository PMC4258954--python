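"""Seeded generators emulating the study's inputs.

Two generators:

* :func:`gene_drop` — forward simulation of SNP genotypes through a
  pedigree: founders draw haplotypes from marker allele frequencies and a
  causal disease allele with frequency q; meioses recombine between
  adjacent loci with the Haldane probability for their cM distance;
  affection is sampled from the penetrance triple given each member's
  causal genotype. Families are ascertained the way a clinical linkage
  study finds them: draws are rejected until the family is "loaded"
  (enough affected, spread over the generations), which is how a rare
  dominant pedigree comes to attention at all.

* :func:`make_variant_tables` — exome-style annotated variant tables:
  background variants with a realistic novelty/MAF/class mix plus exactly
  one planted causal variant that survives the prioritization cascade for
  the family design, and qualifying variants seeded into a configurable
  number of unrelated replication samples.

Identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .linkage import DiseaseModel
from ._engine import haldane_theta
from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    UNCONFIRMED,
    UNKNOWN,
    GenotypeMatrix,
    Individual,
    Marker,
    Pedigree,
    write_affection_sidecar,
    write_ped_map,
)
from .variants import (
    GT_HET,
    GT_HOM,
    GT_MISSING,
    GT_REF,
    AnnotatedVariant,
    CohortDesign,
)

__all__ = [
    "ChromosomeSpec",
    "SimulationConfig",
    "VariantTableConfig",
    "GeneDropResult",
    "VariantTablesResult",
    "study_template_pedigree",
    "default_family_design",
    "gene_drop",
    "make_variant_tables",
    "load_simulation_config",
    "DEFAULT_TYPED_IDS",
    "EXOME_SUBSET_IDS",
]

# the twelve SNP-typed members of the study family
DEFAULT_TYPED_IDS = (
    "II:1", "II:2", "II:4", "II:6", "III:1", "III:2", "III:3",
    "IV:2", "IV:3", "IV:4", "IV:5", "IV:6",
)
# the eight family members that were exome sequenced
EXOME_SUBSET_IDS = ("II:1", "II:2", "II:3", "II:5", "III:1", "III:2", "IV:3", "IV:4")

# the study family's observed affection pattern over the typed members
# (clinical-examination-only statuses are unconfirmed, i.e. unknown in all
# likelihoods and in phenotype conditioning)
STUDY_AFFECTION_TEMPLATE = {
    "II:1": UNCONFIRMED,
    "II:2": AFFECTED,
    "II:4": UNAFFECTED,
    "II:6": AFFECTED,
    "III:1": UNAFFECTED,
    "III:2": AFFECTED,
    "III:3": UNAFFECTED,
    "IV:2": UNAFFECTED,
    "IV:3": AFFECTED,
    "IV:4": AFFECTED,
    "IV:5": UNAFFECTED,
    "IV:6": AFFECTED,
}


def study_template_pedigree(affection: dict | None = None) -> Pedigree:
    """Default study-family template: 17 members over generations II-IV.

    The generation-II sibship (II:2, II:4, II:6 — the blood line) shares an
    unobserved, untyped ancestral couple I:1 x I:2, included so a single
    founder haplotype can reach every affected branch: III:2 (father of the
    proband IV:3), III:3 (who can be an unaffected carrier whose child IV:6
    is affected), and II:6 herself. The other generation-II members married
    in; the twelve typed members are those in :data:`DEFAULT_TYPED_IDS`
    (5 males / 12 females among the seventeen study members). Spouse
    assignments not recoverable from the published account are filled in
    plausibly; pass your own Pedigree to :class:`SimulationConfig` to
    change the topology.

    Affection statuses default to unknown (the simulator samples them).
    """
    rows = [
        # id, father, mother, sex
        ("I:1", None, None, MALE),
        ("I:2", None, None, FEMALE),
        ("II:1", None, None, MALE),
        ("II:2", "I:1", "I:2", FEMALE),
        ("II:3", None, None, MALE),
        ("II:4", "I:1", "I:2", FEMALE),
        ("II:5", None, None, MALE),
        ("II:6", "I:1", "I:2", FEMALE),
        ("III:1", None, None, FEMALE),
        ("III:2", "II:1", "II:2", MALE),
        ("III:3", "II:3", "II:4", MALE),
        ("III:4", None, None, FEMALE),
        ("III:5", "II:5", "II:6", FEMALE),
        ("IV:1", "III:2", "III:1", FEMALE),
        ("IV:2", "III:2", "III:1", FEMALE),
        ("IV:3", "III:2", "III:1", FEMALE),
        ("IV:4", "III:2", "III:1", FEMALE),
        ("IV:5", "III:3", "III:4", FEMALE),
        ("IV:6", "III:3", "III:4", FEMALE),
    ]
    affection = affection or {}
    return Pedigree(
        Individual(i, f, m, sex=s, affection=affection.get(i, "unknown"))
        for i, f, m, s in rows
    )


def default_family_design() -> CohortDesign:
    """Exome cohort design of the study family (four affected of eight)."""
    return CohortDesign(
        affected=("II:2", "III:2", "IV:3", "IV:4"),
        unaffected=("III:1",),
        unconfirmed=("II:1", "II:3", "II:5"),
    )


@dataclass(frozen=True)
class ChromosomeSpec:
    """A simulated chromosome: evenly spaced biallelic markers.

    Marker minor allele frequencies are drawn uniformly from ``maf_range``
    (array-like common SNPs). Physical coordinates follow ``bp_per_cm``.
    """

    name: str
    n_markers: int = 300
    spacing_cm: float = 0.5
    start_bp: int = 1_000_000
    bp_per_cm: int = 1_000_000
    maf_range: tuple = (0.1, 0.5)

    @property
    def length_cm(self) -> float:
        return (self.n_markers - 1) * self.spacing_cm

    def cm_to_bp(self, cm: float) -> int:
        return int(round(self.start_bp + cm * self.bp_per_cm))


@dataclass
class SimulationConfig:
    """Study-shaped gene-dropping configuration.

    Defaults are the study's conditions: the 17-member three-generation
    template with 12 typed members, the rare-dominant disease model
    (q = 0.005, penetrances 0.005/0.95/0.95), a two-chromosome map of 300
    markers at 0.5 cM spacing each, and the causal locus mid-chromosome 1.

    Phenotypes are sampled from the penetrances given each member's causal
    genotype, with ascertainment rejection emulating how a family in which
    dominant inheritance looks conceivable reaches a linkage study: at
    least ``min_affected_typed`` typed members affected, spanning
    ``min_affected_generations`` generations, none of them married-in
    spouses (``require_affected_nonfounders``), and with affecteds in at
    least ``min_affected_last_gen_sibships`` distinct sibships of the last
    generation — all properties the study family's pedigree shows. Set
    ``min_affected_typed=None`` for unascertained draws.

    Alternatively ``affection_template`` fixes the affection pattern
    outright (``"study"`` = the family's published pattern) and draws the
    causal-locus descent from its exact posterior given those phenotypes
    (SLINK-style phenotype-conditional simulation).
    """

    pedigree: Pedigree | None = None
    typed_ids: tuple | None = None
    chromosomes: tuple = (
        ChromosomeSpec("1"),
        ChromosomeSpec("14", start_bp=2_000_000),
    )
    causal_chromosome: str = "1"
    causal_cm: float = 75.0
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    missing_rate: float = 0.01
    affection_template: dict | str | None = None
    min_affected_typed: int | None = 6
    min_affected_generations: int | None = 3
    require_affected_nonfounders: bool = True
    min_affected_last_gen_sibships: int | None = 2
    require_dominant_chains: bool = True
    max_tries: int = 500_000
    seed: int = 0

    def resolve_pedigree(self):
        ped = self.pedigree if self.pedigree is not None else study_template_pedigree()
        typed = self.typed_ids
        if typed is None:
            typed = DEFAULT_TYPED_IDS if self.pedigree is None else tuple(ped.ids)
        return ped, tuple(typed)

    def resolve_affection_template(self):
        if self.affection_template == "study":
            return dict(STUDY_AFFECTION_TEMPLATE) if self.pedigree is None else None
        return self.affection_template


@dataclass
class GeneDropResult:
    """Output of one gene drop, plus simulation-truth metadata.

    ``pedigree`` carries the *recorded* affection (typed members get their
    true status, untyped members are recorded as unconfirmed, mirroring
    clinical-exam-only statuses); ``true_affection`` keeps the sampled
    truth for every member. ``causal_copies`` is each member's number of
    disease alleles; ``transmission_bits`` maps chromosome ->
    (n_meioses, n_markers) 0/1 array of simulated meiosis outcomes (useful
    for recombination checks).
    """

    pedigree: Pedigree
    markers: list
    genotypes: GenotypeMatrix
    true_affection: dict
    causal_copies: dict
    causal_chromosome: str
    causal_cm: float
    causal_bp: int
    transmission_bits: dict
    n_tries: int
    seed: int
    config: SimulationConfig

    @property
    def affection_recorded(self) -> dict:
        return {ind.id: ind.affection for ind in self.pedigree}

    def write(self, directory):
        """Write PED/MAP + affection sidecar (seed noted in headers)."""
        os.makedirs(directory, exist_ok=True)
        ped_text, map_text = write_ped_map(self.pedigree, self.markers, self.genotypes)
        header = f"# pedlink gene_drop seed={self.seed}\n"
        for name, text in (
            ("family.ped", ped_text),
            ("family.map", map_text),
            ("affection.tsv", write_affection_sidecar(self.affection_recorded)),
        ):
            with open(os.path.join(directory, name), "w") as fh:
                fh.write(header + text)


def _generation_depths(ped: Pedigree) -> dict:
    depth = {}
    for iid in ped.topological_ids():
        ind = ped[iid]
        if ind.is_founder:
            depth[iid] = 0
        else:
            depth[iid] = max(depth[ind.father_id], depth[ind.mother_id]) + 1
    return depth


def gene_drop(config: SimulationConfig, seed: int | None = None) -> GeneDropResult:
    """Simulate genotypes, causal-locus inheritance and affection statuses.

    The causal locus and affection are drawn first (with rejection until
    the ascertainment condition holds); marker haplotypes are then dropped
    *conditional on* the accepted causal-locus inheritance pattern by
    extending the meiosis indicators outward along each chromosome with
    Haldane flip probabilities, so markers near the causal locus stay in
    linkage with it. Missingness is applied last; untyped members are
    emitted fully missing with recorded status 'unconfirmed'.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    used_seed = config.seed if seed is None else seed
    ped, typed_ids = config.resolve_pedigree()
    typed_set = set(typed_ids)
    unknown_typed = typed_set - set(ped.ids)
    if unknown_typed:
        raise ConfigurationError(f"typed ids not in pedigree: {sorted(unknown_typed)}")

    chrom_by_name = {c.name: c for c in config.chromosomes}
    causal = chrom_by_name.get(config.causal_chromosome)
    if causal is None or not 0.0 <= config.causal_cm <= causal.length_cm:
        raise ConfigurationError(
            f"causal locus {config.causal_chromosome}@{config.causal_cm} cM "
            "is off the simulated map"
        )

    founders = ped.founders
    nonfounders = ped.nonfounders
    n_f = len(founders)
    b = 2 * len(nonfounders)
    dm = config.disease_model
    pen = np.array(dm.penetrances)

    row = {ind.id: i for i, ind in enumerate(ped.individuals)}
    f_index = {f.id: k for k, f in enumerate(founders)}
    nf_index = {ind.id: k for k, ind in enumerate(nonfounders)}
    topo = ped.topological_ids()
    depths = _generation_depths(ped)
    n_generations = max(depths.values()) + 1 if depths else 1

    # marker maps and MAFs are fixed before the ascertainment loop
    markers: list[Marker] = []
    chrom_markers: dict[str, list[int]] = {}
    for spec in config.chromosomes:
        mafs = rng.uniform(*spec.maf_range, size=spec.n_markers)
        idxs = []
        for j in range(spec.n_markers):
            cm = j * spec.spacing_cm
            markers.append(
                Marker(
                    id=f"rs{spec.name}_{j:05d}",
                    chromosome=spec.name,
                    position_bp=spec.cm_to_bp(cm),
                    position_cm=cm,
                    founder_freqs=(float(mafs[j]), float(1.0 - mafs[j])),
                )
            )
            idxs.append(len(markers) - 1)
        chrom_markers[spec.name] = idxs

    def drop_locus(founder_alleles, bits):
        """Propagate one locus through the pedigree given meiosis bits."""
        pat = np.empty(len(ped.individuals), dtype=founder_alleles.dtype)
        mat = np.empty_like(pat)
        for iid in topo:
            i = row[iid]
            ind = ped[iid]
            if ind.is_founder:
                k = f_index[iid]
                pat[i] = founder_alleles[k, 0]
                mat[i] = founder_alleles[k, 1]
            else:
                k = nf_index[iid]
                fa, mo = row[ind.father_id], row[ind.mother_id]
                pat[i] = pat[fa] if bits[2 * k] == 0 else mat[fa]
                mat[i] = pat[mo] if bits[2 * k + 1] == 0 else mat[mo]
        return pat, mat

    # --- causal locus and affection ---
    template = config.resolve_affection_template()
    if template is not None:
        founder_disease, v0 = _conditional_disease_drop(rng, ped, template, dm)
        n_tries = 1
        dpat, dmat = drop_locus(founder_disease, v0)
        copies = dpat + dmat
        sampled = rng.random(len(ped.individuals)) < pen[copies]
        affected = np.empty(len(ped.individuals), dtype=bool)
        for i, ind in enumerate(ped.individuals):
            status = template.get(ind.id, UNKNOWN)
            if status == AFFECTED:
                affected[i] = True
            elif status == UNAFFECTED:
                affected[i] = False
            else:  # unknown / unconfirmed: sampled from the penetrances
                affected[i] = sampled[i]
    else:
        n_tries = 0
        while True:
            n_tries += 1
            if n_tries > config.max_tries:
                raise ConfigurationError(
                    f"ascertainment not satisfied within {config.max_tries} "
                    "draws; relax min_affected_typed or the generation "
                    "requirement"
                )
            founder_disease = (rng.random((n_f, 2)) < dm.q).astype(np.int8)
            v0 = rng.integers(0, 2, size=b).astype(np.int8)
            dpat, dmat = drop_locus(founder_disease, v0)
            copies = dpat + dmat
            affected = rng.random(len(ped.individuals)) < pen[copies]
            if config.min_affected_typed is None:
                break
            aff_typed = [
                ind.id for ind in ped.individuals
                if ind.id in typed_set and affected[row[ind.id]]
            ]
            if len(aff_typed) < config.min_affected_typed:
                continue
            if config.min_affected_generations is not None:
                need = min(config.min_affected_generations, n_generations)
                if len({depths[i] for i in aff_typed}) < need:
                    continue
            if config.require_affected_nonfounders and any(
                ped[i].is_founder for i in aff_typed
            ):
                continue
            if config.min_affected_last_gen_sibships is not None:
                last = n_generations - 1
                sibships = {
                    (ped[i].father_id, ped[i].mother_id)
                    for i in aff_typed
                    if depths[i] == last
                }
                if len(sibships) < config.min_affected_last_gen_sibships:
                    continue
            if config.require_dominant_chains:
                # visibly unbroken dominant transmission: every affected
                # typed member has an affected parent, unless its parents
                # are unobserved ancestors (untyped, unknown-status leaves
                # of the recorded pedigree)
                ok = True
                for i in aff_typed:
                    ind = ped[i]
                    if ind.is_founder:
                        continue
                    fa, mo = row[ind.father_id], row[ind.mother_id]
                    if affected[fa] or affected[mo]:
                        continue
                    if (
                        ind.father_id not in typed_set
                        and ind.mother_id not in typed_set
                        and ped[ind.father_id].is_founder
                        and ped[ind.mother_id].is_founder
                    ):
                        continue  # ancestral couple not observable
                    ok = False
                    break
                if not ok:
                    continue
            break

    # --- marker haplotypes conditional on the accepted causal inheritance ---
    transmission_bits: dict[str, np.ndarray] = {}
    n_ind = len(ped.individuals)
    n_markers = len(markers)
    pat_all = np.empty((n_ind, n_markers), dtype=np.int8)
    mat_all = np.empty((n_ind, n_markers), dtype=np.int8)
    for spec in config.chromosomes:
        idxs = chrom_markers[spec.name]
        cms = np.array([markers[j].position_cm for j in idxs])
        L = len(idxs)
        B = np.empty((b, L), dtype=np.int8) if b else np.zeros((0, L), dtype=np.int8)
        if b:
            if spec.name == config.causal_chromosome:
                anchor_cm = config.causal_cm
                anchor = v0
            else:
                anchor_cm = cms[0]
                anchor = rng.integers(0, 2, size=b).astype(np.int8)
            right = np.flatnonzero(cms >= anchor_cm)
            left = np.flatnonzero(cms < anchor_cm)[::-1]  # walk outward
            prev, prev_cm = anchor, anchor_cm
            for j in right:
                theta = haldane_theta(cms[j] - prev_cm)
                flip = (rng.random(b) < theta).astype(np.int8)
                B[:, j] = prev ^ flip
                prev, prev_cm = B[:, j], cms[j]
            prev, prev_cm = anchor, anchor_cm
            for j in left:
                theta = haldane_theta(prev_cm - cms[j])
                flip = (rng.random(b) < theta).astype(np.int8)
                B[:, j] = prev ^ flip
                prev, prev_cm = B[:, j], cms[j]
        transmission_bits[spec.name] = B

        freqs1 = np.array([markers[j].founder_freqs[0] for j in idxs])
        founder_alleles = np.where(
            rng.random((n_f, 2, L)) < freqs1[None, None, :], 1, 2
        ).astype(np.int8)

        # vectorized descent over this chromosome's markers
        for iid in topo:
            i = row[iid]
            ind = ped[iid]
            if ind.is_founder:
                k = f_index[iid]
                pat_all[i, idxs] = founder_alleles[k, 0]
                mat_all[i, idxs] = founder_alleles[k, 1]
            else:
                k = nf_index[iid]
                fa, mo = row[ind.father_id], row[ind.mother_id]
                pbits = B[2 * k]
                mbits = B[2 * k + 1]
                pat_all[i, idxs] = np.where(
                    pbits == 0, pat_all[fa, idxs], mat_all[fa, idxs]
                )
                mat_all[i, idxs] = np.where(
                    mbits == 0, pat_all[mo, idxs], mat_all[mo, idxs]
                )

    codes = np.stack(
        [np.minimum(pat_all, mat_all), np.maximum(pat_all, mat_all)], axis=2
    )
    # missingness, then blank untyped members entirely
    if config.missing_rate > 0:
        miss = rng.random((n_ind, n_markers)) < config.missing_rate
        codes[miss] = 0
    for ind in ped.individuals:
        if ind.id not in typed_set:
            codes[row[ind.id]] = 0

    true_affection = {
        ind.id: (AFFECTED if affected[row[ind.id]] else UNAFFECTED)
        for ind in ped.individuals
    }
    recorded = {}
    for iid, status in true_affection.items():
        if iid not in typed_set:
            recorded[iid] = UNCONFIRMED
        elif template is not None and iid in template:
            recorded[iid] = template[iid]
        else:
            recorded[iid] = status
    out_ped = ped.with_affection(recorded)
    genotypes = GenotypeMatrix(out_ped.ids, [m.id for m in markers], codes)
    return GeneDropResult(
        pedigree=out_ped,
        markers=markers,
        genotypes=genotypes,
        true_affection=true_affection,
        causal_copies={ind.id: int(copies[row[ind.id]]) for ind in ped.individuals},
        causal_chromosome=config.causal_chromosome,
        causal_cm=config.causal_cm,
        causal_bp=causal.cm_to_bp(config.causal_cm),
        transmission_bits=transmission_bits,
        n_tries=n_tries,
        seed=used_seed,
        config=config,
    )


def load_simulation_config(source) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a JSON file or JSON text.

    Recognized keys mirror the dataclass fields; ``chromosomes`` is a list
    of ChromosomeSpec field mappings and ``disease_model`` a mapping with
    q/f_AA/f_Aa/f_aa. The pedigree itself cannot be expressed in the config
    (supply PED text via the pedigree module instead); the default study
    template is used.
    """
    import json

    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            data = json.load(fh)
    elif isinstance(source, str):
        data = json.loads(source)
    else:
        data = json.load(source)
    kwargs = dict(data)
    if "chromosomes" in kwargs:
        kwargs["chromosomes"] = tuple(
            ChromosomeSpec(**c) for c in kwargs["chromosomes"]
        )
    if "disease_model" in kwargs:
        kwargs["disease_model"] = DiseaseModel(**kwargs["disease_model"])
    allowed = set(SimulationConfig.__dataclass_fields__)
    unknown = set(kwargs) - allowed
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)


def _conditional_disease_drop(rng, ped, template, dm):
    """Sample (founder disease alleles, causal meiosis bits) given phenotypes.

    Exact posterior sampling: the inheritance vector at the causal locus is
    drawn with probability proportional to the phenotype likelihood
    P(affection | v) on the founder-symmetry quotient of the
    phenotype-informative subpedigree, founder phases are restored by
    uniform orbit toggles, founder disease alleles are then drawn from
    their conditional distribution component by component, and everything
    outside the informative subpedigree reverts to its prior.
    """
    from . import _engine
    from .linkage import (
        _phenotype_factors,
        disease_likelihood_vector,
        prune_uninformative,
    )

    statuses = {ind.id: UNKNOWN for ind in ped}
    statuses.update({k: v for k, v in template.items() if k in statuses})
    cond = prune_uninformative(ped.with_affection(statuses))
    coord_bits, _sym, dl = disease_likelihood_vector(cond, dm)
    total = dl.sum()
    if total <= 0:
        raise ConfigurationError(
            "affection template has zero likelihood under the disease model"
        )
    idx = int(rng.choice(dl.size, p=dl / total))
    v_cond = 0
    for j, bit in enumerate(coord_bits):
        v_cond |= ((idx >> j) & 1) << bit

    # uniform founder-phase toggles restore the full orbit
    founder_ids = {f.id for f in cond.founders}
    by_founder: dict[str, list[int]] = {}
    for i, ind in enumerate(cond.nonfounders):
        for bit, parent in ((2 * i, ind.father_id), (2 * i + 1, ind.mother_id)):
            if parent in founder_ids:
                by_founder.setdefault(parent, []).append(bit)
    for bits in by_founder.values():
        if rng.random() < 0.5:
            for bit in bits:
                v_cond ^= 1 << bit

    # founder disease alleles | v_cond, phenotypes (per slot component)
    slot_pat, slot_mat, _ = _engine.compute_slots(cond, np.array([v_cond]))
    rows, factors = _phenotype_factors(cond, dm)
    n_slots = 2 * len(cond.founders)
    pairs = [(int(slot_pat[r, 0]), int(slot_mat[r, 0])) for r in rows]

    parent = list(range(n_slots))

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for s1, s2 in pairs:
        r1, r2 = find(s1), find(s2)
        if r1 != r2:
            parent[r2] = r1
    comp: dict[int, set] = {}
    for s1, s2 in pairs:
        comp.setdefault(find(s1), set()).update((s1, s2))

    alleles = np.full(n_slots, -1, dtype=np.int8)
    for root, slots in comp.items():
        slots = sorted(slots)
        loc = {s: j for j, s in enumerate(slots)}
        k = len(slots)
        tbl = (np.arange(1 << k)[:, None] >> np.arange(k)) & 1
        w = np.prod(np.where(tbl == 1, dm.q, 1.0 - dm.q), axis=1)
        for (s1, s2), f in zip(pairs, factors):
            if find(s1) == root:
                w = w * f[tbl[:, loc[s1]] + tbl[:, loc[s2]]]
        pick = tbl[int(rng.choice(w.size, p=w / w.sum()))]
        for s, j in loc.items():
            alleles[s] = pick[j]
    free = alleles < 0
    alleles[free] = (rng.random(int(free.sum())) < dm.q).astype(np.int8)

    # map back onto the full pedigree; everything unconstrained is prior
    cond_f = {f.id: k for k, f in enumerate(cond.founders)}
    founder_disease = np.empty((len(ped.founders), 2), dtype=np.int8)
    for k, f in enumerate(ped.founders):
        if f.id in cond_f:
            kk = cond_f[f.id]
            founder_disease[k, 0] = alleles[2 * kk]
            founder_disease[k, 1] = alleles[2 * kk + 1]
        else:
            founder_disease[k] = (rng.random(2) < dm.q).astype(np.int8)
    bit_val = {}
    for i, ind in enumerate(cond.nonfounders):
        bit_val[(ind.id, 0)] = (v_cond >> (2 * i)) & 1
        bit_val[(ind.id, 1)] = (v_cond >> (2 * i + 1)) & 1
    v0 = np.empty(2 * len(ped.nonfounders), dtype=np.int8)
    for i, ind in enumerate(ped.nonfounders):
        for which in (0, 1):
            v0[2 * i + which] = bit_val.get(
                (ind.id, which), int(rng.integers(0, 2))
            )
    return founder_disease, v0


# ---------------------------------------------------------------------------
# exome-style variant tables

_DEFAULT_CLASS_MIX = (
    ("synonymous_SNV", 0.45),
    ("nonsynonymous_SNV", 0.40),
    ("splicing", 0.01),
    ("stopgain", 0.01),
    ("stoploss", 0.005),
    ("frameshift_indel", 0.015),
    ("nonframeshift_indel", 0.02),
    ("other", 0.09),
)

_BASES = ("A", "C", "G", "T")


@dataclass
class VariantTableConfig:
    """Configuration of the exome-table generator.

    The background mix approximates exome proportions: ~5% of variants are
    novel (absent from dbSNP/1000 Genomes); among catalogued variants ~4%
    are rare (panel MAF <= maf_max). The planted causal variant satisfies
    its branch's predicates by construction; background variants that
    would accidentally survive the cascade have one affected genotype
    reset so the plant is the unique survivor.
    """

    n_background: int = 1000
    frac_novel: float = 0.05
    frac_rare_known: float = 0.04
    class_mix: tuple = _DEFAULT_CLASS_MIX
    panels: tuple = ("Japanese", "European")
    panel: str = "Japanese"
    maf_max: float = 0.02
    design: CohortDesign = field(default_factory=default_family_design)
    genotype_missing_rate: float = 0.005
    background_chromosomes: tuple = (("1", 249_000_000), ("2", 243_000_000),
                                     ("14", 107_000_000), ("19", 59_000_000))
    plant: bool = True
    planted_gene: str = "HMCN1"
    planted_class: str = "nonsynonymous_SNV"
    planted_branch: str = "rare"  # or "novel"
    planted_maf: float | None = None
    planted_dbsnp_id: str | None = None
    planted_position: tuple | None = None  # (chromosome, bp)
    unrelated_samples: tuple = ("Kos-1", "Kos-2", "Kos-3", "Kos-4")
    n_replicating: int = 3
    seed: int = 0


@dataclass
class VariantTablesResult:
    """Family and unrelated-cohort variant tables plus generation metadata."""

    family: list
    unrelated: list
    planted: AnnotatedVariant | None
    unrelated_planted: list
    design: CohortDesign
    alt_freqs: dict  # variant key -> generating alt-allele frequency (family)
    seed: int

    def write(self, directory):
        from .variants import write_variant_tables

        os.makedirs(directory, exist_ok=True)
        write_variant_tables(
            self.family,
            os.path.join(directory, "family.vcf"),
            os.path.join(directory, "family_annotation.tsv"),
            sample_order=list(self.design.all_samples),
        )
        if self.unrelated:
            write_variant_tables(
                self.unrelated,
                os.path.join(directory, "unrelated.vcf"),
                os.path.join(directory, "unrelated_annotation.tsv"),
            )


def _hw_genotype(rng, f, missing_rate):
    u = rng.random()
    if u < missing_rate:
        return GT_MISSING
    u = rng.random()
    if u < f * f:
        return GT_HOM
    if u < f * f + 2 * f * (1 - f):
        return GT_HET
    return GT_REF


def _background_variant(rng, cfg: VariantTableConfig, samples, used_keys, alt_freqs):
    classes, probs = zip(*cfg.class_mix)
    chrom_names = [c for c, _ in cfg.background_chromosomes]
    chrom_lens = np.array([ln for _, ln in cfg.background_chromosomes], dtype=float)
    chrom_w = chrom_lens / chrom_lens.sum()

    while True:
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_w)]
        length = dict(cfg.background_chromosomes)[chrom]
        pos = int(rng.integers(1, length))
        func_class = classes[rng.choice(len(classes), p=np.array(probs))]
        ref = _BASES[rng.integers(4)]
        if func_class in ("frameshift_indel", "nonframeshift_indel"):
            ins = 1 if func_class == "frameshift_indel" else 3
            alt = ref + "".join(_BASES[rng.integers(4)] for _ in range(ins))
        else:
            alt = _BASES[(int(_BASES.index(ref)) + int(rng.integers(1, 4))) % 4]
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key in used_keys:
            continue
        used_keys.add(key)
        break

    novel = rng.random() < cfg.frac_novel
    if novel:
        dbsnp, in_kg = None, False
        maf = {p: None for p in cfg.panels}
        alt_f = 0.003
    else:
        dbsnp, in_kg = f"rs{int(rng.integers(10_000_000, 99_999_999))}", True
        if rng.random() < cfg.frac_rare_known:
            base = float(rng.uniform(0.0005, cfg.maf_max))
        else:
            base = float(rng.uniform(cfg.maf_max, 0.5))
        maf = {
            p: float(np.clip(base * rng.uniform(0.7, 1.3), 0.0, 0.5))
            for p in cfg.panels
        }
        alt_f = maf[cfg.panel]
    genotypes = {
        s: _hw_genotype(rng, alt_f, cfg.genotype_missing_rate) for s in samples
    }
    v = AnnotatedVariant(
        chromosome=chrom,
        position_bp=pos,
        ref=ref,
        alt=alt,
        gene=f"G{chrom}_{pos // 1_000_000}",
        func_class=func_class,
        dbsnp_id=dbsnp,
        in_thousand_genomes=in_kg,
        maf=maf,
        genotypes=genotypes,
    )
    alt_freqs[v.key] = alt_f
    return v


def make_variant_tables(
    cfg: VariantTableConfig, regions=None, seed: int | None = None
) -> VariantTablesResult:
    """Generate the family exome table and the unrelated replication cohort.

    ``regions`` (LinkageRegion objects or (chrom, start, end) tuples) place
    the planted variant when ``cfg.planted_position`` is not given. The
    planted variant is heterozygous in every affected sample, absent from
    every unaffected one, and random (het/ref) in unconfirmed samples; it
    satisfies its branch's predicates by construction, and any background
    variant that would also survive the cascade is demoted, making the
    plant the unique survivor.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    used_seed = cfg.seed if seed is None else seed
    if cfg.planted_branch not in ("novel", "rare"):
        raise ConfigurationError(f"unknown planted branch {cfg.planted_branch!r}")
    if cfg.plant and cfg.planted_branch == "novel" and cfg.planted_dbsnp_id:
        raise ConfigurationError("a novel-branch plant cannot carry a dbSNP id")
    if cfg.plant and cfg.planted_maf is not None and cfg.planted_maf > cfg.maf_max:
        raise ConfigurationError(
            f"planted MAF {cfg.planted_maf} exceeds the rarity bound {cfg.maf_max}"
        )

    family_samples = cfg.design.all_samples
    used_keys: set[str] = set()
    alt_freqs: dict[str, float] = {}

    planted = None
    if cfg.plant:
        if cfg.planted_position is not None:
            chrom, pos = cfg.planted_position
        elif regions:
            r = _first_interval(regions)
            chrom, pos = r[0], (r[1] + r[2]) // 2
        else:
            raise ConfigurationError(
                "planting a causal variant requires regions or planted_position"
            )
        ref, alt = "G", "A"
        if cfg.planted_branch == "novel":
            dbsnp, in_kg = None, False
            maf = {p: None for p in cfg.panels}
        else:
            dbsnp = cfg.planted_dbsnp_id or f"rs{int(rng.integers(100_000_000, 999_999_999))}"
            in_kg = True
            pm = cfg.planted_maf if cfg.planted_maf is not None else float(
                rng.uniform(0.001, cfg.maf_max)
            )
            maf = {p: pm for p in cfg.panels}
        genotypes = {s: GT_HET for s in cfg.design.affected}
        genotypes.update({s: GT_REF for s in cfg.design.unaffected})
        genotypes.update(
            {s: (GT_HET if rng.random() < 0.5 else GT_REF) for s in cfg.design.unconfirmed}
        )
        planted = AnnotatedVariant(
            chromosome=str(chrom),
            position_bp=int(pos),
            ref=ref,
            alt=alt,
            gene=cfg.planted_gene,
            func_class=cfg.planted_class,
            dbsnp_id=dbsnp,
            in_thousand_genomes=in_kg,
            maf=maf,
            genotypes=genotypes,
        )
        used_keys.add(planted.key)

    family = [
        _background_variant(rng, cfg, family_samples, used_keys, alt_freqs)
        for _ in range(cfg.n_background)
    ]
    if planted is not None:
        family.append(planted)
        if regions is not None:
            _suppress_accidental_survivors(family, planted, cfg, regions)

    # unrelated replication cohort
    unrelated: list[AnnotatedVariant] = []
    unrelated_planted: list[AnnotatedVariant] = []
    if cfg.unrelated_samples:
        dummy = {}
        unrelated = [
            _background_variant(rng, cfg, cfg.unrelated_samples, used_keys, dummy)
            for _ in range(cfg.n_background)
        ]
        if cfg.plant:
            reps = list(
                rng.choice(
                    len(cfg.unrelated_samples),
                    size=min(cfg.n_replicating, len(cfg.unrelated_samples)),
                    replace=False,
                )
            )
            base_pos = planted.position_bp if planted else 1_000_000
            for i, si in enumerate(sorted(reps)):
                sample = cfg.unrelated_samples[si]
                gts = {s: GT_REF for s in cfg.unrelated_samples}
                gts[sample] = GT_HET
                v = AnnotatedVariant(
                    chromosome=planted.chromosome if planted else "1",
                    position_bp=base_pos + 1000 * (i + 1),
                    ref="C",
                    alt="T",
                    gene=cfg.planted_gene,
                    func_class="nonsynonymous_SNV",
                    dbsnp_id=f"rs{int(rng.integers(100_000_000, 999_999_999))}",
                    in_thousand_genomes=True,
                    maf={p: float(rng.uniform(0.001, cfg.maf_max)) for p in cfg.panels},
                    genotypes=gts,
                )
                unrelated.append(v)
                unrelated_planted.append(v)

    return VariantTablesResult(
        family=family,
        unrelated=unrelated,
        planted=planted,
        unrelated_planted=unrelated_planted,
        design=cfg.design,
        alt_freqs=alt_freqs,
        seed=used_seed,
    )


def _first_interval(regions):
    from .variants import _as_intervals

    intervals = _as_intervals(regions)
    if not intervals:
        raise ConfigurationError("no regions available to place the planted variant")
    return intervals[0]


def _suppress_accidental_survivors(family, planted, cfg, regions):
    """Reset one affected genotype on any background cascade survivor."""
    from .variants import (
        CARRIER_GENOTYPES,
        FUNCTIONAL_SNV_CLASSES,
        INDEL_CLASSES,
        _as_intervals,
    )

    intervals = _as_intervals(regions)
    first_affected = cfg.design.affected[0]
    for v in family:
        if v is planted:
            continue
        if v.func_class not in FUNCTIONAL_SNV_CLASSES | INDEL_CLASSES:
            continue
        f = v.maf.get(cfg.panel)
        if not (v.is_novel or f is None or f <= cfg.maf_max):
            continue
        if not any(
            str(v.chromosome) == c and s <= v.position_bp <= e for c, s, e in intervals
        ):
            continue
        if any(
            v.genotypes[s] not in CARRIER_GENOTYPES for s in cfg.design.affected
        ):
            continue
        if any(v.genotypes[s] in CARRIER_GENOTYPES for s in cfg.design.unaffected):
            continue
        v.genotypes[first_affected] = GT_REF
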