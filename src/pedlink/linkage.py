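"""Parametric multipoint linkage analysis on pedigrees.

The engine is a Lander–Green hidden Markov model over inheritance vectors:
the hidden state at each locus is the vector of meiosis outcomes (one bit
per meiosis, ``2 * n_nonfounders`` bits in total), transitions between
adjacent loci flip each bit independently with the Haldane recombination
fraction, and emissions are founder-allele-graph probabilities of the
observed marker genotypes. The parametric LOD at a position x is

    LOD(x) = log10 sum_v P(v at x | marker data) P(phenotypes | v)
           - log10 sum_v 2^-b P(phenotypes | v)

i.e. the likelihood ratio of the disease locus being at x versus unlinked,
under a single-locus penetrance model (here a dominant model with
phenocopies and incomplete penetrance).

Dense SNP maps are handled the way the original analysis handles linkage
disequilibrium and memory: the marker panel is split into k interleaved
subsets (every k-th SNP), each subset is analysed separately, and the
per-position LOD curves are averaged.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .exceptions import (
    CapacityError,
    ConfigurationError,
    ParameterError,
    PedigreeStructureError,
)
from .pedigree import UNKNOWN, AFFECTED, UNAFFECTED, GenotypeMatrix, Marker, Pedigree

__all__ = [
    "DiseaseModel",
    "LodCurve",
    "AnalysisConfig",
    "load_analysis_config",
    "disease_likelihood",
    "marker_likelihood",
    "multipoint_lod",
    "thin_interleaved",
    "average_lod",
    "prune_uninformative",
    "ParametricLinkageModel",
    "LinkageResults",
    "DEFAULT_BIT_CEILING",
]

DEFAULT_BIT_CEILING = 20


@dataclass(frozen=True)
class DiseaseModel:
    """Single-locus disease model: allele frequency and penetrance triple.

    ``q`` is the population frequency of the disease allele ``a``;
    ``f_AA``, ``f_Aa``, ``f_aa`` are the probabilities of being affected
    given 0, 1, 2 copies of ``a``. The defaults encode a rare dominant
    disease with incomplete penetrance (0.95) and a phenocopy rate of 0.005
    at q = 5e-3.
    """

    q: float = 0.005
    f_AA: float = 0.005
    f_Aa: float = 0.95
    f_aa: float = 0.95

    def __post_init__(self):
        for name in ("q", "f_AA", "f_Aa", "f_aa"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"DiseaseModel.{name} must be in [0, 1], got {val}")

    @property
    def penetrances(self) -> tuple[float, float, float]:
        """Penetrance by copies of the disease allele (0, 1, 2)."""
        return (self.f_AA, self.f_Aa, self.f_aa)


@dataclass
class AnalysisConfig:
    """Disease model plus pipeline knobs, loadable from a JSON config file."""

    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    subsets_k: int = 30
    lod_threshold: float = 1.90


def load_analysis_config(source) -> AnalysisConfig:
    """Read a JSON config with keys q, f_AA, f_Aa, f_aa, subsets_k, lod_threshold."""
    if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            data = json.load(fh)
    elif isinstance(source, str):
        data = json.loads(source)
    else:
        data = json.load(source)
    known = {"q", "f_AA", "f_Aa", "f_aa", "subsets_k", "lod_threshold"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    dm_kwargs = {k: data[k] for k in ("q", "f_AA", "f_Aa", "f_aa") if k in data}
    return AnalysisConfig(
        disease_model=DiseaseModel(**dm_kwargs),
        subsets_k=int(data.get("subsets_k", 30)),
        lod_threshold=float(data.get("lod_threshold", 1.90)),
    )


# ---------------------------------------------------------------------------
# inheritance vectors and single-v likelihoods


def _as_vector_int(v, b: int) -> int:
    """Normalize an inheritance vector (int or bit sequence) to an int."""
    if isinstance(v, (int, np.integer)):
        vi = int(v)
        if not 0 <= vi < (1 << b):
            raise PedigreeStructureError(
                f"inheritance vector {vi} out of range for {b} meioses"
            )
        return vi
    bits = list(v)
    if len(bits) != b:
        raise PedigreeStructureError(
            f"inheritance vector has {len(bits)} bits, pedigree has {b} meioses"
        )
    return sum((1 << i) for i, bit in enumerate(bits) if bit)


def _phenotype_factors(pedigree: Pedigree, model: DiseaseModel):
    """Rows + per-copy phenotype factor table for phenotyped individuals.

    Unknown (and unconfirmed) statuses contribute no factor and are
    excluded; affected contribute the penetrance, unaffected its complement.
    """
    rows, factors = [], []
    pen = np.array(model.penetrances)
    for i, ind in enumerate(pedigree.individuals):
        status = ind.affection_effective
        if status == AFFECTED:
            rows.append(i)
            factors.append(pen)
        elif status == UNAFFECTED:
            rows.append(i)
            factors.append(1.0 - pen)
    return rows, np.array(factors, dtype=float).reshape(len(rows), 3)


def disease_likelihood(pedigree: Pedigree, v, model: DiseaseModel | None = None) -> float:
    """P(affection phenotypes | inheritance vector v) under the disease model.

    Sums over all founder disease-allele configurations: each founder allele
    carries the disease allele independently with probability q, genotypes
    of descendants are determined by v, and each phenotyped individual
    contributes its penetrance (affected) or complement (unaffected).
    Individuals of unknown/unconfirmed status contribute a factor of 1.
    """
    model = model or DiseaseModel()
    vi = _as_vector_int(v, pedigree.bit_count)
    slot_pat, slot_mat, _ = _engine.compute_slots(pedigree, np.array([vi]))
    rows, factors = _phenotype_factors(pedigree, model)
    if not rows:
        return 1.0
    out = _engine.disease_likelihood_all_v(slot_pat[rows], slot_mat[rows], factors, model.q)
    return float(out[0])


def _marker_gcodes(pedigree: Pedigree, marker: Marker, genotypes: GenotypeMatrix):
    """Rows (pedigree order) and genotype codes of individuals typed at a marker."""
    rows, codes = [], []
    for i, ind in enumerate(pedigree.individuals):
        if ind.id not in genotypes.sample_ids:
            continue
        pair = genotypes.get(ind.id, marker.id)
        if pair is None:
            continue
        rows.append(i)
        codes.append(pair[0] + pair[1] - 1)  # (1,1)->1, (1,2)->2, (2,2)->3
    return rows, np.array(codes, dtype=np.int8)


def marker_likelihood(
    pedigree: Pedigree, v, marker: Marker, genotypes: GenotypeMatrix
) -> float:
    """P(observed genotypes at one marker | inheritance vector v).

    Partitions the founder allele slots by descent under v; genotyped
    individuals constrain their two slots; the result is the product over
    connected components of the founder-allele graph of the total
    population-frequency mass of consistent allele assignments (0 when a
    component is unsatisfiable).
    """
    vi = _as_vector_int(v, pedigree.bit_count)
    slot_pat, slot_mat, _ = _engine.compute_slots(pedigree, np.array([vi]))
    rows, codes = _marker_gcodes(pedigree, marker, genotypes)
    out = _engine.marker_emission_all_v(
        slot_pat[rows], slot_mat[rows], codes, marker.founder_freqs
    )
    return float(out[0])


# ---------------------------------------------------------------------------
# pruning


def prune_uninformative(pedigree: Pedigree, genotypes=None, marker_ids=None) -> Pedigree:
    """Drop members that carry no information for the likelihood.

    An individual is uninformative when it has no observed genotype at any
    of the markers under analysis, has unknown (or unconfirmed) affection,
    and has no retained children. Removing such leaves marginalizes their
    meioses exactly (each contributes a free bit and no emission
    constraint), so likelihood ratios are unchanged while the inheritance
    vector shrinks by two bits per pruned non-founder.
    """
    typed: set[str] = set()
    if genotypes is not None:
        ids = marker_ids if marker_ids is not None else genotypes.marker_ids
        cols = [genotypes.marker_index(m) for m in ids]
        sub = genotypes.codes[:, cols, :]
        has_data = (sub > 0).any(axis=(1, 2))
        typed = {s for s, h in zip(genotypes.sample_ids, has_data) if h}

    kept = set(pedigree.ids)
    children: dict[str, set[str]] = {iid: set() for iid in kept}
    for ind in pedigree.nonfounders:
        children[ind.father_id].add(ind.id)
        children[ind.mother_id].add(ind.id)

    changed = True
    while changed:
        changed = False
        for ind in pedigree.individuals:
            if ind.id not in kept:
                continue
            if ind.id in typed or ind.affection_effective != UNKNOWN:
                continue
            if any(c in kept for c in children[ind.id]):
                continue
            kept.discard(ind.id)
            changed = True
    return pedigree.restrict(kept)


# ---------------------------------------------------------------------------
# phenotype-likelihood vector over the (quotient) inheritance space, memoized
# because the same vector is needed once per marker subset and by the
# phenotype-conditional simulator

_dl_cache: dict = {}


def _pedigree_key(ped: Pedigree, model: DiseaseModel):
    return (
        tuple(
            (i.id, i.father_id, i.mother_id, i.affection_effective)
            for i in ped.individuals
        ),
        model,
    )


def disease_likelihood_vector(ped: Pedigree, model: DiseaseModel,
                              use_founder_symmetry: bool = True):
    """``(coord_bits, sym_groups, dl)`` with dl over all quotient states."""
    key = (_pedigree_key(ped, model), use_founder_symmetry)
    hit = _dl_cache.get(key)
    if hit is not None:
        return hit
    if use_founder_symmetry:
        coord_bits, sym_groups = _engine.founder_symmetry_layout(ped)
        v_reps = _engine.representative_vectors(coord_bits)
    else:
        coord_bits = list(range(ped.bit_count))
        sym_groups = []
        v_reps = np.arange(1 << ped.bit_count, dtype=np.int64)
    slot_pat, slot_mat, _ = _engine.compute_slots(ped, v_reps)
    rows, factors = _phenotype_factors(ped, model)
    dl = _engine.disease_likelihood_all_v(
        slot_pat[rows], slot_mat[rows], factors, model.q
    )
    if len(_dl_cache) > 8:
        _dl_cache.clear()
    _dl_cache[key] = (coord_bits, sym_groups, dl)
    return coord_bits, sym_groups, dl


# ---------------------------------------------------------------------------
# LOD curves


@dataclass
class LodCurve:
    """LOD scores at ordered genome positions, per subset and averaged.

    ``subset_lods`` has shape (n_subsets, n_positions); ``mean_lod`` is
    their arithmetic mean position-wise (equal to the single row when only
    one subset was analysed).
    """

    chromosomes: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    subset_lods: np.ndarray
    mean_lod: np.ndarray

    def __post_init__(self):
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.subset_lods = np.atleast_2d(np.asarray(self.subset_lods, dtype=float))
        self.mean_lod = np.asarray(self.mean_lod, dtype=float)

    @property
    def n_positions(self) -> int:
        return self.mean_lod.size

    @property
    def n_subsets(self) -> int:
        return self.subset_lods.shape[0]

    @property
    def max_lod(self) -> float:
        return float(np.max(self.mean_lod))

    @property
    def argmax(self) -> tuple[str, int, float]:
        """(chromosome, bp, cM) of the genome-wide maximum of the mean curve.

        Multipoint curves are flat across the no-recombination window
        around a fully supported locus, so ties (within 1e-6) are resolved
        to the midpoint of the maximal run containing the first maximum
        rather than its left edge.
        """
        i = int(np.argmax(self.mean_lod))
        top = self.mean_lod[i]
        chrom = self.chromosomes[i]
        j = i
        while (
            j + 1 < self.mean_lod.size
            and self.chromosomes[j + 1] == chrom
            and self.mean_lod[j + 1] >= top - 1e-6
        ):
            j += 1
        k = i
        while (
            k - 1 >= 0
            and self.chromosomes[k - 1] == chrom
            and self.mean_lod[k - 1] >= top - 1e-6
        ):
            k -= 1
        mid = (k + j) // 2
        return (
            str(self.chromosomes[mid]),
            int(self.positions_bp[mid]),
            float(self.positions_cm[mid]),
        )

    def chromosome_list(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(str(c))
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chrom": [str(c) for c in self.chromosomes],
            "bp": self.positions_bp,
            "cM": self.positions_cm,
        }
        for j in range(self.n_subsets):
            data[f"subset_{j}"] = self.subset_lods[j]
        data["mean"] = self.mean_lod
        return pd.DataFrame(data)

    def to_tsv(self, path=None):
        text = self.to_frame().to_csv(sep="\t", index=False, float_format="%.6g")
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)

    def to_json(self, path=None):
        payload = self.to_frame().to_dict(orient="list")
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)


def thin_interleaved(markers, k: int):
    """Split genome-ordered markers into k interleaved subsets.

    Subset j holds markers at indices j, j+k, j+2k, ...; the subsets
    partition the input and preserve order. This is the
    one-SNP-in-every-k thinning used to break linkage disequilibrium in
    dense SNP panels.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    markers = list(markers)
    return [markers[j::k] for j in range(k)]


def _group_by_chromosome(markers):
    groups: dict[str, list] = {}
    for m in markers:
        groups.setdefault(str(m.chromosome), []).append(m)
    for chrom, ms in groups.items():
        cms = [m.position_cm for m in ms]
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise ParameterError(
                f"chromosome {chrom}: markers not sorted by genetic position"
            )
    return groups


def multipoint_lod(
    pedigree: Pedigree,
    markers,
    genotypes: GenotypeMatrix,
    disease_model: DiseaseModel | None = None,
    positions=None,
    bit_ceiling: int = DEFAULT_BIT_CEILING,
    prune: bool = True,
    use_founder_symmetry: bool = True,
) -> LodCurve:
    """Multipoint parametric LOD curve over one marker set.

    Runs the forward–backward algorithm over inheritance vectors per
    chromosome, with Haldane transitions between adjacent loci, and
    evaluates the parametric LOD at ``positions`` (default: the marker
    positions themselves, mirroring marker-coordinate peak reporting).

    ``positions`` may be a mapping ``{chromosome: iterable of cM}``;
    physical coordinates for non-marker positions are linearly interpolated
    from the marker map.

    With ``use_founder_symmetry`` (default) the HMM runs on the exact
    founder-phase quotient space, dropping one bit per transmitting
    founder; LOD values are unchanged to numerical precision.
    """
    model = disease_model or DiseaseModel()
    markers = list(markers)
    if not markers:
        raise ParameterError("no markers supplied")
    groups = _group_by_chromosome(markers)

    ped = pedigree
    if prune:
        ped = prune_uninformative(pedigree, genotypes, [m.id for m in markers])
    b = ped.bit_count
    if use_founder_symmetry:
        m_bits = len(_engine.founder_symmetry_layout(ped)[0])
    else:
        m_bits = b
    if m_bits > bit_ceiling:
        raise CapacityError(
            f"pedigree requires {m_bits} effective inheritance bits "
            f"({b} raw) > ceiling {bit_ceiling}; split the pedigree or "
            "raise bit_ceiling"
        )
    coord_bits, sym_groups, dl = disease_likelihood_vector(
        ped, model, use_founder_symmetry
    )
    v_reps = _engine.representative_vectors(coord_bits)

    slot_pat, slot_mat, _ = _engine.compute_slots(ped, v_reps)
    denom = float(np.mean(dl))  # sum_v 2^-b * DL(v)
    if denom <= 0.0:
        raise ParameterError(
            "phenotype likelihood is zero for every inheritance vector; "
            "the phenotypes are inconsistent with the disease model"
        )
    log10_denom = math.log10(denom)

    out_chrom, out_bp, out_cm, out_lod = [], [], [], []
    for chrom, ms in groups.items():
        emissions = []
        for m in ms:
            rws, codes = _marker_gcodes(ped, m, genotypes)
            e = _engine.marker_emission_all_v(
                slot_pat[rws], slot_mat[rws], codes, m.founder_freqs
            )
            if not np.any(e > 0):
                raise ParameterError(
                    f"marker {m.id}: genotypes inconsistent with the pedigree "
                    "(did QC run?)"
                )
            emissions.append(e)
        cms = np.array([m.position_cm for m in ms], dtype=float)
        bps = np.array([m.position_bp for m in ms], dtype=np.int64)
        if positions is None:
            eval_cm = cms
            eval_bp = bps
        else:
            eval_cm = np.asarray(sorted(positions.get(chrom, [])), dtype=float)
            if eval_cm.size == 0:
                continue
            if cms.size > 1:
                eval_bp = np.interp(eval_cm, cms, bps).round().astype(np.int64)
            else:
                eval_bp = np.full(eval_cm.size, bps[0], dtype=np.int64)
        lods = _chromosome_lod(emissions, cms, eval_cm, dl, m_bits, sym_groups,
                               log10_denom)
        out_chrom += [chrom] * eval_cm.size
        out_bp.append(eval_bp)
        out_cm.append(eval_cm)
        out_lod.append(lods)

    bp = np.concatenate(out_bp)
    cm = np.concatenate(out_cm)
    lod = np.concatenate(out_lod)
    return LodCurve(np.array(out_chrom, dtype=object), bp, cm, lod[None, :], lod)


def _chromosome_lod(emissions, cms, eval_cms, dl, m_bits, sym_groups, log10_denom):
    """Forward-backward over one chromosome; LOD at each requested cM."""
    n_states = emissions[0].size
    L = len(emissions)
    thetas = _engine.haldane_theta(np.diff(cms))

    def T(x, theta):
        return _engine.apply_transition_quotient(x, theta, m_bits, sym_groups)

    fwd = []
    f = emissions[0] / n_states
    s = f.sum()
    f = f / s
    fwd.append(f)
    for m in range(1, L):
        f = T(fwd[-1], thetas[m - 1]) * emissions[m]
        s = f.sum()
        if s <= 0:
            raise ParameterError("joint marker likelihood is zero; inconsistent data")
        fwd.append(f / s)

    bwd = [None] * L
    bw = np.ones(n_states)
    bwd[L - 1] = bw
    for m in range(L - 2, -1, -1):
        bw = T(bwd[m + 1] * emissions[m + 1], thetas[m])
        bw = bw / bw.sum()
        bwd[m] = bw

    lods = np.empty(len(eval_cms))
    for i, x in enumerate(eval_cms):
        if x <= cms[0]:
            post = T(emissions[0] * bwd[0], _engine.haldane_theta(cms[0] - x))
        elif x >= cms[-1]:
            post = T(fwd[L - 1], _engine.haldane_theta(x - cms[-1]))
        else:
            m = int(np.searchsorted(cms, x, side="right")) - 1
            if abs(cms[m] - x) < 1e-12:
                post = fwd[m] * bwd[m]
            else:
                left = T(fwd[m], _engine.haldane_theta(x - cms[m]))
                right = T(
                    emissions[m + 1] * bwd[m + 1],
                    _engine.haldane_theta(cms[m + 1] - x),
                )
                post = left * right
        post = post / post.sum()
        num = float(post @ dl)
        lods[i] = (math.log10(num) - log10_denom) if num > 0 else -math.inf
    return lods


def average_lod(curves, positions=None) -> LodCurve:
    """Average per-subset LOD curves position-wise.

    ``positions`` may be an iterable of (chromosome, bp, cM) triples;
    by default the union of all curve positions is used. Curves are
    evaluated at the requested positions by linear interpolation in cM
    (constant extension beyond a curve's ends). Per-subset curves are
    retained in the result.
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("no curves to average")

    if positions is None:
        seen: dict[tuple[str, float], int] = {}
        chrom_order: dict[str, None] = {}
        triples = []
        for c in curves:
            for chrom, bp, cm in zip(c.chromosomes, c.positions_bp, c.positions_cm):
                chrom_order.setdefault(str(chrom))
                key = (str(chrom), float(cm))
                if key not in seen:
                    seen[key] = 1
                    triples.append((str(chrom), int(bp), float(cm)))
        triples.sort(key=lambda t: (list(chrom_order).index(t[0]), t[2]))
    else:
        triples = [(str(c), int(bp), float(cm)) for c, bp, cm in positions]

    chroms = np.array([t[0] for t in triples], dtype=object)
    bps = np.array([t[1] for t in triples], dtype=np.int64)
    cms = np.array([t[2] for t in triples], dtype=float)

    rows = np.empty((len(curves), len(triples)))
    for j, curve in enumerate(curves):
        curve_chroms = np.array([str(c) for c in curve.chromosomes], dtype=object)
        for chrom in np.unique(chroms.astype(str)):
            mask = chroms.astype(str) == chrom
            cmask = curve_chroms == chrom
            if not cmask.any():
                raise ParameterError(
                    f"subset curve {j} does not cover chromosome {chrom}"
                )
            order = np.argsort(curve.positions_cm[cmask], kind="stable")
            xp = curve.positions_cm[cmask][order]
            yp = curve.mean_lod[cmask][order]
            rows[j, mask] = np.interp(cms[mask], xp, yp)
    return LodCurve(chroms, bps, cms, rows, rows.mean(axis=0))


# ---------------------------------------------------------------------------
# model / results


class ParametricLinkageModel:
    """Genome-wide parametric multipoint linkage model for one pedigree.

    Parameters
    ----------
    pedigree : Pedigree
        Family structure with affection statuses (unconfirmed statuses are
        treated as unknown in the likelihood).
    markers : sequence of Marker
        Genome-ordered biallelic markers with genetic positions and founder
        allele frequencies (typically the post-QC panel).
    genotypes : GenotypeMatrix
        Observed unordered genotypes.
    disease_model : DiseaseModel, optional
        Penetrance model; defaults to the rare-dominant model with
        phenocopies (q=0.005, penetrances 0.005/0.95/0.95).
    bit_ceiling : int
        Maximum inheritance-vector size after pruning (default 20).

    Examples
    --------
    >>> model = ParametricLinkageModel(ped, markers, gm)
    >>> res = model.fit(subsets_k=30)
    >>> res.max_lod, res.peak
    >>> regions = res.call_regions(threshold=1.90)
    """

    def __init__(
        self,
        pedigree: Pedigree,
        markers,
        genotypes: GenotypeMatrix,
        disease_model: DiseaseModel | None = None,
        bit_ceiling: int = DEFAULT_BIT_CEILING,
    ):
        self.pedigree = pedigree
        self.markers = list(markers)
        self.genotypes = genotypes
        self.disease_model = disease_model or DiseaseModel()
        self.bit_ceiling = bit_ceiling

    @classmethod
    def from_ped_map(
        cls,
        ped_source,
        map_source,
        affection_sidecar=None,
        disease_model: DiseaseModel | None = None,
        qc: bool = True,
        **kwargs,
    ):
        """Build a model from PED/MAP text, applying marker QC by default."""
        from .pedigree import (
            apply_affection,
            qc_markers,
            read_affection_sidecar,
            read_ped_map,
        )

        pedigree, markers, genotypes = read_ped_map(ped_source, map_source)
        if affection_sidecar is not None:
            pedigree = apply_affection(
                pedigree, read_affection_sidecar(affection_sidecar)
            )
        if qc:
            markers, _ = qc_markers(pedigree, markers, genotypes)
        return cls(pedigree, markers, genotypes, disease_model, **kwargs)

    def fit(self, subsets_k: int = 1, positions=None) -> "LinkageResults":
        """Run the thin-analyse-average pipeline and return results.

        The marker panel is thinned genome-wide into ``subsets_k``
        interleaved subsets, each is analysed with the multipoint HMM, and
        the per-subset LOD curves are averaged at the full marker grid
        (linear interpolation in cM).
        """
        order: dict[str, None] = {}
        for m in self.markers:
            order.setdefault(str(m.chromosome))
        chrom_rank = {c: i for i, c in enumerate(order)}
        markers = sorted(
            self.markers,
            key=lambda m: (chrom_rank[str(m.chromosome)], m.position_cm, m.position_bp),
        )
        subsets = thin_interleaved(markers, subsets_k)
        curves = [
            multipoint_lod(
                self.pedigree,
                sub,
                self.genotypes,
                self.disease_model,
                positions=positions,
                bit_ceiling=self.bit_ceiling,
            )
            for sub in subsets
            if sub
        ]
        grid = [(str(m.chromosome), m.position_bp, m.position_cm) for m in markers]
        curve = average_lod(curves, positions=grid)
        return LinkageResults(self, curve, subsets_k)


class LinkageResults:
    """Fitted linkage results: the averaged LOD curve and derived reports."""

    def __init__(self, model: ParametricLinkageModel, curve: LodCurve, subsets_k: int):
        self.model = model
        self.curve = curve
        self.subsets_k = subsets_k

    @property
    def max_lod(self) -> float:
        return self.curve.max_lod

    @property
    def peak(self) -> tuple[str, int, float]:
        """(chromosome, bp, cM) of the genome-wide maximum averaged LOD."""
        return self.curve.argmax

    def call_regions(self, threshold: float = 1.90):
        """Candidate linkage regions on the averaged curve (see regions module)."""
        from .regions import call_regions

        return call_regions(self.curve, threshold)

    def summary(self, threshold: float = 1.90) -> str:
        dm = self.model.disease_model
        lines = [
            "Parametric multipoint linkage results",
            "=" * 53,
            f"pedigree members: {len(self.model.pedigree)}   "
            f"markers: {len(self.model.markers)}   subsets: {self.subsets_k}",
            f"disease model: q={dm.q:g}, penetrances "
            f"(f_AA, f_Aa, f_aa)=({dm.f_AA:g}, {dm.f_Aa:g}, {dm.f_aa:g})",
            "-" * 53,
            f"{'chrom':>6} {'n_pos':>6} {'max LOD':>9} {'argmax bp':>12} {'argmax cM':>10}",
        ]
        chroms = np.array([str(c) for c in self.curve.chromosomes])
        for chrom in self.curve.chromosome_list():
            mask = chroms == chrom
            sub = self.curve.mean_lod[mask]
            i = int(np.argmax(sub))
            lines.append(
                f"{chrom:>6} {mask.sum():>6d} {sub[i]:>9.3f} "
                f"{int(self.curve.positions_bp[mask][i]):>12d} "
                f"{self.curve.positions_cm[mask][i]:>10.2f}"
            )
        lines.append("-" * 53)
        peak = self.peak
        lines.append(
            f"genome-wide max LOD {self.max_lod:.3f} at chr{peak[0]}:{peak[1]} "
            f"({peak[2]:.2f} cM); regions called at LOD >= {threshold:g}: "
            f"{len(self.call_regions(threshold))}"
        )
        return "\n".join(lines)

    def plot(self, ax=None, threshold: float = 1.90):
        """Genome-wide averaged LOD plot with the calling threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        chroms = np.array([str(c) for c in self.curve.chromosomes])
        for chrom in self.curve.chromosome_list():
            mask = chroms == chrom
            x = self.curve.positions_cm[mask] + offset
            ax.plot(x, self.curve.mean_lod[mask], lw=0.8, label=f"chr{chrom}")
            offset = x.max() + 10.0
        ax.axhline(threshold, ls=":", color="k", lw=0.8)
        ax.set_xlabel("cumulative genetic position (cM)")
        ax.set_ylabel("average LOD")
        return ax
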