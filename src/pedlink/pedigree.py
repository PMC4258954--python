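"""Pedigree and genotype data model, PLINK-style PED/MAP I/O, and marker QC.

The data model is deliberately small: a :class:`Pedigree` of
:class:`Individual` records, a list of biallelic :class:`Marker` objects
carrying genetic (cM) and physical (bp) coordinates plus founder allele
frequencies, and a :class:`GenotypeMatrix` of unordered allele pairs.
Coordinates are 1-based inclusive base pairs throughout; phase is never read
from input.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import FileFormatError, ParameterError, PedigreeStructureError

__all__ = [
    "AFFECTED",
    "UNAFFECTED",
    "UNKNOWN",
    "UNCONFIRMED",
    "Individual",
    "Pedigree",
    "Marker",
    "GenotypeMatrix",
    "QCReport",
    "read_ped_map",
    "write_ped_map",
    "read_affection_sidecar",
    "write_affection_sidecar",
    "apply_affection",
    "mendelian_check",
    "qc_markers",
    "estimate_allele_frequencies",
]

# affection statuses; "unconfirmed" records a clinically-assessed-only status
# and collapses to unknown in every likelihood computation
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"
UNCONFIRMED = "unconfirmed"
_AFFECTIONS = {AFFECTED, UNAFFECTED, UNKNOWN, UNCONFIRMED}

MALE = "male"
FEMALE = "female"
_SEXES = {MALE, FEMALE, UNKNOWN}

# chromosomes excluded from the autosomal linkage model (PLINK numeric codes
# for X/Y/XY/MT included)
SEX_LINKED_CHROMOSOMES = frozenset(
    {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26", "chrX", "chrY", "chrM"}
)


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are both ``None`` (founder) or both set.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    affection: str = UNKNOWN

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeStructureError(
                f"individual {self.id!r}: half-specified parents "
                f"(father={self.father_id!r}, mother={self.mother_id!r})"
            )
        if self.sex not in _SEXES:
            raise ParameterError(f"individual {self.id!r}: bad sex {self.sex!r}")
        if self.affection not in _AFFECTIONS:
            raise ParameterError(
                f"individual {self.id!r}: bad affection {self.affection!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def affection_effective(self) -> str:
        """Affection as used in likelihoods (unconfirmed -> unknown)."""
        return UNKNOWN if self.affection == UNCONFIRMED else self.affection


class Pedigree:
    """An ordered collection of individuals with validated parent links.

    Derived quantities: founders, non-founders, the meiosis list (one
    paternal and one maternal meiosis per non-founder, in individual order)
    and the inheritance-vector bit count ``b = 2 * n_nonfounders``.
    """

    def __init__(self, individuals):
        self.individuals: list[Individual] = list(individuals)
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise PedigreeStructureError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for pid, role in ((ind.father_id, "father"), (ind.mother_id, "mother")):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeStructureError(
                        f"individual {ind.id!r}: unknown {role} {pid!r}"
                    )
        self._toposort()

    def _toposort(self):
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for root in self._by_id:
            if root in state:
                continue
            stack = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if node in state:
                    if state[node] == 0:
                        raise PedigreeStructureError(
                            f"parent links contain a cycle through {node!r}"
                        )
                    continue
                state[node] = 0
                stack.append((node, True))
                ind = self._by_id[node]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None and state.get(pid) != 1:
                        if state.get(pid) == 0:
                            raise PedigreeStructureError(
                                f"parent links contain a cycle through {pid!r}"
                            )
                        stack.append((pid, False))
        self._topo_order = order

    def __len__(self):
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    @property
    def meioses(self) -> list[tuple[str, str]]:
        """Ordered meiosis list: ``(child_id, 'paternal'|'maternal')``.

        Bit ``2i`` of an inheritance vector is the paternal meiosis of the
        i-th non-founder, bit ``2i + 1`` the maternal one.
        """
        out = []
        for ind in self.nonfounders:
            out.append((ind.id, "paternal"))
            out.append((ind.id, "maternal"))
        return out

    @property
    def bit_count(self) -> int:
        return 2 * len(self.nonfounders)

    def topological_ids(self) -> list[str]:
        """Individual ids with every parent before its children."""
        return list(self._topo_order)

    def with_affection(self, statuses: dict[str, str]) -> "Pedigree":
        """Return a copy with affection statuses replaced from a mapping."""
        return Pedigree(
            [
                replace(ind, affection=statuses.get(ind.id, ind.affection))
                for ind in self.individuals
            ]
        )

    def restrict(self, keep_ids) -> "Pedigree":
        """Subset to ``keep_ids``; retained non-founders must keep both parents."""
        keep = set(keep_ids)
        out = []
        for ind in self.individuals:
            if ind.id not in keep:
                continue
            if ind.father_id is not None and ind.father_id not in keep:
                raise PedigreeStructureError(
                    f"cannot restrict: {ind.id!r} would lose parent {ind.father_id!r}"
                )
            out.append(ind)
        return Pedigree(out)


@dataclass
class Marker:
    """A biallelic SNP with map coordinates and founder allele frequencies."""

    id: str
    chromosome: str
    position_bp: int
    position_cm: float
    alleles: tuple[str, str] = ("1", "2")
    founder_freqs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if abs(sum(self.founder_freqs) - 1.0) > 1e-12:
            raise ParameterError(
                f"marker {self.id!r}: founder_freqs must sum to 1, "
                f"got {self.founder_freqs}"
            )
        if min(self.founder_freqs) < 0:
            raise ParameterError(f"marker {self.id!r}: negative allele frequency")


class GenotypeMatrix:
    """Unordered allele pairs per (individual, marker).

    Stored as an ``(n_samples, n_markers, 2)`` int8 array of allele codes:
    0 = missing, 1/2 = first/second allele of the marker's allele pair. Both
    slots are 0 or both non-zero; the pair is kept sorted (unordered
    genotype, phase is never represented).
    """

    def __init__(self, sample_ids, marker_ids, codes: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.sample_ids), len(self.marker_ids), 2):
            raise ParameterError(
                f"genotype array shape {codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        self.codes = codes
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    @classmethod
    def empty(cls, sample_ids, marker_ids):
        return cls(
            sample_ids,
            marker_ids,
            np.zeros((len(sample_ids), len(marker_ids), 2), dtype=np.int8),
        )

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def get(self, sample_id: str, marker_id: str) -> tuple[int, int] | None:
        """Unordered genotype as a sorted code pair, or None when missing."""
        pair = self.codes[self._sample_index[sample_id], self._marker_index[marker_id]]
        if pair[0] == 0:
            return None
        return (int(pair[0]), int(pair[1]))

    def set(self, sample_id: str, marker_id: str, pair: tuple[int, int] | None):
        i = self._sample_index[sample_id]
        j = self._marker_index[marker_id]
        if pair is None:
            self.codes[i, j] = 0
        else:
            a, b = sorted(pair)
            if not (1 <= a <= 2 and 1 <= b <= 2):
                raise ParameterError(f"allele codes must be 1 or 2, got {pair}")
            self.codes[i, j, 0] = a
            self.codes[i, j, 1] = b

    def restrict_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = [self._marker_index[m] for m in marker_ids]
        return GenotypeMatrix(self.sample_ids, marker_ids, self.codes[:, idx, :])

    def column(self, marker_id: str) -> np.ndarray:
        """All samples' code pairs for one marker, shape (n_samples, 2)."""
        return self.codes[:, self._marker_index[marker_id], :]


# ---------------------------------------------------------------------------
# PED/MAP I/O

_PHENO_TO_AFFECTION = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_AFFECTION_TO_PHENO = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0", UNCONFIRMED: "0"}
_SEX_FROM_CODE = {"1": MALE, "2": FEMALE}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}


def _as_lines(source) -> list[str]:
    """Accept a path, file-like object, or literal text content."""
    if hasattr(source, "read"):
        return source.read().splitlines()
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            return fh.read().splitlines()
    if isinstance(source, str):
        if "\n" in source or not os.path.exists(source):
            return source.splitlines()
        with open(source) as fh:
            return fh.read().splitlines()
    raise ParameterError(f"cannot read from {type(source).__name__}")


def read_ped_map(ped_source, map_source):
    """Parse whitespace-delimited PED + MAP text.

    PED columns: family, id, father, mother, sex, phenotype, then two allele
    columns per marker ('0' = missing allele). MAP columns: chromosome, id,
    cM, bp. ``0`` parent ids map to founder; phenotype 1/2/0/-9 map to
    unaffected/affected/unknown/unknown. When the MAP's genetic positions are
    all zero, physical positions are converted at 1 cM/Mb.

    Returns ``(Pedigree, [Marker], GenotypeMatrix)``. Allele labels per
    marker are the (at most two) distinct non-missing labels observed, in
    sorted order; founder allele frequencies are estimated by counting
    founder alleles (falling back to all typed individuals when fewer than
    four founder alleles are observed).
    """
    map_lines = [ln for ln in _as_lines(map_source) if ln.strip() and not ln.startswith("#")]
    markers: list[Marker] = []
    for lineno, ln in enumerate(map_lines, start=1):
        parts = ln.split()
        if len(parts) != 4:
            raise FileFormatError(
                f"MAP expects 4 columns (chrom id cM bp), got {len(parts)}", lineno
            )
        chrom, mid, cm, bp = parts
        markers.append(Marker(mid, chrom, int(bp), float(cm)))
    if markers and all(m.position_cm == 0.0 for m in markers):
        for m in markers:
            m.position_cm = m.position_bp / 1e6  # 1 cM/Mb fallback

    ped_lines = [ln for ln in _as_lines(ped_source) if ln.strip() and not ln.startswith("#")]
    n_markers = len(markers)
    individuals = []
    raw_genotypes = []  # per sample: list of (a1, a2) labels or None
    for lineno, ln in enumerate(ped_lines, start=1):
        parts = ln.split()
        if len(parts) != 6 + 2 * n_markers:
            raise FileFormatError(
                f"PED expects {6 + 2 * n_markers} columns for {n_markers} "
                f"markers, got {len(parts)}",
                lineno,
            )
        _fam, iid, fid, mid, sex_code, pheno = parts[:6]
        father = None if fid == "0" else fid
        mother = None if mid == "0" else mid
        if (father is None) != (mother is None):
            raise PedigreeStructureError(
                f"individual {iid!r}: half-specified parents ({fid!r}, {mid!r})"
            )
        if pheno not in _PHENO_TO_AFFECTION:
            raise FileFormatError(f"unknown phenotype code {pheno!r}", lineno)
        individuals.append(
            Individual(
                iid,
                father,
                mother,
                sex=_SEX_FROM_CODE.get(sex_code, UNKNOWN),
                affection=_PHENO_TO_AFFECTION[pheno],
            )
        )
        row = []
        for j in range(n_markers):
            a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
            if (a1 == "0") != (a2 == "0"):
                raise FileFormatError(
                    f"marker {markers[j].id}: half-missing genotype "
                    f"({a1!r}/{a2!r}) for {iid!r}",
                    lineno,
                )
            row.append(None if a1 == "0" else (a1, a2))
        raw_genotypes.append(row)

    pedigree = Pedigree(individuals)

    # assign allele labels per marker from observed data
    codes = np.zeros((len(individuals), n_markers, 2), dtype=np.int8)
    for j, marker in enumerate(markers):
        labels = sorted({a for row in raw_genotypes for a in (row[j] or ())})
        if len(labels) > 2:
            raise FileFormatError(
                f"marker {marker.id}: more than two alleles observed: {labels}"
            )
        if len(labels) == 0:
            labels = ["1", "2"]
        elif len(labels) == 1:
            labels = [labels[0], "0"]  # placeholder second allele, freq 0
        marker.alleles = (labels[0], labels[1])
        code_of = {labels[0]: 1, labels[1]: 2}
        for i, row in enumerate(raw_genotypes):
            if row[j] is not None:
                c = sorted(code_of[a] for a in row[j])
                codes[i, j] = c

    genotypes = GenotypeMatrix([i.id for i in individuals], [m.id for m in markers], codes)
    estimate_allele_frequencies(pedigree, markers, genotypes)
    return pedigree, markers, genotypes


def write_ped_map(pedigree: Pedigree, markers, genotypes: GenotypeMatrix, family_id="FAM1"):
    """Inverse of :func:`read_ped_map`; returns ``(ped_text, map_text)``."""
    map_lines = [
        f"{m.chromosome}\t{m.id}\t{m.position_cm:g}\t{m.position_bp}" for m in markers
    ]
    ped_lines = []
    for ind in pedigree:
        cols = [
            family_id,
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            _SEX_TO_CODE[ind.sex],
            _AFFECTION_TO_PHENO[ind.affection],
        ]
        for m in markers:
            pair = genotypes.get(ind.id, m.id)
            if pair is None:
                cols += ["0", "0"]
            else:
                cols += [m.alleles[pair[0] - 1], m.alleles[pair[1] - 1]]
        ped_lines.append("\t".join(cols))
    return "\n".join(ped_lines) + "\n", "\n".join(map_lines) + "\n"


def read_affection_sidecar(source) -> dict[str, str]:
    """Read the (id, status) TSV carrying statuses PED cannot express."""
    out = {}
    for lineno, ln in enumerate(_as_lines(source), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise FileFormatError("affection sidecar expects two columns", lineno)
        iid, status = parts
        if status not in _AFFECTIONS:
            raise FileFormatError(f"unknown affection status {status!r}", lineno)
        out[iid] = status
    return out


def write_affection_sidecar(statuses: dict[str, str]) -> str:
    return "".join(f"{iid}\t{status}\n" for iid, status in statuses.items())


def apply_affection(pedigree: Pedigree, statuses: dict[str, str]) -> Pedigree:
    """Overlay sidecar statuses (including 'unconfirmed') onto a pedigree."""
    unknown = set(statuses) - set(pedigree.ids)
    if unknown:
        raise ParameterError(f"sidecar names unknown individuals: {sorted(unknown)}")
    return pedigree.with_affection(statuses)


# ---------------------------------------------------------------------------
# marker QC


def estimate_allele_frequencies(pedigree, markers, genotypes, min_founder_alleles=4):
    """Set each marker's founder_freqs by allele counting (in place).

    Counts founder alleles; falls back to all typed individuals when fewer
    than ``min_founder_alleles`` founder alleles are observed; 0.5/0.5 when
    nothing is typed.
    """
    founder_rows = [genotypes.sample_index(f.id) for f in pedigree.founders
                    if f.id in genotypes.sample_ids]
    all_rows = list(range(len(genotypes.sample_ids)))
    for m in markers:
        col = genotypes.codes[:, genotypes.marker_index(m.id), :]
        fc = col[founder_rows].ravel() if founder_rows else np.empty(0, dtype=np.int8)
        fc = fc[fc > 0]
        if fc.size < min_founder_alleles:
            fc = col[all_rows].ravel()
            fc = fc[fc > 0]
        if fc.size == 0:
            m.founder_freqs = (0.5, 0.5)
        else:
            p1 = float(np.mean(fc == 1))
            m.founder_freqs = (p1, 1.0 - p1)
    return markers


def mendelian_check(pedigree: Pedigree, marker, genotypes: GenotypeMatrix) -> list[str]:
    """Ids of non-founders whose genotype at one marker is impossible.

    A child genotype {x, y} is possible when some orientation assigns one
    allele to each parent such that a typed parent's genotype contains it.
    Missing genotypes (child or parent) never violate.
    """
    marker_id = marker.id if isinstance(marker, Marker) else marker
    violators = []
    for ind in pedigree.nonfounders:
        child = genotypes.get(ind.id, marker_id)
        if child is None:
            continue
        pat = genotypes.get(ind.father_id, marker_id)
        mat = genotypes.get(ind.mother_id, marker_id)
        x, y = child
        ok = False
        for from_father, from_mother in ((x, y), (y, x)):
            if pat is not None and from_father not in pat:
                continue
            if mat is not None and from_mother not in mat:
                continue
            ok = True
            break
        if not ok:
            violators.append(ind.id)
    return violators


@dataclass
class QCReport:
    """Per-reason exclusion counts and per-marker reasons from qc_markers."""

    n_input: int
    n_retained: int
    counts: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "counts": self.counts,
                "reasons": self.reasons,
            },
            indent=2,
        )


def qc_markers(pedigree, markers, genotypes, exclude_chromosomes=None):
    """Drop sex-linked, monomorphic, and Mendelian-inconsistent markers.

    A marker with zero observed alleles counts as monomorphic. Each excluded
    marker is reported under a single reason, checked in the order
    sex_linked, monomorphic, mendelian. Retained order is preserved.

    Returns ``(retained_markers, QCReport)``.
    """
    if exclude_chromosomes is None:
        exclude_chromosomes = SEX_LINKED_CHROMOSOMES
    exclude_chromosomes = {str(c) for c in exclude_chromosomes}
    retained = []
    counts = {"sex_linked": 0, "monomorphic": 0, "mendelian": 0}
    reasons = {}
    for m in markers:
        if str(m.chromosome) in exclude_chromosomes:
            reason = "sex_linked"
        else:
            col = genotypes.column(m.id).ravel()
            observed = np.unique(col[col > 0])
            if observed.size <= 1:
                reason = "monomorphic"
            elif mendelian_check(pedigree, m, genotypes):
                reason = "mendelian"
            else:
                retained.append(m)
                continue
        counts[reason] += 1
        reasons[m.id] = reason
    report = QCReport(len(markers), len(retained), counts, reasons)
    return retained, report
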