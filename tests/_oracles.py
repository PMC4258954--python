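"""Independent brute-force oracles used to validate the likelihood engine.

Everything here enumerates explicitly — founder allele configurations,
parental transmissions, joint inheritance-vector paths — and shares no code
with the package's HMM/union-find machinery.
"""

from __future__ import annotations

import itertools

import numpy as np


def mendelian_possible(child, father, mother, alleles=(1, 2)):
    """Brute-force transmission enumeration for one trio at one marker.

    Each argument is an unordered code pair or None (untyped). Returns True
    when some (paternal, maternal) transmission yields the child genotype.
    """
    if child is None:
        return True
    pat_choices = set(father) if father is not None else set(alleles)
    mat_choices = set(mother) if mother is not None else set(alleles)
    for p in pat_choices:
        for m in mat_choices:
            if tuple(sorted((p, m))) == tuple(sorted(child)):
                return True
    return False


def slot_map(ped, v: int):
    """Founder-slot descent under inheritance vector v (dict-based, recursive)."""
    founders = {f.id: k for k, f in enumerate(ped.founders)}
    bit_of = {ind.id: 2 * i for i, ind in enumerate(ped.nonfounders)}
    pat: dict[str, int] = {}
    mat: dict[str, int] = {}

    def fill(iid):
        if iid in pat:
            return
        ind = ped[iid]
        if ind.is_founder:
            pat[iid] = 2 * founders[iid]
            mat[iid] = 2 * founders[iid] + 1
            return
        fill(ind.father_id)
        fill(ind.mother_id)
        bp = bit_of[iid]
        pat[iid] = pat[ind.father_id] if ((v >> bp) & 1) == 0 else mat[ind.father_id]
        mat[iid] = pat[ind.mother_id] if ((v >> (bp + 1)) & 1) == 0 else mat[ind.mother_id]

    for ind in ped.individuals:
        fill(ind.id)
    return pat, mat


def _slot_bit_table(n_slots):
    cfgs = np.arange(1 << n_slots, dtype=np.int64)
    return (cfgs[:, None] >> np.arange(n_slots)) & 1  # (n_cfg, n_slots)


def disease_likelihood_oracle(ped, v: int, model) -> float:
    """Sum over founder disease-allele configurations, explicitly."""
    n_slots = 2 * len(ped.founders)
    bits = _slot_bit_table(n_slots)
    prior = np.prod(np.where(bits == 1, model.q, 1.0 - model.q), axis=1)
    pat, mat = slot_map(ped, v)
    pen = np.array(model.penetrances)
    total = np.ones(bits.shape[0])
    for ind in ped.individuals:
        status = ind.affection_effective
        if status == "unknown":
            continue
        copies = bits[:, pat[ind.id]] + bits[:, mat[ind.id]]
        f = pen[copies]
        total = total * (f if status == "affected" else (1.0 - f))
    return float((prior * total).sum())


def marker_likelihood_oracle(ped, v: int, marker, genotypes) -> float:
    """Sum over ordered founder allele assignments, explicitly."""
    n_slots = 2 * len(ped.founders)
    bits = _slot_bit_table(n_slots)  # 0 -> allele code 1, 1 -> allele code 2
    f1, f2 = marker.founder_freqs
    prior = np.prod(np.where(bits == 0, f1, f2), axis=1)
    pat, mat = slot_map(ped, v)
    ok = np.ones(bits.shape[0], dtype=bool)
    for ind in ped.individuals:
        if ind.id not in genotypes.sample_ids:
            continue
        g = genotypes.get(ind.id, marker.id)
        if g is None:
            continue
        a = bits[:, pat[ind.id]] + 1
        b = bits[:, mat[ind.id]] + 1
        ok &= (np.minimum(a, b) == g[0]) & (np.maximum(a, b) == g[1])
    return float((prior * ok).sum())


def _haldane(d_cm):
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def transition_matrix_oracle(b, theta):
    """Full 2^b x 2^b per-bit-flip transition matrix via popcounts."""
    s = np.arange(1 << b, dtype=np.uint64)
    flips = np.bitwise_count(s[:, None] ^ s[None, :]).astype(float)
    return (theta**flips) * ((1.0 - theta) ** (b - flips))


def multipoint_lod_oracle(ped, markers, genotypes, model):
    """LOD at each marker by materializing the full joint over all loci.

    Builds the complete (2^b)^L joint probability array over inheritance
    vectors at every locus by broadcasting, marginalizes it per locus, and
    forms the parametric LOD with the enumeration-based phenotype
    likelihood. Only feasible for tiny problems, by design.
    """
    b = ped.bit_count
    S = 1 << b
    L = len(markers)
    if S**L > 2_000_000:
        raise ValueError("oracle problem too large")
    E = np.empty((L, S))
    for j, m in enumerate(markers):
        for v in range(S):
            E[j, v] = marker_likelihood_oracle(ped, v, m, genotypes)
    dl = np.array([disease_likelihood_oracle(ped, v, model) for v in range(S)])
    cms = np.array([m.position_cm for m in markers])

    joint = np.full((S,) * L, 1.0 / S)
    for j in range(L):
        shape = [1] * L
        shape[j] = S
        joint = joint * E[j].reshape(shape)
    for j in range(L - 1):
        theta = _haldane(cms[j + 1] - cms[j])
        T = transition_matrix_oracle(b, theta)
        shape = [1] * L
        shape[j] = S
        shape[j + 1] = S
        joint = joint * T.reshape(shape)

    denom = dl.mean()  # sum_v 2^-b DL(v)
    lods = np.empty(L)
    for j in range(L):
        axes = tuple(k for k in range(L) if k != j)
        marg = joint.sum(axis=axes)
        post = marg / marg.sum()
        lods[j] = np.log10(post @ dl) - np.log10(denom)
    return lods
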