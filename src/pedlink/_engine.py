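"""Low-level kernels for inheritance-vector computations.

Everything here is indexed numerics: individuals are row indices, founder
allele slots are integers (founder ``k`` owns slots ``2k`` and ``2k+1``),
and an inheritance vector ``v`` is an integer whose bit ``2i`` (``2i+1``)
records the paternal (maternal) meiosis of the i-th non-founder — bit 0
means the grandpaternal allele was transmitted.

The marker emission kernel exploits the biallelic structure: a genotyped
individual either forces its two founder slots to one allele (homozygote)
or constrains them to differ (heterozygote), so the founder-allele graph is
a parity (2-coloring) problem solved by weighted union-find in O(alpha) per
constraint instead of enumerating allele assignments. The disease-locus
kernel carries arbitrary penetrance factors, so it enumerates assignments
within each connected component of the founder-slot graph.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "compute_slots",
    "marker_emission_all_v",
    "disease_likelihood_all_v",
    "apply_transition",
    "haldane_theta",
]


def haldane_theta(d_cm):
    """Recombination fraction from map distance (cM), no interference."""
    d_morgan = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def compute_slots(pedigree, v_values=None):
    """Founder-slot indices of every individual for each inheritance vector.

    Returns ``(slot_pat, slot_mat, founder_index)`` where the slot arrays
    have shape ``(n_individuals, len(v_values))`` (int16) giving, for each
    vector, which founder allele slot each individual's paternal/maternal
    allele descends from. ``v_values`` defaults to all ``2**b`` vectors.
    """
    b = pedigree.bit_count
    if v_values is None:
        v_values = np.arange(1 << b, dtype=np.int64)
    else:
        v_values = np.asarray(v_values, dtype=np.int64)
    n = len(pedigree.individuals)
    row = {ind.id: i for i, ind in enumerate(pedigree.individuals)}
    founder_index = {f.id: k for k, f in enumerate(pedigree.founders)}
    nf_bit = {ind.id: 2 * i for i, ind in enumerate(pedigree.nonfounders)}

    slot_pat = np.empty((n, v_values.size), dtype=np.int16)
    slot_mat = np.empty((n, v_values.size), dtype=np.int16)
    for iid in pedigree.topological_ids():
        ind = pedigree[iid]
        i = row[iid]
        if ind.is_founder:
            k = founder_index[iid]
            slot_pat[i] = 2 * k
            slot_mat[i] = 2 * k + 1
        else:
            bp = nf_bit[iid]
            fa, mo = row[ind.father_id], row[ind.mother_id]
            pat_bit = (v_values >> bp) & 1
            mat_bit = (v_values >> (bp + 1)) & 1
            slot_pat[i] = np.where(pat_bit == 0, slot_pat[fa], slot_mat[fa])
            slot_mat[i] = np.where(mat_bit == 0, slot_pat[mo], slot_mat[mo])
    return slot_pat, slot_mat, founder_index


@njit(cache=True, inline="always")
def _find(parent, parity, s):
    r = s
    p = 0
    while parent[r] != r:
        p ^= parity[r]
        r = parent[r]
    # path compression
    cur = s
    cp = p
    while parent[cur] != r:
        nxt = parent[cur]
        np_ = cp ^ parity[cur]
        parent[cur] = r
        parity[cur] = cp
        cur = nxt
        cp = np_
    return r, p


@njit(cache=True)
def _marker_emission_kernel(slot_pat, slot_mat, gcodes, f1, f2, n_slots, out):
    """P(one marker's genotypes | v) for every v (biallelic parity graph).

    gcodes: 1 = hom first allele, 2 = het, 3 = hom second allele (missing
    individuals are excluded upstream). f1/f2: population frequencies of the
    marker's two alleles.
    """
    n_ind, n_v = slot_pat.shape
    parent = np.empty(n_slots, dtype=np.int16)
    parity = np.empty(n_slots, dtype=np.int8)
    forced = np.empty(n_slots, dtype=np.int8)
    w1 = np.empty(n_slots, dtype=np.float64)
    w2 = np.empty(n_slots, dtype=np.float64)
    touched = np.zeros(n_slots, dtype=np.int8)
    tlist = np.empty(n_slots, dtype=np.int16)

    for v in range(n_v):
        ntouch = 0
        dead = False
        for i in range(n_ind):
            s1 = slot_pat[i, v]
            s2 = slot_mat[i, v]
            for s in (s1, s2):
                if touched[s] == 0:
                    touched[s] = 1
                    parent[s] = s
                    parity[s] = 0
                    forced[s] = -1
                    w1[s] = f1
                    w2[s] = f2
                    tlist[ntouch] = s
                    ntouch += 1
            g = gcodes[i]
            if g == 2:  # het: slots must differ
                if s1 == s2:
                    dead = True
                    break
                r1, p1 = _find(parent, parity, s1)
                r2, p2 = _find(parent, parity, s2)
                if r1 == r2:
                    if (p1 ^ p2) != 1:
                        dead = True
                        break
                else:
                    adj = p1 ^ p2 ^ 1
                    parent[r2] = r1
                    parity[r2] = adj
                    if adj == 0:
                        w1[r1] *= w1[r2]
                        w2[r1] *= w2[r2]
                    else:
                        w1[r1] *= w2[r2]
                        w2[r1] *= w1[r2]
                    if forced[r2] >= 0:
                        fc = forced[r2] ^ adj
                        if forced[r1] == -1:
                            forced[r1] = fc
                        elif forced[r1] != fc:
                            dead = True
                            break
            else:  # hom: both slots carry allele a (0-based)
                a = 0 if g == 1 else 1
                if s1 != s2:
                    r1, p1 = _find(parent, parity, s1)
                    r2, p2 = _find(parent, parity, s2)
                    if r1 == r2:
                        if (p1 ^ p2) != 0:
                            dead = True
                            break
                    else:
                        adj = p1 ^ p2
                        parent[r2] = r1
                        parity[r2] = adj
                        if adj == 0:
                            w1[r1] *= w1[r2]
                            w2[r1] *= w2[r2]
                        else:
                            w1[r1] *= w2[r2]
                            w2[r1] *= w1[r2]
                        if forced[r2] >= 0:
                            fc = forced[r2] ^ adj
                            if forced[r1] == -1:
                                forced[r1] = fc
                            elif forced[r1] != fc:
                                dead = True
                                break
                r, p = _find(parent, parity, s1)
                c = a ^ p
                if forced[r] == -1:
                    forced[r] = c
                elif forced[r] != c:
                    dead = True
                    break

        if dead:
            out[v] = 0.0
        else:
            prob = 1.0
            for t in range(ntouch):
                s = tlist[t]
                if parent[s] == s:
                    if forced[s] == 0:
                        prob *= w1[s]
                    elif forced[s] == 1:
                        prob *= w2[s]
                    else:
                        prob *= w1[s] + w2[s]
            out[v] = prob
        for t in range(ntouch):
            touched[tlist[t]] = 0


def marker_emission_all_v(slot_pat, slot_mat, gcodes, freqs):
    """Vector of P(marker genotypes | v) over the given slot arrays.

    Rows of ``slot_pat``/``slot_mat`` correspond to the entries of
    ``gcodes`` (only genotyped individuals). Returns float64 of length n_v.
    """
    n_slots = int(max(slot_pat.max(initial=0), slot_mat.max(initial=0))) + 1
    out = np.empty(slot_pat.shape[1], dtype=np.float64)
    if len(gcodes) == 0:
        out[:] = 1.0
        return out
    _marker_emission_kernel(
        np.ascontiguousarray(slot_pat),
        np.ascontiguousarray(slot_mat),
        np.asarray(gcodes, dtype=np.int8),
        float(freqs[0]),
        float(freqs[1]),
        n_slots,
        out,
    )
    return out


@njit(cache=True)
def _disease_kernel(slot_pat, slot_mat, factors, q, n_slots, max_component, out):
    """P(affection phenotypes | v) for every v.

    factors[i, c]: phenotype probability of individual i given c copies of
    the disease allele. Founder slots carry the disease allele with
    probability q, independently; the sum over founder configurations
    factorizes over connected components of the slot graph, and assignments
    are enumerated within each component.
    """
    n_ind, n_v = slot_pat.shape
    parent = np.empty(n_slots, dtype=np.int16)
    touched = np.zeros(n_slots, dtype=np.int8)
    tlist = np.empty(n_slots, dtype=np.int16)
    comp_slots = np.empty(n_slots, dtype=np.int16)
    local = np.empty(n_slots, dtype=np.int16)

    for v in range(n_v):
        ntouch = 0
        for i in range(n_ind):
            s1 = slot_pat[i, v]
            s2 = slot_mat[i, v]
            for s in (s1, s2):
                if touched[s] == 0:
                    touched[s] = 1
                    parent[s] = s
                    tlist[ntouch] = s
                    ntouch += 1
            # plain union (no parity needed)
            r1 = s1
            while parent[r1] != r1:
                r1 = parent[r1]
            r2 = s2
            while parent[r2] != r2:
                r2 = parent[r2]
            if r1 != r2:
                parent[r2] = r1

        prob = 1.0
        too_big = False
        for t in range(ntouch):
            root = tlist[t]
            if parent[root] != root:
                continue
            # gather this component's slots
            k = 0
            for u in range(ntouch):
                s = tlist[u]
                r = s
                while parent[r] != r:
                    r = parent[r]
                if r == root:
                    comp_slots[k] = s
                    local[s] = k
                    k += 1
            if k > max_component:
                # 2**k assignments would be intractable; signal to caller
                too_big = True
                break
            comp_sum = 0.0
            for a in range(1 << k):
                w = 1.0
                for j in range(k):
                    if (a >> j) & 1:
                        w *= q
                    else:
                        w *= 1.0 - q
                for i in range(n_ind):
                    s1 = slot_pat[i, v]
                    r = s1
                    while parent[r] != r:
                        r = parent[r]
                    if r == root:
                        c = ((a >> local[s1]) & 1) + ((a >> local[slot_mat[i, v]]) & 1)
                        w *= factors[i, c]
                comp_sum += w
            prob *= comp_sum
        if too_big:
            out[v] = -1.0
        else:
            out[v] = prob
        for t in range(ntouch):
            touched[tlist[t]] = 0


def disease_likelihood_all_v(slot_pat, slot_mat, factors, q):
    """Vector of P(phenotypes | v); rows are phenotyped individuals only."""
    out = np.empty(slot_pat.shape[1], dtype=np.float64)
    if slot_pat.shape[0] == 0:
        out[:] = 1.0
        return out
    n_slots = int(max(slot_pat.max(initial=0), slot_mat.max(initial=0))) + 1
    _disease_kernel(
        np.ascontiguousarray(slot_pat),
        np.ascontiguousarray(slot_mat),
        np.asarray(factors, dtype=np.float64),
        float(q),
        n_slots,
        24,
        out,
    )
    if np.any(out < 0):
        raise ValueError(
            "founder-slot component too large to enumerate; "
            "reduce the number of connected phenotyped individuals"
        )
    return out


def apply_transition(x, theta, b):
    """One HMM transition: each inheritance bit flips independently w.p. theta."""
    if b == 0:
        return x.copy()
    arr = x.reshape((2,) * b)
    for axis in range(b):
        arr = (1.0 - theta) * arr + theta * np.flip(arr, axis=axis)
    return arr.reshape(-1)


def founder_symmetry_layout(pedigree):
    """Quotient coordinates under founder-phase symmetry.

    Swapping a founder's two alleles while flipping every meiosis that
    founder transmits leaves all emission and penetrance terms unchanged
    (genotypes are unordered, founder slots are exchangeable), and the
    per-bit transition kernel commutes with the flip. The HMM can therefore
    run on the quotient space: per transmitting founder, the first child
    meiosis (the anchor) is dropped and the remaining ones are kept as
    bits *relative* to the anchor; meioses from non-founder parents keep
    absolute bits.

    Returns ``(coord_bits, groups)``: the original bit positions of the
    quotient axes, and for each founder with two or more child meioses the
    list of quotient axis indices of its relative bits. Representatives are
    obtained by setting anchors to 0, i.e. placing quotient bits at their
    original positions.
    """
    nonfounders = pedigree.nonfounders
    founder_ids = {f.id for f in pedigree.founders}
    by_founder: dict[str, list[int]] = {}
    anchored = set()
    for i, ind in enumerate(nonfounders):
        for bit, parent in ((2 * i, ind.father_id), (2 * i + 1, ind.mother_id)):
            if parent in founder_ids:
                by_founder.setdefault(parent, []).append(bit)
    for bits in by_founder.values():
        anchored.add(min(bits))
    coord_bits = [bit for bit in range(2 * len(nonfounders)) if bit not in anchored]
    axis_of = {bit: j for j, bit in enumerate(coord_bits)}
    groups = [
        [axis_of[bit] for bit in sorted(bits)[1:]]
        for bits in by_founder.values()
        if len(bits) >= 2
    ]
    return coord_bits, groups


def representative_vectors(coord_bits):
    """All quotient states as full-space representative vectors (anchors 0)."""
    m = len(coord_bits)
    y = np.arange(1 << m, dtype=np.int64)
    v = np.zeros_like(y)
    for j, bit in enumerate(coord_bits):
        v |= ((y >> j) & 1) << bit
    return v


def apply_transition_quotient(x, theta, m, groups):
    """Transition on the founder-symmetry quotient space.

    Relative bits within a founder's group flip together when the anchor
    meiosis recombines: after the usual independent per-axis mixing, each
    group is blended with its jointly-flipped image with weight theta.
    ``groups`` lists quotient *bit* indices (bit j of the flat state index);
    a C-ordered reshape puts bit j on array axis m-1-j.
    """
    if m == 0:
        return x.copy()
    arr = x.reshape((2,) * m)
    for axis in range(m):
        arr = (1.0 - theta) * arr + theta * np.flip(arr, axis=axis)
    for bits in groups:
        if bits:
            axes = tuple(m - 1 - j for j in bits)
            arr = (1.0 - theta) * arr + theta * np.flip(arr, axis=axes)
    return arr.reshape(-1)
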