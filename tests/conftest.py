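"""Shared fixtures: tiny pedigrees, random small instances, study replicates."""

from __future__ import annotations

import numpy as np
import pytest

from pedlink.linkage import DiseaseModel
from pedlink.pedigree import Individual, Marker, Pedigree
from pedlink.synthetic import ChromosomeSpec, SimulationConfig, gene_drop


def make_pedigree(rows):
    """rows: (id, father, mother[, affection[, sex]]) tuples."""
    inds = []
    for r in rows:
        iid, fa, mo = r[:3]
        aff = r[3] if len(r) > 3 else "unknown"
        sex = r[4] if len(r) > 4 else "unknown"
        inds.append(Individual(iid, fa, mo, sex=sex, affection=aff))
    return Pedigree(inds)


def random_small_pedigree(rng, max_nonfounders=3):
    """Random pedigree with <= 8 members and <= max_nonfounders non-founders."""
    rows = [("F1", None, None), ("F2", None, None)]
    couples = [("F1", "F2")]
    n_nf = int(rng.integers(1, max_nonfounders + 1))
    nxt = 1
    for _ in range(n_nf):
        fa, mo = couples[int(rng.integers(len(couples)))]
        cid = f"N{nxt}"
        nxt += 1
        rows.append((cid, fa, mo))
        if rng.random() < 0.5 and len(rows) < 7:
            sid = f"S{nxt}"
            nxt += 1
            rows.append((sid, None, None))
            couples.append((cid, sid))
    return make_pedigree(rows)


def random_instance(seed, max_nonfounders=3, max_markers=3):
    """A random small linkage problem the joint-enumeration oracle can handle.

    Genotypes come from a gene drop (guaranteeing Mendelian consistency)
    with random marker spacing and missingness; a fraction of affection
    statuses is blanked to unknown.
    """
    rng = np.random.default_rng(seed)
    ped = random_small_pedigree(rng, max_nonfounders)
    b = ped.bit_count
    max_L = max_markers if (1 << b) ** max_markers <= 2_000_000 else 2
    L = int(rng.integers(2, max_L + 1))
    spacing = float(rng.uniform(2.0, 40.0))
    spec = ChromosomeSpec("1", n_markers=L, spacing_cm=spacing, maf_range=(0.1, 0.5))
    config = SimulationConfig(
        pedigree=ped,
        typed_ids=tuple(ped.ids),
        chromosomes=(spec,),
        causal_chromosome="1",
        causal_cm=float(rng.uniform(0.0, spec.length_cm)),
        missing_rate=0.15,
        min_affected_typed=None,
        seed=int(rng.integers(2**31)),
    )
    sim = gene_drop(config)
    statuses = {
        iid: ("unknown" if rng.random() < 0.25 else sim.true_affection[iid])
        for iid in ped.ids
    }
    return sim.pedigree.with_affection(statuses), sim.markers, sim.genotypes, DiseaseModel()


@pytest.fixture(scope="session")
def study_replicates():
    """100 seeded full-pipeline replicates under the default study conditions.

    Shared by the linkage parameter-recovery and end-to-end recovery checks
    (both consume the same replicates, which is also how a simulation study
    would report them).
    """
    from pedlink.pipeline import run_study_replicate

    return [run_study_replicate(seed) for seed in range(100)]
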