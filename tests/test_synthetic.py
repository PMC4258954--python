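"""Gene-dropping simulator and exome-table generator."""

import numpy as np
import pytest

from pedlink.exceptions import ConfigurationError
from pedlink.linkage import DiseaseModel
from pedlink.pedigree import Individual, Pedigree, mendelian_check, read_ped_map
from pedlink.synthetic import (
    DEFAULT_TYPED_IDS,
    STUDY_AFFECTION_TEMPLATE,
    ChromosomeSpec,
    SimulationConfig,
    VariantTableConfig,
    default_family_design,
    gene_drop,
    make_variant_tables,
    study_template_pedigree,
)
from pedlink.variants import run_cascade
from pedlink.followup import replicate_genes


def founders_only(n):
    return Pedigree([Individual(f"f{i}") for i in range(n)])


class TestGeneDrop:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=42)
        a = gene_drop(cfg)
        b = gene_drop(cfg)
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("family.ped", "family.map", "affection.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        # and a different seed changes the data
        c = gene_drop(SimulationConfig(seed=43))
        assert not np.array_equal(a.genotypes.codes, c.genotypes.codes)

    def test_q_zero_gives_phenocopy_rate_only(self):
        """With no disease allele, the affected fraction is the phenocopy rate."""
        n = 10_000
        cfg = SimulationConfig(
            pedigree=founders_only(n),
            typed_ids=None,
            chromosomes=(ChromosomeSpec("1", n_markers=1),),
            causal_cm=0.0,
            disease_model=DiseaseModel(q=0.0),
            affection_template=None,
            min_affected_typed=None,
            missing_rate=0.0,
            seed=5,
        )
        sim = gene_drop(cfg)
        assert all(c == 0 for c in sim.causal_copies.values())
        frac = np.mean([s == "affected" for s in sim.true_affection.values()])
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(frac - 0.005) < 4 * se

    def test_recombinant_fraction_matches_haldane(self):
        """Markers 10 cM apart: theta = (1 - e^-0.2)/2 ~ 0.0906."""
        rows = [Individual("F"), Individual("M")] + [
            Individual(f"c{i}", "F", "M") for i in range(5000)
        ]
        cfg = SimulationConfig(
            pedigree=Pedigree(rows),
            typed_ids=None,
            chromosomes=(ChromosomeSpec("1", n_markers=2, spacing_cm=10.0),),
            causal_cm=0.0,
            affection_template=None,
            min_affected_typed=None,
            missing_rate=0.0,
            seed=11,
        )
        sim = gene_drop(cfg)
        bits = sim.transmission_bits["1"]  # (10000 meioses, 2 loci)
        assert bits.shape == (10_000, 2)
        frac = np.mean(bits[:, 0] != bits[:, 1])
        theta = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(theta * (1 - theta) / 10_000)
        assert abs(frac - theta) < 4 * se

    def test_no_missingness_is_mendelian_clean(self):
        cfg = SimulationConfig(seed=3, missing_rate=0.0)
        sim = gene_drop(cfg)
        for m in sim.markers[::50]:
            assert mendelian_check(sim.pedigree, m, sim.genotypes) == []

    def test_founder_allele_frequency_recovery(self):
        """Estimated founder frequencies match the configured values (3 SE)."""
        n = 1000
        cfg = SimulationConfig(
            pedigree=founders_only(n),
            typed_ids=None,
            chromosomes=(ChromosomeSpec("1", n_markers=20),),
            causal_cm=0.0,
            affection_template=None,
            min_affected_typed=None,
            missing_rate=0.0,
            seed=21,
        )
        sim = gene_drop(cfg)
        for m in sim.markers:
            col = sim.genotypes.column(m.id).ravel()
            est = np.mean(col == 1)
            p = m.founder_freqs[0]
            se = np.sqrt(p * (1 - p) / (2 * n))
            assert abs(est - p) < 3 * se, m.id

    def test_causal_locus_off_map_rejected(self):
        with pytest.raises(ConfigurationError, match="off the simulated map"):
            gene_drop(SimulationConfig(causal_chromosome="99", seed=0))
        with pytest.raises(ConfigurationError, match="off the simulated map"):
            gene_drop(SimulationConfig(causal_cm=1e6, seed=0))

    def test_template_shape(self):
        ped = study_template_pedigree()
        study_members = [i for i in ped.ids if not i.startswith("I:")]
        assert len(study_members) == 17
        males = [i for i in ped if i.sex == "male" and not i.id.startswith("I:")]
        assert len(males) == 5
        assert set(DEFAULT_TYPED_IDS) <= set(ped.ids)
        # III:3 can carry the founder haplotype and has affected-able child IV:6
        assert ped["IV:6"].father_id == "III:3"
        assert ped["IV:3"].father_id == "III:2"

    def test_ascertained_draw_meets_conditions(self):
        sim = gene_drop(SimulationConfig(seed=7))
        affected = [
            i for i in DEFAULT_TYPED_IDS
            if sim.affection_recorded[i] == "affected"
        ]
        assert len(affected) >= 6
        assert not any(sim.pedigree[i].is_founder for i in affected)
        # untyped members are recorded as unconfirmed
        untyped = set(sim.pedigree.ids) - set(DEFAULT_TYPED_IDS)
        assert all(sim.affection_recorded[i] == "unconfirmed" for i in untyped)

    def test_written_files_read_back(self, tmp_path):
        sim = gene_drop(SimulationConfig(seed=9))
        sim.write(tmp_path)
        ped, markers, gm = read_ped_map(tmp_path / "family.ped", tmp_path / "family.map")
        assert len(ped) == len(sim.pedigree)
        assert len(markers) == len(sim.markers)

    def test_phenotype_conditional_mode_reproduces_pattern(self):
        sim = gene_drop(SimulationConfig(affection_template="study", seed=13))
        for iid, status in STUDY_AFFECTION_TEMPLATE.items():
            assert sim.affection_recorded[iid] == status
        # the affected share a causal allele far more often than not: the
        # posterior strongly favors a segregating configuration
        affected = [i for i, s in STUDY_AFFECTION_TEMPLATE.items() if s == "affected"]
        carriers = [i for i in affected if sim.causal_copies[i] > 0]
        assert len(carriers) >= len(affected) - 1


def test_simulation_config_loads_from_json():
    from pedlink.synthetic import load_simulation_config

    cfg = load_simulation_config(
        '{"seed": 5, "missing_rate": 0.0,'
        ' "chromosomes": [{"name": "1", "n_markers": 10, "spacing_cm": 2.0}],'
        ' "causal_cm": 4.0, "disease_model": {"q": 0.01}}'
    )
    assert cfg.seed == 5
    assert cfg.chromosomes[0].n_markers == 10
    assert cfg.disease_model.q == 0.01
    sim = gene_drop(cfg)
    assert len(sim.markers) == 10
    with pytest.raises(ConfigurationError, match="unknown"):
        load_simulation_config('{"bogus": 1}')


class TestMakeVariantTables:
    REGIONS = [("1", 181_329_186, 211_652_185)]

    def test_planted_rare_variant_is_unique_cascade_survivor(self):
        cfg = VariantTableConfig(seed=1)
        tables = make_variant_tables(cfg, regions=self.REGIONS)
        candidates, reports = run_cascade(
            tables.family, tables.design, self.REGIONS, cfg.panel, cfg.maf_max
        )
        assert [c.variant.key for c in candidates] == [tables.planted.key]
        assert "rare" in candidates[0].branches
        assert tables.planted.gene == "HMCN1"
        for report in reports:
            assert report.is_monotone()

    def test_planted_novel_variant_survives(self):
        cfg = VariantTableConfig(seed=2, planted_branch="novel")
        tables = make_variant_tables(cfg, regions=self.REGIONS)
        candidates, _ = run_cascade(
            tables.family, tables.design, self.REGIONS, cfg.panel, cfg.maf_max
        )
        assert [c.variant.key for c in candidates] == [tables.planted.key]
        assert tables.planted.is_novel

    def test_replication_pattern_three_of_four(self):
        cfg = VariantTableConfig(seed=3)
        tables = make_variant_tables(cfg, regions=self.REGIONS)
        res = replicate_genes(tables.unrelated, {"HMCN1"}, panel="European")
        assert res.support_count("HMCN1") == 3

    def test_determinism(self):
        cfg = VariantTableConfig(seed=4)
        t1 = make_variant_tables(cfg, regions=self.REGIONS)
        t2 = make_variant_tables(cfg, regions=self.REGIONS)
        assert [v.key for v in t1.family] == [v.key for v in t2.family]
        assert all(
            v1.genotypes == v2.genotypes for v1, v2 in zip(t1.family, t2.family)
        )

    def test_novel_plant_with_forced_rsid_rejected(self):
        cfg = VariantTableConfig(
            seed=5, planted_branch="novel", planted_dbsnp_id="rs1"
        )
        with pytest.raises(ConfigurationError, match="novel"):
            make_variant_tables(cfg, regions=self.REGIONS)

    def test_plant_without_regions_rejected(self):
        with pytest.raises(ConfigurationError, match="region"):
            make_variant_tables(VariantTableConfig(seed=6), regions=None)

    def test_background_survivors_match_analytic_expectation(self):
        """Without a plant, the cascade's survivor count is what the
        generating mix predicts (per-variant survival probabilities given
        the drawn annotations and allele frequencies)."""
        from pedlink.variants import (
            FUNCTIONAL_SNV_CLASSES,
            INDEL_CLASSES,
            GT_HET,
            GT_HOM,
        )

        design = default_family_design()
        cfg = VariantTableConfig(
            seed=0, plant=False, unrelated_samples=(),
            n_background=400, genotype_missing_rate=0.0,
        )
        regions = [("1", 1, 240_000_000)]  # wide region: survival not vanishing
        observed = 0
        expected = 0.0
        for rep in range(25):
            tables = make_variant_tables(cfg, regions=regions, seed=1000 + rep)
            candidates, _ = run_cascade(
                tables.family, design, regions, cfg.panel, cfg.maf_max
            )
            observed += len(candidates)
            for v in tables.family:
                if v.func_class not in FUNCTIONAL_SNV_CLASSES | INDEL_CLASSES:
                    continue
                f = v.maf.get(cfg.panel)
                if not (v.is_novel or f is None or f <= cfg.maf_max):
                    continue
                if not (v.chromosome == "1" and v.position_bp <= 240_000_000):
                    continue
                af = tables.alt_freqs[v.key]
                p_carrier = 2 * af * (1 - af) + af * af
                expected += (
                    p_carrier ** len(design.affected)
                    * (1 - p_carrier) ** len(design.unaffected)
                )
        # genotypes were realized by the generator; compare observed count
        # against the analytic expectation under the same annotations
        sd = np.sqrt(max(expected, 1.0))
        assert abs(observed - expected) < 5 * sd
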