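"""Exome prioritization cascade: filters, branches, reports, I/O."""

import numpy as np
import pytest

from pedlink.exceptions import ConfigurationError, ParameterError
from pedlink.variants import (
    GT_HET,
    GT_HOM,
    GT_MISSING,
    GT_REF,
    STAGE_NOVEL,
    STAGE_REGION,
    STAGE_SHARED,
    AnnotatedVariant,
    CohortDesign,
    functional_filter,
    novelty_branch,
    rarity_branch,
    read_variant_tables,
    region_filter,
    run_cascade,
    segregation_filter,
    write_variant_tables,
)

ALL_CLASSES = [
    "nonsynonymous_SNV", "stopgain", "stoploss", "splicing",
    "synonymous_SNV", "other", "frameshift_indel", "nonframeshift_indel",
]


def mkvar(pos=100, chrom="1", func_class="nonsynonymous_SNV", gene="G1",
          dbsnp=None, kg=False, maf=None, genotypes=None, ref="A", alt="C"):
    if func_class in ("frameshift_indel", "nonframeshift_indel"):
        ref, alt = "A", "AT" if func_class == "frameshift_indel" else "ATTT"
    return AnnotatedVariant(
        chromosome=chrom, position_bp=pos, ref=ref, alt=alt, gene=gene,
        func_class=func_class, dbsnp_id=dbsnp, in_thousand_genomes=kg,
        maf=maf or {}, genotypes=genotypes or {},
    )


class TestFunctionalFilter:
    def test_one_variant_per_class(self):
        variants = [mkvar(pos=i, func_class=c) for i, c in enumerate(ALL_CLASSES, 1)]
        snvs, indels = functional_filter(variants)
        assert {v.func_class for v in snvs} == {
            "nonsynonymous_SNV", "stopgain", "stoploss", "splicing",
        }
        assert {v.func_class for v in indels} == {
            "frameshift_indel", "nonframeshift_indel",
        }
        assert len(snvs) == 4 and len(indels) == 2

    def test_empty_input(self):
        assert functional_filter([]) == ([], [])

    def test_500_random_variants_match_predicate(self):
        rng = np.random.default_rng(0)
        variants = [
            mkvar(pos=i, func_class=ALL_CLASSES[rng.integers(len(ALL_CLASSES))])
            for i in range(500)
        ]
        snvs, indels = functional_filter(variants)
        assert [v.key for v in snvs] == [
            v.key for v in variants
            if v.func_class in {"nonsynonymous_SNV", "stopgain", "stoploss", "splicing"}
        ]
        assert [v.key for v in indels] == [
            v.key for v in variants
            if v.func_class in {"frameshift_indel", "nonframeshift_indel"}
        ]

    def test_indel_cannot_be_nonsynonymous(self):
        with pytest.raises(ParameterError, match="indel"):
            AnnotatedVariant("1", 1, "A", "AT", "G", "nonsynonymous_SNV")


class TestNoveltyAndRarity:
    def test_novelty(self):
        known = mkvar(pos=1, dbsnp="rs1", kg=True)
        kg_only = mkvar(pos=2, dbsnp=None, kg=True)
        novel = mkvar(pos=3)
        assert novelty_branch([known, kg_only, novel]) == [novel]

    def test_mixed_panel_matches_comprehension(self):
        rng = np.random.default_rng(1)
        variants = [
            mkvar(pos=i, dbsnp="rs%d" % i if rng.random() < 0.5 else None,
                  kg=bool(rng.random() < 0.5))
            for i in range(20)
        ]
        assert [v.key for v in novelty_branch(variants)] == [
            v.key for v in variants if v.dbsnp_id is None and not v.in_thousand_genomes
        ]

    def test_rare_japanese_variant_kept(self):
        """MAF 0.018 in the Japanese panel passes the 2% filter (as R5205H did)."""
        v = mkvar(maf={"Japanese": 0.018}, dbsnp="rs150188026", kg=True)
        assert rarity_branch([v], "Japanese") == [v]

    def test_boundary_inclusive_and_excluded(self):
        at = mkvar(pos=1, maf={"Japanese": 0.02})
        over = mkvar(pos=2, maf={"Japanese": 0.05})
        null = mkvar(pos=3, maf={"Japanese": None})
        assert rarity_branch([at, over, null], "Japanese") == [at, null]

    def test_unknown_panel_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="panel"):
            rarity_branch([mkvar(maf={"Japanese": 0.01})], "Martian")


class TestRegionFilter:
    REGIONS = [("1", 181_329_186, 211_652_185), ("14", 36_888_532, 56_953_253)]

    def test_inclusive_lower_bound(self):
        inside = mkvar(pos=181_329_186, chrom="1")
        outside = mkvar(pos=181_329_185, chrom="1")
        assert region_filter([inside, outside], self.REGIONS) == [inside]

    def test_inclusive_upper_bound(self):
        edge = mkvar(pos=211_652_185, chrom="1")
        past = mkvar(pos=211_652_186, chrom="1")
        assert region_filter([edge, past], self.REGIONS) == [edge]

    def test_chromosome_must_match(self):
        v = mkvar(pos=181_400_000, chrom="2")
        assert region_filter([v], self.REGIONS) == []

    def test_random_positions_match_linear_scan(self):
        rng = np.random.default_rng(2)
        variants = [
            mkvar(pos=int(rng.integers(1, 250_000_000)),
                  chrom=str(rng.choice(["1", "14", "2"])))
            for _ in range(300)
        ]
        got = {v.key for v in region_filter(variants, self.REGIONS)}
        expected = {
            v.key for v in variants
            if any(
                v.chromosome == c and lo <= v.position_bp <= hi
                for c, lo, hi in self.REGIONS
            )
        }
        assert got == expected


DESIGN = CohortDesign(
    affected=("A1", "A2", "A3", "A4"),
    unaffected=("U1", "U2"),
    unconfirmed=("X1",),
)


def geno(affected=GT_HET, unaffected=GT_REF, unconfirmed=GT_REF, **overrides):
    g = {s: affected for s in DESIGN.affected}
    g.update({s: unaffected for s in DESIGN.unaffected})
    g.update({s: unconfirmed for s in DESIGN.unconfirmed})
    g.update(overrides)
    return g


class TestSegregationFilter:
    def test_shared_by_affected_absent_in_unaffected_kept(self):
        v = mkvar(genotypes=geno())
        assert segregation_filter([v], DESIGN) == [v]

    def test_hom_alt_affected_satisfies_sharing(self):
        v = mkvar(genotypes=geno(affected=GT_HOM))
        assert segregation_filter([v], DESIGN) == [v]

    def test_three_of_four_affected_excluded(self):
        v = mkvar(genotypes=geno(A4=GT_REF))
        assert segregation_filter([v], DESIGN) == []

    def test_missing_affected_fails_closed(self):
        v = mkvar(genotypes=geno(A2=GT_MISSING))
        assert segregation_filter([v], DESIGN) == []

    def test_carrier_unaffected_excluded(self):
        v = mkvar(genotypes=geno(U1=GT_HET))
        assert segregation_filter([v], DESIGN) == []

    def test_unconfirmed_ignored(self):
        carrier = mkvar(pos=1, genotypes=geno(X1=GT_HOM))
        missing = mkvar(pos=2, genotypes=geno(X1=GT_MISSING))
        assert segregation_filter([carrier, missing], DESIGN) == [carrier, missing]

    def test_sample_missing_from_mapping_is_configuration_error(self):
        g = geno()
        del g["A1"]
        with pytest.raises(ConfigurationError, match="A1"):
            segregation_filter([mkvar(genotypes=g)], DESIGN)

    def test_random_fixture_matches_per_sample_predicate(self):
        rng = np.random.default_rng(3)
        states = [GT_REF, GT_HET, GT_HOM, GT_MISSING]
        variants = [
            mkvar(pos=i, genotypes={
                s: states[rng.integers(4)] for s in DESIGN.all_samples
            })
            for i in range(50)
        ]
        got = {v.key for v in segregation_filter(variants, DESIGN)}
        expected = set()
        for v in variants:
            ok = all(v.genotypes[s] in (GT_HET, GT_HOM) for s in DESIGN.affected)
            ok &= all(v.genotypes[s] not in (GT_HET, GT_HOM) for s in DESIGN.unaffected)
            if ok:
                expected.add(v.key)
        assert got == expected


class TestRunCascade:
    REGIONS = [("1", 100, 200)]

    def test_empty_table(self):
        candidates, (novel, rare) = run_cascade([], DESIGN, self.REGIONS, "Japanese")
        assert candidates == []
        for report in (novel, rare):
            assert all(
                count == 0
                for counts in report.counts.values()
                for count in counts.values()
            )

    def test_report_uses_study_stage_labels(self):
        _, (novel, _) = run_cascade([], DESIGN, self.REGIONS, "Japanese")
        assert STAGE_NOVEL in novel.stages
        assert STAGE_REGION in novel.stages
        assert STAGE_SHARED in novel.stages
        assert novel.stages.index(STAGE_NOVEL) < novel.stages.index(STAGE_REGION)
        assert novel.stages.index(STAGE_REGION) < novel.stages.index(STAGE_SHARED)

    def _random_table(self, rng, n=60):
        states = [GT_REF, GT_HET, GT_HOM, GT_MISSING]
        out = []
        for i in range(n):
            maf = None if rng.random() < 0.3 else float(rng.uniform(0, 0.4))
            out.append(
                mkvar(
                    pos=int(rng.integers(1, 400)),
                    chrom=str(rng.choice(["1", "2"])),
                    func_class=ALL_CLASSES[rng.integers(len(ALL_CLASSES))],
                    dbsnp="rs%d" % i if rng.random() < 0.6 else None,
                    kg=bool(rng.random() < 0.5),
                    maf={"Japanese": maf},
                    genotypes={s: states[rng.integers(4)] for s in DESIGN.all_samples},
                )
            )
        # keys may repeat positions; make unique
        seen = set()
        unique = []
        for v in out:
            if v.key not in seen:
                seen.add(v.key)
                unique.append(v)
        return unique

    @pytest.mark.parametrize("seed", range(25))
    def test_counts_monotone_through_stages(self, seed):
        rng = np.random.default_rng(seed)
        variants = self._random_table(rng)
        _, reports = run_cascade(variants, DESIGN, self.REGIONS, "Japanese")
        for report in reports:
            assert report.is_monotone(), report.to_tsv()

    def test_row_order_independence(self):
        rng = np.random.default_rng(99)
        variants = self._random_table(rng)
        c1, _ = run_cascade(variants, DESIGN, self.REGIONS, "Japanese")
        c2, _ = run_cascade(variants[::-1], DESIGN, self.REGIONS, "Japanese")
        assert {c.variant.key for c in c1} == {c.variant.key for c in c2}
        assert {c.variant.key: c.branches for c in c1} == {
            c.variant.key: c.branches for c in c2
        }

    def test_region_and_branch_filters_commute(self):
        rng = np.random.default_rng(7)
        variants = self._random_table(rng)
        snvs, indels = functional_filter(variants)
        pool = snvs + indels
        a = {v.key for v in region_filter(novelty_branch(pool), self.REGIONS)}
        b = {v.key for v in novelty_branch(region_filter(pool, self.REGIONS))}
        assert a == b

    def test_planted_variant_is_unique_survivor(self):
        rng = np.random.default_rng(5)
        background = self._random_table(rng, n=200)
        # force backgrounds to fail sharing so the plant is unique
        for v in background:
            v.genotypes["A1"] = GT_REF
        plant = mkvar(pos=150, chrom="1", maf={"Japanese": 0.01},
                      dbsnp="rs555", kg=True, genotypes=geno())
        candidates, _ = run_cascade(
            background + [plant], DESIGN, self.REGIONS, "Japanese"
        )
        assert [c.variant.key for c in candidates] == [plant.key]
        assert candidates[0].branches == ("rare",)

    def test_novel_plant_tagged_with_both_branches(self):
        """A novel variant also passes the rare branch (no recorded MAF)."""
        plant = mkvar(pos=150, chrom="1", maf={"Japanese": None}, genotypes=geno())
        candidates, _ = run_cascade([plant], DESIGN, self.REGIONS, "Japanese")
        assert candidates[0].branches == ("novel", "rare")


def test_candidates_frame_lists_branch_tags():
    from pedlink.variants import candidates_to_frame

    plant = mkvar(pos=150, chrom="1", maf={"Japanese": None}, genotypes=geno())
    candidates, _ = run_cascade([plant], DESIGN, [("1", 100, 200)], "Japanese")
    df = candidates_to_frame(candidates)
    assert df.loc[0, "branches"] == "novel+rare"
    assert df.loc[0, "variant_key"] == plant.key


class TestVariantIO:
    def test_vcf_tsv_round_trip(self, tmp_path):
        variants = [
            mkvar(pos=10, chrom="1", dbsnp="rs1", kg=True,
                  maf={"Japanese": 0.01, "European": None},
                  genotypes=geno(A2=GT_HOM, U2=GT_MISSING)),
            mkvar(pos=20, chrom="14", func_class="frameshift_indel",
                  maf={"Japanese": None, "European": 0.3},
                  genotypes=geno(affected=GT_REF)),
        ]
        variants[0].scores = {"gerp": 2.02, "sift": 0.34, "polyphen2": 0.019}
        vcf = tmp_path / "v.vcf"
        tsv = tmp_path / "v.tsv"
        write_variant_tables(variants, vcf, tsv, sample_order=list(DESIGN.all_samples))
        back = read_variant_tables(vcf, tsv)
        assert [v.key for v in back] == [v.key for v in variants]
        for orig, new in zip(variants, back):
            assert new.gene == orig.gene
            assert new.func_class == orig.func_class
            assert new.dbsnp_id == orig.dbsnp_id
            assert new.in_thousand_genomes == orig.in_thousand_genomes
            assert new.maf == orig.maf
            assert {s: g for s, g in new.genotypes.items()} == orig.genotypes
        assert back[0].scores["gerp"] == pytest.approx(2.02)
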