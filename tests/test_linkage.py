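"""Likelihood engine, multipoint HMM, thinning and curve averaging."""

import math

import numpy as np
import pytest

from pedlink.exceptions import CapacityError, ParameterError
from pedlink.linkage import (
    AnalysisConfig,
    DiseaseModel,
    LodCurve,
    average_lod,
    disease_likelihood,
    load_analysis_config,
    marker_likelihood,
    multipoint_lod,
    thin_interleaved,
)
from pedlink.pedigree import GenotypeMatrix, Marker

from _oracles import (
    disease_likelihood_oracle,
    marker_likelihood_oracle,
    multipoint_lod_oracle,
)
from conftest import make_pedigree, random_instance


class TestDiseaseLikelihood:
    def test_all_unknown_is_one(self):
        ped = make_pedigree([("F", None, None), ("M", None, None), ("C", "F", "M")])
        assert disease_likelihood(ped, 0) == 1.0

    def test_single_affected_founder_closed_form(self):
        ped = make_pedigree([("A", None, None, "affected")])
        dm = DiseaseModel()
        q = dm.q
        expected = q * q * 0.95 + 2 * q * (1 - q) * 0.95 + (1 - q) ** 2 * 0.005
        assert disease_likelihood(ped, 0, dm) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.014426375)

    def test_six_member_pedigree_matches_enumeration(self):
        ped = make_pedigree(
            [
                ("F", None, None, "affected"),
                ("M", None, None, "unaffected"),
                ("S", None, None, "unknown"),
                ("C1", "F", "M", "affected"),
                ("C2", "F", "M", "unaffected"),
                ("G", "C1", "S", "affected"),
            ]
        )
        dm = DiseaseModel()
        for v in range(1 << ped.bit_count):
            assert disease_likelihood(ped, v, dm) == pytest.approx(
                disease_likelihood_oracle(ped, v, dm), rel=1e-12
            )

    def test_bit_sequence_and_length_check(self):
        ped = make_pedigree([("F", None, None), ("M", None, None), ("C", "F", "M")])
        assert disease_likelihood(ped, [0, 1]) == 1.0
        with pytest.raises(Exception, match="meioses"):
            disease_likelihood(ped, [0, 1, 0])


class TestMarkerLikelihood:
    def test_untyped_pedigree_is_one(self):
        ped = make_pedigree([("F", None, None), ("M", None, None), ("C", "F", "M")])
        m = Marker("m", "1", 100, 0.0, founder_freqs=(0.3, 0.7))
        gm = GenotypeMatrix.empty(ped.ids, ["m"])
        assert marker_likelihood(ped, 0, m, gm) == 1.0

    def test_trio_matches_enumeration(self):
        ped = make_pedigree([("F", None, None), ("M", None, None), ("C", "F", "M")])
        m = Marker("m", "1", 100, 0.0, founder_freqs=(0.5, 0.5))
        gm = GenotypeMatrix.empty(ped.ids, ["m"])
        gm.set("F", "m", (1, 2))
        gm.set("M", "m", (1, 2))
        gm.set("C", "m", (1, 1))
        for v in range(4):
            assert marker_likelihood(ped, v, m, gm) == pytest.approx(
                marker_likelihood_oracle(ped, v, m, gm), rel=1e-12
            )

    def test_sum_over_vectors_gives_unconditional_probability(self):
        """sum_v 2^-b P(G|v) equals the direct genotype probability."""
        rng = np.random.default_rng(5)
        for seed in range(10):
            ped, markers, gm, _ = random_instance(seed)
            b = ped.bit_count
            m = markers[0]
            total = sum(
                marker_likelihood(ped, v, m, gm) for v in range(1 << b)
            ) / (1 << b)
            oracle = sum(
                marker_likelihood_oracle(ped, v, m, gm) for v in range(1 << b)
            ) / (1 << b)
            assert total == pytest.approx(oracle, rel=1e-10)

    def test_permutation_equivariance(self):
        """Reordering individuals leaves both likelihoods unchanged."""
        ped, markers, gm, dm = random_instance(42)
        order = list(range(len(ped.individuals)))
        rng = np.random.default_rng(0)
        rng.shuffle(order)
        shuffled = [ped.individuals[i] for i in order]
        # keep parents resolvable: Pedigree allows any order
        from pedlink.pedigree import Pedigree

        ped2 = Pedigree(shuffled)
        # meiosis bit order changes with individual order; compare marginals
        b = ped.bit_count
        tot1 = sum(disease_likelihood(ped, v, dm) for v in range(1 << b))
        tot2 = sum(disease_likelihood(ped2, v, dm) for v in range(1 << b))
        assert tot1 == pytest.approx(tot2, rel=1e-10)
        m = markers[0]
        g1 = sum(marker_likelihood(ped, v, m, gm) for v in range(1 << b))
        g2 = sum(marker_likelihood(ped2, v, m, gm) for v in range(1 << b))
        assert g1 == pytest.approx(g2, rel=1e-10)


def _informative_family(n_children=4, q=1e-8):
    """Phase-known fully informative co-segregation family.

    Grandfather (affected, hom 2/2) x grandmother (unaffected, 1/1) give a
    phase-known affected father (1/2); his spouse is 1/1 unaffected. Under
    full penetrance with no phenocopies, each child is a scorable meiosis:
    affected children carry allele 2, unaffected ones do not.
    """
    rows = [
        ("GF", None, None, "affected"),
        ("GM", None, None, "unaffected"),
        ("FA", "GF", "GM", "affected"),
        ("MO", None, None, "unaffected"),
    ]
    genos = {"GF": (2, 2), "GM": (1, 1), "FA": (1, 2), "MO": (1, 1)}
    affected_children = (n_children + 1) // 2
    for i in range(n_children):
        cid = f"C{i}"
        if i < affected_children:
            rows.append((cid, "FA", "MO", "affected"))
            genos[cid] = (1, 2)
        else:
            rows.append((cid, "FA", "MO", "unaffected"))
            genos[cid] = (1, 1)
    ped = make_pedigree(rows)
    marker = Marker("m", "1", 1_000_000, 10.0, founder_freqs=(0.5, 0.5))
    gm = GenotypeMatrix.empty(ped.ids, ["m"])
    for iid, g in genos.items():
        gm.set(iid, "m", g)
    model = DiseaseModel(q=q, f_AA=0.0, f_Aa=1.0, f_aa=1.0)
    return ped, [marker], gm, model


class TestMultipoint:
    def test_no_marker_data_gives_zero_lod(self):
        ped = make_pedigree(
            [("F", None, None, "affected"), ("M", None, None), ("C", "F", "M", "affected")]
        )
        markers = [Marker(f"m{j}", "1", 1000 * j, float(j)) for j in range(1, 4)]
        gm = GenotypeMatrix.empty(ped.ids, [m.id for m in markers])
        curve = multipoint_lod(ped, markers, gm)
        assert np.allclose(curve.mean_lod, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n_children", [2, 4, 6])
    def test_cosegregation_closed_form(self, n_children):
        """Fully informative co-segregating marker: LOD = n * log10(2)."""
        ped, markers, gm, model = _informative_family(n_children)
        curve = multipoint_lod(ped, markers, gm, model)
        assert curve.mean_lod[0] == pytest.approx(
            n_children * math.log10(2.0), abs=1e-6
        )

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_joint_enumeration_oracle(self, seed):
        ped, markers, gm, dm = random_instance(seed)
        curve = multipoint_lod(ped, markers, gm, dm)
        oracle = multipoint_lod_oracle(ped, markers, gm, dm)
        assert np.allclose(10.0**curve.mean_lod, 10.0**oracle, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_founder_symmetry_reduction_is_exact(self, seed):
        ped, markers, gm, dm = random_instance(seed)
        fast = multipoint_lod(ped, markers, gm, dm, use_founder_symmetry=True)
        slow = multipoint_lod(ped, markers, gm, dm, use_founder_symmetry=False)
        assert np.max(np.abs(fast.mean_lod - slow.mean_lod)) <= 1e-10

    def test_lod_decays_to_zero_far_from_markers(self):
        ped, markers, gm, model = _informative_family(4)
        far = {"1": [markers[0].position_cm + 3000.0]}
        curve = multipoint_lod(ped, markers, gm, model, positions=far)
        assert abs(curve.mean_lod[0]) < 1e-9

    def test_bit_ceiling_capacity_error(self):
        ped, markers, gm, dm = random_instance(3)
        with pytest.raises(CapacityError, match="split"):
            multipoint_lod(ped, markers, gm, dm, bit_ceiling=0)

    def test_unsorted_markers_rejected(self):
        ped, markers, gm, dm = random_instance(1)
        if len(markers) > 1:
            with pytest.raises(ParameterError, match="sorted"):
                multipoint_lod(ped, markers[::-1], gm, dm)


class TestThinInterleaved:
    def test_k1_identity(self):
        assert thin_interleaved([1, 2, 3], 1) == [[1, 2, 3]]

    def test_ten_markers_k3(self):
        subsets = thin_interleaved(list(range(10)), 3)
        assert [len(s) for s in subsets] == [4, 3, 3]
        assert subsets[0] == [0, 3, 6, 9]

    def test_partition_property(self):
        items = list(range(101))
        subsets = thin_interleaved(items, 7)
        merged = sorted(x for s in subsets for x in s)
        assert merged == items

    def test_study_panel_sizes(self):
        """274,743 SNPs in 30 subsets: around 9,200 SNPs per dataset."""
        subsets = thin_interleaved(range(274_743), 30)
        sizes = [len(s) for s in subsets]
        assert sizes == [9159] * 3 + [9158] * 27
        assert sum(sizes) == 274_743

    def test_bad_k(self):
        with pytest.raises(ParameterError):
            thin_interleaved([1, 2], 0)


def _curve(chrom, cms, values):
    cms = np.asarray(cms, dtype=float)
    return LodCurve(
        np.array([chrom] * len(cms), dtype=object),
        (cms * 1e6).astype(np.int64),
        cms,
        np.asarray(values)[None, :],
        np.asarray(values, dtype=float),
    )


class TestAverageLod:
    def test_single_curve_is_identity(self):
        c = _curve("1", [0, 1, 2], [0.5, 1.5, 0.7])
        avg = average_lod([c])
        assert np.allclose(avg.mean_lod, c.mean_lod)

    def test_two_constant_curves(self):
        c1 = _curve("1", [0, 1, 2], [1.0, 1.0, 1.0])
        c2 = _curve("1", [0, 1, 2], [2.0, 2.0, 2.0])
        avg = average_lod([c1, c2])
        assert np.allclose(avg.mean_lod, 1.5)
        assert avg.subset_lods.shape == (2, 3)

    def test_thirty_simulated_curves_match_positionwise_mean(self):
        rng = np.random.default_rng(11)
        cms = np.arange(20.0)
        curves = [_curve("1", cms, rng.normal(size=20)) for _ in range(30)]
        avg = average_lod(curves)
        stacked = np.vstack([c.mean_lod for c in curves])
        assert np.allclose(avg.mean_lod, stacked.mean(axis=0))

    def test_interpolation_in_cm(self):
        c1 = _curve("1", [0.0, 2.0], [0.0, 2.0])
        c2 = _curve("1", [1.0], [1.0])
        avg = average_lod([c1, c2], positions=[("1", 1_000_000, 1.0)])
        assert avg.mean_lod[0] == pytest.approx(1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            average_lod([])


def test_analysis_config_round_trip(tmp_path):
    cfg = '{"q": 0.01, "f_AA": 0.0, "f_Aa": 0.9, "f_aa": 0.9, "subsets_k": 10, "lod_threshold": 3.0}'
    path = tmp_path / "model.json"
    path.write_text(cfg)
    parsed = load_analysis_config(path)
    assert isinstance(parsed, AnalysisConfig)
    assert parsed.disease_model == DiseaseModel(0.01, 0.0, 0.9, 0.9)
    assert parsed.subsets_k == 10 and parsed.lod_threshold == 3.0
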