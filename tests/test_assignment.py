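import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracle import brute_force_hits
from conftest import markers_from_arrays, percent_profile
from nafkit.assignment import (
    SingleFractionCase,
    absolute_subcellular_levels,
    aggregate_replicates,
    assign_pair_hits,
    hits_to_distribution,
    metabolite_distribution,
    pairwise_slopes,
    psi_distances,
    single_fraction_hits,
)
from nafkit.core import (
    AlgorithmConfig,
    HitTable,
    RelativeDistribution,
    SlopeSet,
    UndetectableAnalyteError,
    ValidationError,
)

CONFIG = AlgorithmConfig()


class TestPairwiseSlopes:
    def test_flat_profile_has_all_zero_deltas(self):
        slopes = pairwise_slopes(percent_profile("m", [25, 25, 25, 25]))
        assert len(slopes.pairs) == 6
        assert all(d == 0 for d in slopes.pairs.values())

    def test_monotone_profile_deltas(self):
        slopes = pairwise_slopes(percent_profile("m", [10, 20, 30, 40]))
        assert slopes.pairs == {
            (0, 1): 10, (0, 2): 20, (0, 3): 30,
            (1, 2): 10, (1, 3): 20, (2, 3): 10,
        }

    def test_pair_count_is_k_choose_2(self):
        prof = percent_profile("m", np.full(6, 100 / 6))
        assert len(pairwise_slopes(prof).pairs) == 15

    def test_undetected_fractions_are_skipped(self):
        prof = percent_profile("m", [50, np.nan, np.nan, 50])
        slopes = pairwise_slopes(prof)
        assert list(slopes.pairs) == [(0, 3)]

    def test_single_detected_fraction_signals_special_case(self):
        with pytest.raises(SingleFractionCase):
            pairwise_slopes(percent_profile("m", [np.nan, 100, np.nan]))

    def test_density_normalized_slopes_divide_by_spacing(self):
        prof = percent_profile("m", [40, 60])
        dens = np.array([1.2, 1.6])
        slopes = pairwise_slopes(prof, dens, density_normalized=True)
        assert slopes.pairs[(0, 1)] == pytest.approx(20 / 0.4)


class TestPsiDistances:
    def test_identical_slopes_give_zero_distance(self):
        met = SlopeSet("m", {(0, 1): 5.0})
        markers = {"plastid": SlopeSet("p", {(0, 1): 5.0}),
                   "cytosol": SlopeSet("c", {(0, 1): 1.0}),
                   "vacuole": SlopeSet("v", {(0, 1): -2.0})}
        psi = psi_distances(met, markers).psi[(0, 1)]
        assert psi == {"plastid": 0.0, "cytosol": 4.0, "vacuole": 7.0}

    def test_absolute_difference(self):
        met = SlopeSet("m", {(0, 1): 5.0})
        markers = {"plastid": SlopeSet("p", {(0, 1): 3.0}),
                   "cytosol": SlopeSet("c", {(0, 1): -4.0}),
                   "vacuole": SlopeSet("v", {(0, 1): 25.0})}
        psi = psi_distances(met, markers).psi[(0, 1)]
        assert psi == {"plastid": 2.0, "cytosol": 9.0, "vacuole": 20.0}

    def test_orientation_flip_leaves_psi_unchanged(self):
        met = SlopeSet("m", {(0, 1): 5.0})
        markers = {"plastid": SlopeSet("p", {(0, 1): 3.0})}
        flipped = psi_distances(
            SlopeSet("m", {(0, 1): -5.0}),
            {"plastid": SlopeSet("p", {(0, 1): -3.0})},
        )
        assert psi_distances(met, markers).psi == flipped.psi

    def test_missing_marker_pair_is_inconsistency(self):
        met = SlopeSet("m", {(0, 1): 5.0, (0, 2): 1.0})
        with pytest.raises(ValidationError, match="pair"):
            psi_distances(met, {"plastid": SlopeSet("p", {(0, 1): 3.0})})


class TestAssignPairHits:
    def test_graded_hits_by_distance_from_minimum(self):
        hits = assign_pair_hits({"plastid": 2.0, "cytosol": 9.0, "vacuole": 20.0})
        assert hits == {"plastid": 3.0, "cytosol": 2.0, "vacuole": 0.0}

    def test_full_tie_hits_every_compartment_fully(self):
        hits = assign_pair_hits({"plastid": 4.0, "cytosol": 4.0, "vacuole": 4.0})
        assert hits == {"plastid": 3.0, "cytosol": 3.0, "vacuole": 3.0}

    def test_boundary_equality_does_not_hit_under_strict_inequality(self):
        hits = assign_pair_hits({"plastid": 0.0, "cytosol": 5.0, "vacuole": 10.0})
        assert hits == {"plastid": 3.0, "cytosol": 2.0, "vacuole": 0.0}

    def test_boundary_equality_hits_with_non_strict_inequality(self):
        config = AlgorithmConfig(strict_inequality=False)
        hits = assign_pair_hits(
            {"plastid": 0.0, "cytosol": 5.0, "vacuole": 10.0}, config
        )
        assert hits == {"plastid": 3.0, "cytosol": 3.0, "vacuole": 1.0}

    def test_min_plus_bounds_scheme_adds_one_extra_hit(self):
        config = AlgorithmConfig(scheme="min-plus-bounds")
        hits = assign_pair_hits(
            {"plastid": 2.0, "cytosol": 9.0, "vacuole": 20.0}, config
        )
        assert hits == {"plastid": 4.0, "cytosol": 2.0, "vacuole": 0.0}

    @given(st.tuples(*[st.floats(0, 60) for _ in range(3)]))
    def test_argmin_always_earns_all_bounds(self, psis):
        psi = dict(zip(("plastid", "cytosol", "vacuole"), psis))
        hits = assign_pair_hits(psi)
        winner = min(psi, key=psi.get)
        assert hits[winner] == len(CONFIG.bounds)
        assert all(0 <= h <= len(CONFIG.bounds) for h in hits.values())

    @given(st.tuples(*[st.floats(0, 60) for _ in range(3)]),
           st.floats(0.1, 30), st.floats(0.1, 30))
    def test_enlarging_bounds_never_loses_hits(self, psis, grow_mid, grow_top):
        psi = dict(zip(("plastid", "cytosol", "vacuole"), psis))
        base = assign_pair_hits(psi)
        bigger = AlgorithmConfig(
            bounds=(5.0, 7.5 + grow_mid, 10.0 + grow_mid + grow_top)
        )
        grown = assign_pair_hits(psi, bigger)
        assert all(grown[c] >= base[c] for c in psi)

    @given(st.tuples(*[st.floats(0, 60) for _ in range(3)]))
    def test_label_permutation_permutes_hits(self, psis):
        labels = ("plastid", "cytosol", "vacuole")
        base = assign_pair_hits(dict(zip(labels, psis)))
        for perm in permutations(range(3)):
            permuted = assign_pair_hits(
                {labels[perm[k]]: psis[k] for k in range(3)}
            )
            assert all(
                permuted[labels[perm[k]]] == base[labels[k]] for k in range(3)
            )


class TestSingleFractionCase:
    def test_highest_marker_takes_all(self, separated_markers):
        hits = single_fraction_hits(0, separated_markers, CONFIG, "m")
        assert hits.counts == {"plastid": 3.0, "cytosol": 0.0, "vacuole": 0.0}
        dist = hits_to_distribution(hits)
        assert dist.percents["plastid"] == pytest.approx(100)

    def test_two_way_tie_split_policy_halves_weight(self):
        markers = markers_from_arrays([40, 60], [40, 60], [20, 80])
        config = AlgorithmConfig(tie_policy="split")
        hits = single_fraction_hits(0, markers, config, "m")
        assert hits.counts == {"plastid": 1.5, "cytosol": 1.5, "vacuole": 0.0}

    def test_full_tie_normalizes_to_thirds(self, tie_markers):
        for policy in ("split", "all-pass"):
            config = AlgorithmConfig(tie_policy=policy)
            hits = single_fraction_hits(2, tie_markers, config, "m")
            dist = hits_to_distribution(hits)
            assert all(
                v == pytest.approx(100 / 3) for v in dist.percents.values()
            )


class TestMetaboliteDistribution:
    def test_profile_matching_plastid_marker_is_fully_plastidic(
        self, separated_markers
    ):
        met = percent_profile("m", separated_markers.profiles["plastid"].percents)
        hits, dist = metabolite_distribution(met, separated_markers)
        assert dist.percents["plastid"] == pytest.approx(100, abs=1e-9)
        assert hits.pair_count == 6

    def test_identical_markers_give_equal_thirds(self, tie_markers):
        met = percent_profile("m", [40, 30, 10, 10, 10])
        _, dist = metabolite_distribution(met, tie_markers)
        assert all(v == pytest.approx(100 / 3) for v in dist.percents.values())

    def test_hit_ratio_three_two_zero_maps_to_60_40_0(self):
        hits = HitTable("m", {"plastid": 3.0, "cytosol": 2.0, "vacuole": 0.0}, 1)
        dist = hits_to_distribution(hits)
        assert dist.percents == {
            "plastid": 60.0, "cytosol": 40.0, "vacuole": 0.0,
        }

    def test_single_detected_fraction_routes_to_special_case(self, separated_markers):
        met = percent_profile("m", [np.nan, np.nan, np.nan, 100.0])
        hits, dist = metabolite_distribution(met, separated_markers)
        assert hits.pair_count == 0
        assert dist.percents["vacuole"] == pytest.approx(100)

    def test_undetected_metabolite_is_an_error(self, separated_markers):
        with pytest.raises(UndetectableAnalyteError):
            metabolite_distribution(
                percent_profile("m", [np.nan] * 4), separated_markers
            )

    def test_partial_detection_uses_matched_marker_pairs(self, separated_markers):
        values = separated_markers.profiles["vacuole"].percents.copy()
        values[1] = np.nan
        partial = values / np.nansum(values) * 100
        met = percent_profile("m", partial)
        hits, dist = metabolite_distribution(met, separated_markers)
        assert hits.pair_count == 3  # C(3,2) over detected fractions
        assert dist.percents["vacuole"] == pytest.approx(
            max(dist.percents.values())
        )


@st.composite
def random_instances(draw):
    f = draw(st.integers(3, 6))
    def percents():
        raw = draw(
            st.lists(st.floats(0.01, 100), min_size=f, max_size=f)
        )
        arr = np.asarray(raw)
        return arr / arr.sum() * 100
    markers = markers_from_arrays(percents(), percents(), percents())
    met_vals = percents()
    n_missing = draw(st.integers(0, f - 2))
    missing = draw(
        st.lists(st.integers(0, f - 1), min_size=n_missing, max_size=n_missing,
                 unique=True)
    )
    met_vals[missing] = np.nan
    met_vals = met_vals / np.nansum(met_vals) * 100
    return markers, percent_profile("met", met_vals)


class TestOracleEquivalence:
    @given(random_instances())
    def test_hit_tables_match_brute_force(self, instance):
        markers, met = instance
        hits, _ = metabolite_distribution(met, markers)
        met_list = [
            float(v) if d else None for v, d in zip(met.percents, met.detected)
        ]
        expected = brute_force_hits(
            met_list,
            {c: p.percents.tolist() for c, p in markers.profiles.items()},
        )
        assert {c: int(v) for c, v in hits.counts.items()} == expected


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self):
        reps = [
            RelativeDistribution("m", {"plastid": 60.0, "cytosol": 40.0, "vacuole": 0.0}),
            RelativeDistribution("m", {"plastid": 40.0, "cytosol": 60.0, "vacuole": 0.0}),
        ]
        agg = aggregate_replicates(reps)
        assert agg.percents == {"plastid": 50.0, "cytosol": 50.0, "vacuole": 0.0}
        sd = agg.replicate_stats["plastid"][1]
        assert sd == pytest.approx(math.sqrt(200))  # 14.142...

    def test_identical_replicates_have_zero_sd(self):
        reps = [
            RelativeDistribution("m", {"plastid": 100.0, "cytosol": 0.0, "vacuole": 0.0})
        ] * 3
        agg = aggregate_replicates(reps)
        assert all(sd == 0 for _, sd, _ in agg.replicate_stats.values())

    def test_single_replicate_reports_zero_sd(self):
        agg = aggregate_replicates(
            [RelativeDistribution("m", {"plastid": 70.0, "cytosol": 30.0, "vacuole": 0.0})]
        )
        assert agg.replicate_stats["plastid"] == (70.0, 0.0, 1)

    def test_mixed_metabolites_rejected(self):
        with pytest.raises(ValidationError, match="mixed"):
            aggregate_replicates(
                [
                    RelativeDistribution("a", {"plastid": 100.0, "cytosol": 0.0}),
                    RelativeDistribution("b", {"plastid": 100.0, "cytosol": 0.0}),
                ]
            )

    def test_means_sum_to_100(self):
        rng = np.random.default_rng(3)
        reps = []
        for _ in range(5):
            w = rng.dirichlet([1, 1, 1]) * 100
            reps.append(
                RelativeDistribution(
                    "m", dict(zip(("plastid", "cytosol", "vacuole"), w))
                )
            )
        agg = aggregate_replicates(reps)
        assert sum(agg.percents.values()) == pytest.approx(100, abs=1e-9)


class TestAbsoluteLevels:
    def test_even_split_of_whole_tissue_level(self):
        rel = RelativeDistribution(
            "m",
            {"plastid": 50.0, "cytosol": 50.0, "vacuole": 0.0},
            replicate_stats={
                "plastid": (50.0, 0.0, 3),
                "cytosol": (50.0, 0.0, 3),
                "vacuole": (0.0, 0.0, 3),
            },
        )
        absd = absolute_subcellular_levels(rel, 10.0, 0.0)
        assert absd.levels == {"plastid": 5.0, "cytosol": 5.0, "vacuole": 0.0}
        assert all(sd == 0 for sd in absd.sds.values())

    def test_pure_compartment_passes_whole_tissue_through(self):
        rel = RelativeDistribution(
            "m",
            {"plastid": 100.0, "cytosol": 0.0, "vacuole": 0.0},
            replicate_stats={
                "plastid": (100.0, 2.5, 3),
                "cytosol": (0.0, 0.0, 3),
                "vacuole": (0.0, 0.0, 3),
            },
        )
        absd = absolute_subcellular_levels(rel, 8.0, 0.8)
        assert absd.levels["plastid"] == pytest.approx(8.0)
        assert absd.levels["cytosol"] == 0.0

    def test_error_propagation_combines_cvs(self):
        rel = RelativeDistribution(
            "m",
            {"plastid": 60.0, "cytosol": 40.0, "vacuole": 0.0},
            replicate_stats={
                "plastid": (60.0, 6.0, 3),
                "cytosol": (40.0, 4.0, 3),
                "vacuole": (0.0, 0.0, 3),
            },
        )
        absd = absolute_subcellular_levels(rel, 10.0, 1.0)
        assert absd.levels["plastid"] == pytest.approx(6.0)
        assert absd.sds["plastid"] == pytest.approx(6.0 * math.sqrt(0.02))
        assert absd.sds["cytosol"] == pytest.approx(4.0 * math.sqrt(0.02))
        assert absd.sds["vacuole"] == 0.0

    def test_levels_sum_to_whole_tissue_mean(self):
        rng = np.random.default_rng(11)
        w = rng.dirichlet([1, 1, 1]) * 100
        rel = RelativeDistribution(
            "m", dict(zip(("plastid", "cytosol", "vacuole"), w))
        )
        absd = absolute_subcellular_levels(rel, 37.5, 3.0)
        assert sum(absd.levels.values()) == pytest.approx(37.5, abs=1e-9)

    def test_nonpositive_whole_tissue_rejected(self):
        rel = RelativeDistribution("m", {"plastid": 100.0, "cytosol": 0.0})
        with pytest.raises(ValidationError):
            absolute_subcellular_levels(rel, 0.0)
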