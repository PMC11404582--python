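"""Unit and property tests for microbiome QC, diversity, overlap,
differential abundance, and 16S quantification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio import DistanceMatrix as SkbioDM

from gutseg.containers import (
    DegenerateInputError,
    DistanceMatrix,
    FeatureTable,
    ModeError,
)
from gutseg.microbiome import (
    StandardCurve,
    aggregate_by_rank,
    bray_curtis,
    copies_per_gram,
    differential_features,
    filter_low_depth_samples,
    filter_rare_features,
    fit_standard_curve,
    flag_blank_overlap,
    pcoa,
    presence_overlap,
    relative_abundance,
    shannon_index,
)
from gutseg.synthetic import QpcrSimDesign, simulate_qpcr


def table_from(values: dict, mode="counts", ann=None) -> FeatureTable:
    return FeatureTable(pd.DataFrame(values), mode=mode, feature_annotations=ann)


class TestDepthFilter:
    def test_boundary_500_is_retained(self):
        t = table_from({"a": [499], "b": [500], "c": [10000]})
        filtered, report = filter_low_depth_samples(t)
        assert filtered.sample_ids == ["b", "c"]
        assert report.discarded_samples == {"a": "low_depth"}

    def test_identity_when_all_deep(self):
        t = table_from({"a": [600], "b": [700]})
        filtered, report = filter_low_depth_samples(t)
        assert filtered.sample_ids == ["a", "b"]
        assert not report.discarded_samples

    def test_all_zero_depths_empty_result(self):
        t = table_from({"a": [0], "b": [0], "c": [0]})
        filtered, report = filter_low_depth_samples(t)
        assert filtered.n_samples == 0
        assert len(report.discarded_samples) == 3

    def test_relative_input_rejected(self):
        t = table_from({"a": [0.4, 0.6]}, mode="relative")
        with pytest.raises(ModeError):
            filter_low_depth_samples(t)

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.integers(0, 300, size=(4, 6)),
                            columns=list("abcdef"))
        t = FeatureTable(data)
        keep1, _ = filter_low_depth_samples(t, min_reads=500)
        shuffled = FeatureTable(data[list("fedcba")])
        keep2, _ = filter_low_depth_samples(shuffled, min_reads=500)
        assert set(keep1.sample_ids) == set(keep2.sample_ids)


class TestRareFeatureFilter:
    def test_low_prevalence_discarded(self):
        # present in 1 of 20 samples (5% < 10%) but abundant
        data = {f"s{i}": [0, 1000] for i in range(20)}
        data["s0"] = [900, 1000]
        t = table_from(data)
        filtered, report = filter_rare_features(t)
        assert 0 not in filtered.data.index
        assert report.discarded_features.get(0) == "low_prevalence"

    def test_dominant_feature_retained(self):
        t = table_from({f"s{i}": [500, 500] for i in range(10)})
        filtered, _ = filter_rare_features(t)
        assert filtered.n_features == 2

    def test_abundance_criterion_despite_prevalence(self):
        # detected in 2/10 samples (20% >= 10%) but mean relative
        # abundance 5e-5 < 1e-4 -> discarded as low_abundance
        rare = np.zeros(10)
        rare[:2] = 0.00025 * 1000  # 2.5e-4 rel in 2 samples -> mean 5e-5
        data = pd.DataFrame(
            {f"s{i}": [rare[i], 1000 - rare[i]] for i in range(10)},
            index=["rare", "common"],
        )
        filtered, report = filter_rare_features(FeatureTable(data))
        assert "rare" not in filtered.data.index
        assert report.discarded_features == {"rare": "low_abundance"}

    def test_empty_table_rejected(self):
        t = FeatureTable(pd.DataFrame(index=["f1"], columns=[], dtype=float))
        with pytest.raises(DegenerateInputError):
            filter_rare_features(t)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.integers(0, 5, size=(30, 12)),
                            index=[f"f{i}" for i in range(30)])
        data.iloc[0] = 100  # keep depths nonzero
        filtered, report = filter_rare_features(FeatureTable(data))
        assert sorted(report.retained_features) + sorted(report.discarded_features) \
            == sorted(report.retained_features + list(report.discarded_features))
        assert set(report.retained_features) | set(report.discarded_features) \
            == set(data.index)
        assert not set(report.retained_features) & set(report.discarded_features)


class TestBlankOverlap:
    def test_dominant_contaminant_flagged(self):
        counts = table_from({"s1": [90, 10], "s2": [1, 99]})
        blank = FeatureTable(pd.DataFrame({"blank": [50]}, index=[0]))
        report = flag_blank_overlap(counts, blank, dominance_threshold=0.5)
        assert report.discarded_samples == {"s1": "blank_overlap"}

    def test_absent_blank_feature_no_flags(self):
        counts = table_from({"s1": [90, 10]})
        blank = FeatureTable(pd.DataFrame({"blank": [50]}, index=["zz"]))
        report = flag_blank_overlap(counts, blank, 0.1)
        assert not report.discarded_samples

    def test_zero_threshold_flags_any_carrier(self):
        counts = table_from({"s1": [1, 999], "s2": [0, 1000]})
        blank = FeatureTable(pd.DataFrame({"blank": [50]}, index=[0]))
        report = flag_blank_overlap(counts, blank, 0.0)
        assert set(report.discarded_samples) == {"s1"}


class TestRelativeAndAggregation:
    def test_column_normalization(self):
        rel = relative_abundance(table_from({"s1": [10, 30]}))
        assert np.allclose(rel.data["s1"], [0.25, 0.75])
        assert rel.mode == "relative"

    def test_zero_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            relative_abundance(table_from({"s1": [0, 0]}))

    def test_genus_aggregation_sums_members(self, toy_counts):
        rel = relative_abundance(toy_counts)
        genus = aggregate_by_rank(rel, "genus")
        assert genus.data.loc["G1", "s1"] == pytest.approx(1.0)
        # column sums preserved
        assert np.allclose(genus.data.sum(axis=0), rel.data.sum(axis=0))

    def test_species_aggregation_is_identity_up_to_order(self, toy_counts):
        agg = aggregate_by_rank(toy_counts, "species")
        assert agg.n_features == toy_counts.n_features
        assert np.allclose(
            agg.data.sum(axis=0), toy_counts.data.sum(axis=0)
        )

    def test_malformed_taxonomy_names_feature(self):
        ann = pd.Series({"f1": "not-a-taxonomy"})
        t = FeatureTable(pd.DataFrame({"s1": [1.0]}, index=["f1"]),
                         feature_annotations=ann)
        with pytest.raises(ValueError, match="f1"):
            aggregate_by_rank(t, "genus")


class TestShannon:
    def test_uniform_equals_log_richness(self):
        t = table_from({"s1": [0.1] * 10}, mode="relative")
        assert shannon_index(t)["s1"] == pytest.approx(np.log(10), abs=1e-9)

    def test_single_species_zero(self):
        t = table_from({"s1": [1.0]}, mode="relative")
        assert shannon_index(t)["s1"] == pytest.approx(0.0)

    def test_hand_evaluated_mixture(self):
        t = table_from({"s1": [0.5, 0.25, 0.25]}, mode="relative")
        assert shannon_index(t)["s1"] == pytest.approx(1.5 * np.log(2), abs=1e-9)

    def test_invariant_to_zero_features(self):
        t1 = table_from({"s1": [0.5, 0.5]}, mode="relative")
        t2 = table_from({"s1": [0.5, 0.5, 0.0]}, mode="relative")
        assert shannon_index(t1)["s1"] == shannon_index(t2)["s1"]

    def test_counts_mode_rejected(self):
        with pytest.raises(ModeError):
            shannon_index(table_from({"s1": [5, 5]}))


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = table_from({"s1": [0.5, 0.5], "s2": [0.5, 0.5]}, mode="relative")
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = table_from({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, mode="relative")
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        t = table_from(
            {"s1": [0.6, 0.4, 0.0], "s2": [0.2, 0.4, 0.4]}, mode="relative"
        )
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_metric_properties_on_random_tables(self):
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(8), size=6).T
        t = FeatureTable(pd.DataFrame(x, columns=[f"s{i}" for i in range(6)]),
                         mode="relative")
        d = bray_curtis(t).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_single_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            bray_curtis(table_from({"s1": [1.0]}, mode="relative"))


class TestPcoa:
    def test_two_points_closed_form(self):
        d = 0.8
        dm = DistanceMatrix(np.array([[0, d], [d, 0]]), ["a", "b"], "test")
        res = pcoa(dm)
        assert res.eigenvalues[0] == pytest.approx(d * d / 2, abs=1e-12)
        coords = res.coordinates["PCo1"].to_numpy()
        assert np.allclose(sorted(np.abs(coords)), [d / 2, d / 2])

    def test_zero_distances_zero_eigenvalues(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"], "test")
        res = pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0)

    def test_euclidean_configuration_roundtrip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(4, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(d, list("abcd"), "euclidean")
        res = pcoa(dm)
        emb = res.coordinates.to_numpy()
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.allclose(d_emb, d, atol=1e-8)

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(10), size=7).T
        t = FeatureTable(pd.DataFrame(x, columns=[f"s{i}" for i in range(7)]),
                         mode="relative")
        dm = bray_curtis(t)
        mine = pcoa(dm)
        ref = skbio_pcoa(SkbioDM(dm.values, ids=dm.sample_ids), method="eigh")
        n_pos = (mine.eigenvalues > 1e-12).sum()
        assert np.allclose(
            mine.eigenvalues[:n_pos], ref.eigvals.to_numpy()[:n_pos], atol=1e-10
        )
        assert np.allclose(
            np.abs(mine.coordinates.to_numpy()),
            np.abs(ref.samples.to_numpy()[:, :mine.coordinates.shape[1]]),
            atol=1e-8,
        )

    def test_nan_rejected(self):
        d = np.zeros((2, 2))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(d, ["a", "b"], "test"))


class TestPresenceOverlap:
    def test_identical_groups_full_core(self):
        t = table_from({"s1": [1, 2], "s2": [3, 4]})
        res = presence_overlap(t, {"s1": "g1", "s2": "g2"})
        assert res.core == set(t.feature_ids)
        assert all(f == pytest.approx(1.0)
                   for f in res.core_abundance_fraction.values())

    def test_disjoint_groups_empty_core(self):
        t = table_from({"s1": [5, 0], "s2": [0, 5]})
        res = presence_overlap(t, {"s1": "g1", "s2": "g2"})
        assert res.core == set()
        assert all(f == 0.0 for f in res.core_abundance_fraction.values())

    def test_inclusion_exclusion_consistency(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            (rng.uniform(size=(40, 9)) < 0.4).astype(int) * 10,
            index=[f"f{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(9)],
        )
        grouping = {f"s{i}": f"g{i % 3}" for i in range(9)}
        res = presence_overlap(FeatureTable(data), grouping)
        union = set().union(*res.presence.values())
        assert sum(res.exclusive_regions.values()) == len(union)
        # subset intersections consistent with exclusive regions
        for combo_size in (1, 2, 3):
            for combo in itertools.combinations(res.group_order, combo_size):
                key = frozenset(combo)
                derived = sum(
                    v for pat, v in res.exclusive_regions.items()
                    if key <= pat
                )
                assert derived == res.intersections[key]

    def test_unassigned_sample_rejected(self):
        t = table_from({"s1": [1], "s2": [1]})
        with pytest.raises(KeyError):
            presence_overlap(t, {"s1": "g1"})

    def test_generator_roundtrip_core(self, microbiome_dataset):
        table, meta, true_core, _ = microbiome_dataset
        res = presence_overlap(
            table, meta.frame["segment"].astype(str),
            group_order=meta.segments_present(),
        )
        assert res.core >= true_core
        assert res.core == true_core  # ample-depth detection is noise-free


class TestDifferentialFeatures:
    @staticmethod
    def _rel_table(a_vals, b_vals, extra=None):
        n_a, n_b = len(a_vals), len(b_vals)
        rows = {"f": list(a_vals) + list(b_vals)}
        rows["other"] = [1 - v for v in rows["f"]]
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_a + n_b)]).T
        return FeatureTable(df, mode="relative"), \
            [f"s{i}" for i in range(n_a)], \
            [f"s{i}" for i in range(n_a, n_a + n_b)]

    def test_identical_groups_not_significant(self):
        t, a, b = self._rel_table([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        res = differential_features(t, a, b)
        assert res.loc["f", "p"] == pytest.approx(1.0)
        assert not res["significant"].any()

    def test_complete_separation_exact_p(self):
        t, a, b = self._rel_table(
            [0.41, 0.42, 0.43, 0.44, 0.45, 0.46],
            [0.11, 0.12, 0.13, 0.14, 0.15, 0.16],
        )
        res = differential_features(t, a, b)
        assert res.loc["f", "p"] == pytest.approx(2 / 924, abs=1e-10)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.dirichlet(np.ones(5), size=8).T
        t = FeatureTable(pd.DataFrame(x, columns=[f"s{i}" for i in range(8)]),
                         mode="relative")
        a, b = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)]
        r1 = differential_features(t, a, b)
        perm = [f"s{i}" for i in [2, 0, 3, 1]], [f"s{i}" for i in [7, 5, 4, 6]]
        r2 = differential_features(t, perm[0], perm[1])
        assert np.allclose(r1["p"], r2["p"])

    def test_small_group_rejected(self):
        t, a, b = self._rel_table([0.5, 0.5], [0.5])
        with pytest.raises(DegenerateInputError):
            differential_features(t, a, b)


class TestQpcrQuantification:
    def test_perfect_efficiency_closed_form(self):
        standards, _ = simulate_qpcr(QpcrSimDesign(noise_sd_ct=0.0))
        curve = fit_standard_curve(standards)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_curve_recovers_slope(self):
        standards, _ = simulate_qpcr(QpcrSimDesign(noise_sd_ct=0.1, seed=10))
        curve = fit_standard_curve(standards)
        assert curve.slope == pytest.approx(-3.3219, abs=0.1)

    def test_too_few_levels_rejected(self):
        df = pd.DataFrame({"log10_copies": [1.0, 2.0], "ct": [30.0, 27.0]})
        with pytest.raises(DegenerateInputError):
            fit_standard_curve(df)

    def test_ct_at_intercept_is_one_copy(self):
        curve = StandardCurve(slope=-3.3219, intercept=38.0, r_squared=1.0)
        assert curve.copies_from_ct(38.0) == pytest.approx(1.0)

    def test_copies_per_gram_chain(self):
        curve = StandardCurve(slope=-3.3219, intercept=38.0, r_squared=1.0)
        result = copies_per_gram(18.0686, curve, dna_per_rxn_ng=1.0,
                                 total_dna_ng=100.0, mass_g=0.01)
        assert result == pytest.approx(1e10, rel=1e-4)

    def test_mass_scaling_law(self):
        curve = StandardCurve(slope=-3.3219, intercept=38.0, r_squared=1.0)
        r1 = copies_per_gram(20.0, curve, 1.0, 100.0, 0.01)
        r2 = copies_per_gram(20.0, curve, 1.0, 100.0, 0.02)
        assert r1 == pytest.approx(2 * r2)

    def test_quantification_inverts_generator_at_zero_noise(self):
        design = QpcrSimDesign(noise_sd_ct=0.0)
        standards, samples = simulate_qpcr(design)
        curve = fit_standard_curve(standards)
        for _, row in samples.iterrows():
            est = copies_per_gram(row["ct"], curve, dna_per_rxn_ng=1.0,
                                  total_dna_ng=design.dna_ratio,
                                  mass_g=row["mass_g"])
            assert est == pytest.approx(row["true_copies_per_g"], rel=1e-9)

    def test_nonpositive_mass_rejected(self):
        curve = StandardCurve(slope=-3.3219, intercept=38.0, r_squared=1.0)
        with pytest.raises(ValueError):
            copies_per_gram(20.0, curve, 1.0, 100.0, 0.0)
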