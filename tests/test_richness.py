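import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import paradiv as pv


def matrix_from_frequencies(h, m):
    """Incidence matrix whose column sums are exactly h, with m rows."""
    mat = np.zeros((m, len(h)), dtype=np.int8)
    for j, hj in enumerate(h):
        mat[:hj, j] = 1
    return pv.IncidenceMatrix(
        [f"u{i}" for i in range(m)], [f"p{j}" for j in range(len(h))], mat
    )


class TestBuildIncidence:
    def test_uninfected_hosts_appear_as_zero_rows(self, make_records_factory):
        rec = make_records_factory([("spA", "fish", 3)], "kelp")
        obs = pd.DataFrame(
            {"host_individual_id": ["spA_h000"], "morphogroup_id": ["p1"], "count": [1]}
        )
        m = pv.build_incidence(pv.make_dataset(rec, obs), "host_individual")
        assert m.m == 3
        assert m.incidence.sum() == 1

    def test_incidence_is_binary_not_abundance(self, make_records_factory):
        rec = make_records_factory([("spA", "fish", 1)], "kelp")
        obs = pd.DataFrame(
            {"host_individual_id": ["spA_h000"], "morphogroup_id": ["p1"], "count": [5]}
        )
        m = pv.build_incidence(pv.make_dataset(rec, obs), "host_individual")
        assert m.incidence.tolist() == [[1]]

    def test_species_level_pools_individuals(self, make_records_factory):
        rec = make_records_factory([("spA", "fish", 2), ("spB", "mollusk", 2)], "kelp")
        obs = pd.DataFrame(
            {
                "host_individual_id": ["spA_h000", "spA_h001", "spB_h000"],
                "morphogroup_id": ["p1", "p1", "p1"],
                "count": [1, 1, 1],
            }
        )
        m = pv.build_incidence(pv.make_dataset(rec, obs), "host_species")
        assert m.m == 2
        assert m.incidence_frequencies().tolist() == [2]

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError):
            pv.build_incidence(pv.make_dataset(pd.DataFrame()), "host_individual")


class TestChao2:
    # frequencies (1,1,2,3,3): S_obs=5, Q1=2, Q2=1
    def test_classic_formula_on_constructed_case(self):
        est = pv.chao2(matrix_from_frequencies([1, 1, 2, 3, 3], 3), "classic")
        assert (est.s_obs, est.q1, est.q2) == (5, 2, 1)
        assert est.estimate == pytest.approx(7.0)  # 5 + 2^2 / (2*1)

    def test_bias_corrected_formula_on_constructed_case(self):
        est = pv.chao2(matrix_from_frequencies([1, 1, 2, 3, 3], 3), "bias_corrected")
        assert est.estimate == pytest.approx(5.5)  # 5 + 2*1 / (2*2)

    def test_no_rare_species_reduces_to_observed(self):
        est = pv.chao2(matrix_from_frequencies([3, 4, 5], 5), "classic")
        assert est.q1 == est.q2 == 0
        assert est.estimate == est.s_obs == 3

    def test_classic_falls_back_to_bias_corrected_term_without_doubletons(self):
        est = pv.chao2(matrix_from_frequencies([1, 1, 3], 3), "classic")
        assert est.q2 == 0
        assert est.estimate == pytest.approx(3 + 2 * 1 / 2)

    def test_zero_morphogroups_gives_zero_estimate(self):
        est = pv.chao2(matrix_from_frequencies([], 4))
        assert est.s_obs == 0 and est.estimate == 0.0

    def test_small_sample_correction_factor(self):
        est = pv.chao2(
            matrix_from_frequencies([1, 1, 2, 3, 3], 4), "classic",
            small_sample_correction=True,
        )
        assert est.estimate == pytest.approx(5 + (3 / 4) * 2.0)

    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=15))
    @settings(deadline=None, derandomize=True)
    def test_estimate_never_below_observed(self, h):
        for variant in ("classic", "bias_corrected"):
            est = pv.chao2(matrix_from_frequencies(h, 6), variant)
            assert est.estimate >= est.s_obs

    def test_mean_chao2_less_biased_than_observed_richness(self):
        # 500 replicate host species, 50 individuals, 20 true parasites at
        # detection probability 0.03 each: most parasites are rare, so
        # observed richness undershoots badly and Chao2 should recover part
        # of the gap.
        rng = np.random.default_rng(42)
        s_true, n, p = 20, 50, 0.03
        chao, sobs = [], []
        for _ in range(500):
            h = (rng.random((n, s_true)) < p).sum(axis=0)
            est = pv.chao2_from_frequencies(h[h > 0], n)
            chao.append(est.estimate)
            sobs.append(est.s_obs)
        assert abs(np.mean(chao) - s_true) < abs(np.mean(sobs) - s_true)


class TestHostSpeciesSummaries:
    def test_uninfected_species_has_zero_estimate(self, make_records_factory):
        ds = pv.make_dataset(make_records_factory([("spA", "fish", 10)], "kelp"))
        summ = pv.host_species_summaries(ds)
        assert summ["chao2_estimate"].tolist() == [0.0]
        assert summ["n_individuals"].tolist() == [10]

    def test_all_singletons_inflate_estimate(self, make_records_factory):
        rec = make_records_factory([("spA", "fish", 10)], "kelp")
        obs = pd.DataFrame(
            {
                "host_individual_id": [f"spA_h{i:03d}" for i in range(3)],
                "morphogroup_id": ["p1", "p2", "p3"],
                "count": 1,
            }
        )
        summ = pv.host_species_summaries(pv.make_dataset(rec, obs))
        assert summ["chao2_estimate"].iloc[0] > summ["s_obs"].iloc[0]

    def test_summaries_match_per_species_incidence_matrices(self, study_dataset):
        """Compositional oracle: the fast summary path must equal chao2
        applied to each species' own hand-built incidence matrix."""
        summ = pv.host_species_summaries(study_dataset).set_index(
            ["ecosystem", "host_species"]
        )
        rec = study_dataset.records
        for (eco, sp), grp in list(rec.groupby(["ecosystem", "host_species"]))[::5]:
            ids = set(grp["host_individual_id"])
            obs = study_dataset.observations[
                study_dataset.observations["host_individual_id"].isin(ids)
            ]
            sub = pv.make_dataset(grp, obs, study_dataset.annotations)
            est = pv.chao2(pv.build_incidence(sub, "host_individual"))
            assert summ.loc[(eco, sp), "chao2_estimate"] == pytest.approx(est.estimate)

    def test_mean_length_ignores_missing_individuals(self, make_records_factory):
        rec = make_records_factory([("spA", "fish", 3)], "kelp", length=100.0)
        rec.loc[2, "host_length_mm"] = np.nan
        summ = pv.host_species_summaries(pv.make_dataset(rec))
        assert summ["mean_length"].iloc[0] == pytest.approx(100.5)


class TestAccumulationCurve:
    def test_toy_expectations_match_exhaustive_enumeration_values(self):
        # h = (1, 2, 4), H = 4: E[S(1)] = (1+2+4)/4 = 7/4;
        # E[S(2)] over the 6 two-host subsets = 14/6.
        m = matrix_from_frequencies([1, 2, 4], 4)
        curve = pv.accumulation_curve(m)
        assert curve.expected_richness[0] == pytest.approx(7 / 4)
        assert curve.expected_richness[1] == pytest.approx(14 / 6)
        assert curve.expected_richness[-1] == pytest.approx(3)

    def test_full_sample_recovers_total_richness(self, random_incidence_factory):
        rng = np.random.default_rng(0)
        m = random_incidence_factory(rng, 8, 12)
        curve = pv.accumulation_curve(m)
        assert curve.expected_richness[-1] == pytest.approx(12)

    def test_curve_matches_enumeration_oracle_on_random_matrices(
        self, random_incidence_factory
    ):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = random_incidence_factory(rng, 6, rng.integers(1, 9))
            curve = pv.accumulation_curve(m)
            for k in range(1, 7):
                assert curve.expected_richness[k - 1] == pytest.approx(
                    pv.accumulation_oracle(m, k), abs=1e-9
                )

    def test_curve_is_nondecreasing_and_concave(self, random_incidence_factory):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = random_incidence_factory(rng, rng.integers(3, 15), rng.integers(2, 10))
            e = pv.accumulation_curve(m).expected_richness
            assert (np.diff(e) >= -1e-12).all()
            assert (np.diff(e, 2) <= 1e-12).all()

    def test_large_H_is_numerically_stable(self):
        rng = np.random.default_rng(3)
        h = rng.integers(1, 1001, size=50)
        mat = np.zeros((1000, 50), dtype=np.int8)
        for j, hj in enumerate(h):
            mat[:hj, j] = 1
        m = pv.IncidenceMatrix(
            [f"u{i}" for i in range(1000)], [f"p{j}" for j in range(50)], mat
        )
        e = pv.accumulation_curve(m).expected_richness
        assert np.isfinite(e).all()
        assert e[-1] == pytest.approx(50)

    def test_monte_carlo_variance_is_reported_and_seeded(self):
        m = matrix_from_frequencies([1, 2, 4], 4)
        c1 = pv.accumulation_curve(m, var_draws=50, seed=5)
        c2 = pv.accumulation_curve(m, var_draws=50, seed=5)
        assert c1.variance is not None
        np.testing.assert_array_equal(c1.variance, c2.variance)
        assert c1.variance[-1] == 0.0  # full sample has no sampling variance

    def test_curve_matches_vegan_exact_accumulation(
        self, tmp_path, random_incidence_factory
    ):
        """Independent cross-check against vegan's exact sample-based
        rarefaction (specaccum, method='exact')."""
        import subprocess

        rng = np.random.default_rng(6)
        m = random_incidence_factory(rng, 9, 14)
        csv = tmp_path / "incidence.csv"
        np.savetxt(csv, m.incidence, fmt="%d", delimiter=",")
        script = tmp_path / "acc.R"
        script.write_text(
            'x <- as.matrix(read.csv("%s", header=FALSE))\n'
            'suppressMessages(library(vegan))\n'
            'cat(specaccum(x, method="exact")$richness, sep=",")\n' % csv
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_values = np.array([float(v) for v in out.stdout.strip().split(",")])
        ours = pv.accumulation_curve(m).expected_richness
        np.testing.assert_allclose(ours, r_values, atol=1e-5)

    def test_oracle_guard_refuses_large_enumerations(self):
        m = matrix_from_frequencies([10], 60)
        with pytest.raises(ValueError, match="guard"):
            pv.accumulation_oracle(m, 30)

    def test_out_of_range_k_is_an_error(self):
        m = matrix_from_frequencies([1, 2], 3)
        with pytest.raises(ValueError):
            pv.accumulation_oracle(m, 4)
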