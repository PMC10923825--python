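import itertools

import numpy as np
import pandas as pd
import pytest

import ctitrack as ct
from ctitrack import decomposition as dec


def records_from(site, biases, changes):
    rows = []
    for i, (b, c) in enumerate(zip(biases, changes)):
        rows.append({"site_id": site, "species_id": f"sp{i}",
                     "thermal_bias": b, "abundance_change": c,
                     "process": dec.classify_process(b, c),
                     "contribution": b * c})
    return pd.DataFrame(rows)


class TestStationReference:
    def test_constant_series(self):
        assert dec.station_reference_cti([14.2, 14.2, 14.2]) == pytest.approx(14.2)
        assert dec.station_reference_cti([14.2], "first_year") == 14.2

    def test_two_conventions(self):
        series = np.array([10.0, 12.0, 14.0])
        assert dec.station_reference_cti(series, "time_mean") == 12.0
        assert dec.station_reference_cti(series, "first_year") == 10.0

    def test_convention_flips_bias_by_reference_difference(self):
        series = np.array([10.0, 12.0, 14.0])
        delta = (dec.station_reference_cti(series, "time_mean")
                 - dec.station_reference_cti(series, "first_year"))
        pref = 18.0
        bias_mean = pref - dec.station_reference_cti(series, "time_mean")
        bias_first = pref - dec.station_reference_cti(series, "first_year")
        assert bias_first - bias_mean == pytest.approx(delta)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            dec.station_reference_cti([])


class TestAbundanceChange:
    def test_constant_weight_zero_change(self):
        years = np.arange(2000, 2010)
        assert dec.species_abundance_change(years, np.full(10, 0.3)) == 0.0

    def test_noiseless_line(self):
        years = np.arange(2000, 2010)
        w = 0.01 * (years - 2000) + 0.1
        assert dec.species_abundance_change(years, w) == pytest.approx(0.01, abs=1e-12)

    def test_five_year_hand_oracle(self):
        years = np.array([1, 2, 3, 4, 5])
        w = np.array([1.0, 3.0, 2.0, 5.0, 4.0])  # slope 0.8 by hand
        assert dec.species_abundance_change(years, w) == pytest.approx(0.8)

    def test_endpoint_estimator(self):
        years = np.array([2000, 2001, 2010])
        w = np.array([0.1, 0.5, 0.6])
        est = dec.species_abundance_change(years, w, estimator="endpoint")
        assert est == pytest.approx(0.5 / 10)


class TestClassify:
    @pytest.mark.parametrize("bias,change,expected", [
        (2.0, 0.5, "tropicalization"),    # both positive
        (-1.5, -0.2, "deborealization"),  # both negative
        (-1.0, 0.5, "borealization"),
        (1.0, -0.5, "detropicalization"),
        (0.0, 0.7, "none"),
        (1.0, 0.0, "none"),
    ])
    def test_quadrant_rule(self, bias, change, expected):
        assert dec.classify_process(bias, change) == expected

    def test_sign_grid_partitions_all_cases(self):
        # enumeration oracle over {-1, 0, 1}^2
        labels = [dec.classify_process(b, c)
                  for b, c in itertools.product([-1.0, 0.0, 1.0], repeat=2)]
        assert len(labels) == 9
        counts = pd.Series(labels).value_counts()
        assert counts["none"] == 5
        for proc in dec.PROCESSES:
            assert counts[proc] == 1


class TestIntensities:
    def test_no_change_all_zero(self):
        recs = records_from("s", [1.0, -1.0], [0.0, 0.0])
        s = dec.process_intensities(recs)
        assert (s.tropicalization == s.deborealization == s.borealization
                == s.detropicalization == 0.0)

    def test_four_quadrant_toy(self):
        # hand oracle: trop=1.0, deb=1.0, bor=0.25, det=0.25, signed=1.5
        recs = records_from("s", [2.0, -2.0, -1.0, 1.0],
                           [0.5, -0.5, 0.25, -0.25])
        s = dec.process_intensities(recs)
        assert s.tropicalization == pytest.approx(1.0)
        assert s.deborealization == pytest.approx(1.0)
        assert s.borealization == pytest.approx(0.25)
        assert s.detropicalization == pytest.approx(0.25)
        assert s.signed_total == pytest.approx(1.5)
        assert dec.trop_minus_deb(s) == pytest.approx(0.0)
        assert dec.gain_minus_loss(s) == pytest.approx(0.0)

    def test_conservation_identity_random_communities(self, rng):
        # brute-force double-loop oracle over 100 random communities
        for _ in range(100):
            n = rng.integers(2, 40)
            biases = rng.normal(0, 3, n)
            changes = rng.normal(0, 0.05, n)
            recs = records_from("s", biases, changes)
            s = dec.process_intensities(recs)
            brute = sum(b * c for b, c in zip(biases, changes))
            identity = (s.tropicalization + s.deborealization
                        - s.borealization - s.detropicalization)
            assert identity == pytest.approx(brute, abs=1e-9)
            assert s.signed_total == pytest.approx(brute, abs=1e-9)

    def test_sign_coherence(self):
        # all warm species increase, all cold decrease -> bor = det = 0
        recs = records_from("s", [2.0, 1.0, -1.0, -2.0],
                           [0.1, 0.2, -0.1, -0.2])
        s = dec.process_intensities(recs)
        assert s.borealization == 0.0 and s.detropicalization == 0.0

    def test_partition_label_counts(self, rng):
        n = 50
        recs = records_from("s", rng.normal(0, 2, n), rng.normal(0, 0.1, n))
        assert recs["process"].isin(list(dec.PROCESSES) + ["none"]).all()
        assert recs["process"].value_counts().sum() == n

    def test_antisymmetry_of_trop_minus_deb(self, rng):
        biases = rng.normal(0, 2, 30)
        changes = rng.normal(0, 0.1, 30)
        s1 = dec.process_intensities(records_from("s", biases, changes))
        s2 = dec.process_intensities(records_from("s", -biases, -changes))
        assert dec.trop_minus_deb(s2) == pytest.approx(-dec.trop_minus_deb(s1))

    def test_gains_only_community(self):
        recs = records_from("s", [2.0, -1.0], [0.3, 0.4])
        s = dec.process_intensities(recs)
        assert dec.gain_minus_loss(s) == pytest.approx(s.tropicalization
                                                       + s.borealization)
        assert s.detropicalization == 0.0 and s.deborealization == 0.0

    def test_dominance_tie_broken_by_fixed_order(self):
        recs = records_from("s", [1.0, -1.0], [0.5, -0.5])  # trop == deb
        s = dec.process_intensities(recs)
        assert s.dominant == "tropicalization"


class TestDominanceShares:
    def summaries(self, dominants):
        return pd.DataFrame({"site_id": [f"s{i}" for i in range(len(dominants))],
                             "dominant": dominants})

    def test_unanimous(self):
        shares = dec.dominance_shares(self.summaries(["tropicalization"] * 4))
        assert shares["tropicalization"] == 100.0
        assert sum(shares.values()) == 100.0

    def test_thirteen_site_hand_oracle(self):
        doms = (["tropicalization"] * 7 + ["deborealization"] * 2
                + ["borealization"] * 2 + ["detropicalization"] * 2)
        shares = dec.dominance_shares(self.summaries(doms))
        assert shares["tropicalization"] == pytest.approx(100 * 7 / 13, abs=0.05)
        assert shares["deborealization"] == pytest.approx(100 * 2 / 13, abs=0.05)

    def test_order_invariance(self, rng):
        doms = list(rng.choice(dec.PROCESSES, 20))
        a = dec.dominance_shares(self.summaries(doms))
        b = dec.dominance_shares(self.summaries(list(reversed(doms))))
        assert a == b


class TestFactorComparison:
    def test_single_level_matches_one_sample_t(self):
        # hand one-sample t on 5 values
        vals = np.array([0.4, 0.1, 0.5, 0.3, 0.2])
        values = pd.DataFrame({"site_id": [f"s{i}" for i in range(5)],
                               "value": vals})
        meta = pd.DataFrame({"site_id": values["site_id"], "basin": ["open"] * 5})
        out = ct.compare_processes_across_factors(values, meta, "basin")
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(5)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(mean)
        assert row["se"] == pytest.approx(se)
        assert row["t_stat"] == pytest.approx(mean / se)

    def test_two_level_recovery(self, rng):
        n = 30
        levels = ["a"] * n + ["b"] * n
        vals = np.concatenate([rng.normal(0.4, 0.2, n), rng.normal(0.0, 0.2, n)])
        values = pd.DataFrame({"site_id": [f"s{i}" for i in range(2 * n)],
                               "value": vals})
        meta = pd.DataFrame({"site_id": values["site_id"], "f": levels})
        out = ct.compare_processes_across_factors(values, meta, "f").set_index("level")
        assert out.loc["a", "mean"] == pytest.approx(0.4, abs=0.15)
        assert out.loc["b", "mean"] == pytest.approx(0.0, abs=0.15)

    def test_constant_shift_equivariance(self, rng):
        vals = rng.normal(0, 0.3, 12)
        values = pd.DataFrame({"site_id": [f"s{i}" for i in range(12)],
                               "value": vals})
        meta = pd.DataFrame({"site_id": values["site_id"],
                             "f": ["a", "b"] * 6})
        base = ct.compare_processes_across_factors(values, meta, "f")
        shifted = ct.compare_processes_across_factors(
            values.assign(value=vals + 1.0), meta, "f")
        np.testing.assert_allclose(shifted["mean"], base["mean"] + 1.0)
        np.testing.assert_allclose(shifted["se"], base["se"])

    def test_per_species_basis_with_site_random_effect(self, rng):
        rows = []
        for i in range(8):
            for j in range(10):
                rows.append({"site_id": f"s{i}",
                             "value": 0.3 + rng.normal(0, 0.1)})
        values = pd.DataFrame(rows)
        meta = pd.DataFrame({"site_id": [f"s{i}" for i in range(8)],
                             "f": ["a"] * 4 + ["b"] * 4})
        out = ct.compare_processes_across_factors(values, meta, "f",
                                                  basis="per_species")
        assert set(out["level"]) == {"a", "b"}
        assert out["mean"].mean() == pytest.approx(0.3, abs=0.1)

    def test_singleton_level_flagged_unreliable(self):
        values = pd.DataFrame({"site_id": ["s0", "s1", "s2"],
                               "value": [0.1, 0.2, 0.3]})
        meta = pd.DataFrame({"site_id": values["site_id"],
                             "f": ["a", "a", "b"]})
        out = ct.compare_processes_across_factors(values, meta, "f").set_index("level")
        assert out.loc["b", "unreliable"].item() is True


class TestEndToEnd:
    def test_decompose_all_on_synthetic_site(self, small_scenario):
        cfg, niches, abundance, _, truth = small_scenario
        prefs = pd.DataFrame({"species_id": [n.species_id for n in niches],
                              "midpoint": [n.optimum for n in niches]})
        cti = ct.cti_time_series(abundance, prefs)
        records, summaries = ct.decompose_all(abundance, prefs, cti)
        assert summaries.shape[0] == 1
        s = summaries.iloc[0]
        identity = (s["tropicalization"] + s["deborealization"]
                    - s["borealization"] - s["detropicalization"])
        assert identity == pytest.approx(records["contribution"].sum(), abs=1e-9)

    def test_signed_total_agrees_with_cti_direction_under_warming(self):
        # niche-tracking warming sites should show signed_total > 0 together
        # with a positive estimated CTI trend in most replicates
        agree = 0
        n_reps = 25
        for seed in range(n_reps):
            cfg = ct.ScenarioConfig(seed=900 + seed, observation_noise_sd=0.15)
            niches = ct.sample_niche_pool(cfg)
            ab, _, _ = ct.simulate_community_series(cfg, niches)
            prefs = pd.DataFrame({"species_id": [n.species_id for n in niches],
                                  "midpoint": [n.optimum for n in niches]})
            cti = ct.cti_time_series(ab, prefs)
            est = ct.fit_site_trend(cti["year"].to_numpy(), cti["cti"].to_numpy())
            recs = ct.decompose_site(ab, prefs, cti)
            s = ct.process_intensities(recs, site_id="x")
            agree += (s.signed_total > 0) == (est.slope > 0)
        assert agree / n_reps >= 0.9
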