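"""Construction of enhancer-system reaction networks."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shadownoise import (EnhancerSpec, ModelError, ModulationError,
                         NegativeRateError, RateParameters, SystemConfig,
                         apply_rate_modulation, build_network,
                         canonical_site_multiset, duplicate_system,
                         enumerate_configurations, load_config,
                         make_kruppel_config, save_config, split_system,
                         transcription_rate)
from shadownoise.model_core import (SUBADDITIVE_D1, SUBADDITIVE_D2,
                                    SUPERADDITIVE_D2, config_from_dict,
                                    config_to_dict)


class TestKruppelModel:
    def test_two_single_site_enhancers_with_fitted_rates(self):
        cfg = make_kruppel_config()
        assert [e.site_counts for e in cfg.enhancers] == [(1, 0), (0, 1)]
        assert cfg.regime == "additive"
        p = cfg.params
        assert p.transcription_rate == (120.0, 140.0)
        assert p.burst_size == (4, 12)
        assert p.kon == (0.36, 0.19) and p.koff == (1.8, 1.5)
        assert p.burst_rate == (0.33, 0.29)
        assert p.tf_degradation == (2.7, 3.9)
        assert p.mrna_degradation == 1.96

    def test_network_has_seven_species_eleven_reactions(self, kruppel_network):
        assert sorted(kruppel_network.species_names) == [
            "A0", "A1", "B0", "B1", "R", "T1", "T2"]
        assert len(kruppel_network.reactions) == 11
        kinds = sorted(r.name.split(":")[0] for r in kruppel_network.reactions)
        assert kinds.count("bind") == 2 and kinds.count("unbind") == 2
        assert kinds.count("transcribe") == 2
        assert kinds.count("burst") == 2 and kinds.count("degrade") == 3

    def test_initial_state_is_empty_enhancers(self, kruppel_network):
        assert kruppel_network.initial_state == {"A0": 1, "B0": 1}
        assert kruppel_network.conservation_groups == [["A0", "A1"], ["B0", "B1"]]


class TestBuildNetwork:
    def test_two_site_enhancer_enumerates_four_occupancy_states(self):
        cfg = SystemConfig(enhancers=((2, 0),))
        net = build_network(cfg)
        states = [s for s in net.species if s.role == "enhancer_state"]
        assert len(states) == 4
        # the doubly-occupied state transcribes at 2*r1
        full = next(r for r in net.reactions if r.name == "transcribe:A11")
        assert full.rate == pytest.approx(240.0)

    def test_burst_reactions_have_cluster_stoichiometry(self, kruppel_network):
        burst = {r.name: dict(r.products) for r in kruppel_network.reactions
                 if r.name.startswith("burst")}
        assert burst == {"burst:T1": {"T1": 4}, "burst:T2": {"T2": 12}}

    def test_all_propensities_are_mass_action_of_order_at_most_two(self):
        for cfg in enumerate_configurations(2, 3, 2):
            for r in build_network(cfg).reactions:
                assert r.order in ("constant", "first", "second")

    def test_site_count_bookkeeping(self):
        # distinct (state, site) binding targets must equal total sites * 2^(k-1)
        # summed over states; per-site coverage equals the site totals.
        cfg = SystemConfig(enhancers=((2, 1), (0, 1)))
        net = build_network(cfg)
        binds = [r for r in net.reactions if r.name.startswith("bind")]
        by_tf = {"T1": 0, "T2": 0}
        for r in binds:
            tf = [n for n in r.propensity_species if n.startswith("T")][0]
            by_tf[tf] += 1
        # each k-site enhancer has k * 2^(k-1) (state, empty-site) pairs
        assert by_tf["T1"] == 2 * 2 ** 2
        assert by_tf["T2"] == 1 * 2 ** 2 + 1

    def test_zero_site_enhancer_is_rejected(self):
        with pytest.raises(ModelError):
            EnhancerSpec((0, 0))

    def test_empty_enhancer_list_is_rejected(self):
        with pytest.raises(ModelError):
            SystemConfig(enhancers=())

    def test_oversized_enhancer_is_refused(self):
        cfg = SystemConfig(enhancers=((13, 0),))
        with pytest.raises(ModelError, match="cap"):
            build_network(cfg)

    def test_only_bound_tf_types_become_species(self):
        net = build_network(SystemConfig(enhancers=((2, 0),)))
        assert "T2" not in net.species_names

    def test_additive_networks_with_equal_totals_share_canonical_site_form(self):
        groups = {}
        for cfg in enumerate_configurations(4, 4, 2):
            groups.setdefault(cfg.total_site_counts, set()).add(
                canonical_site_multiset(cfg))
        for key, forms in groups.items():
            assert len(forms) == 1, key

    def test_saturation_uses_joint_occupancy_with_single_conservation_group(self):
        cfg = SystemConfig(enhancers=((1,), (1,)),
                           params=RateParameters(
                               kon=(0.36,), koff=(1.8,), burst_rate=(0.33,),
                               burst_size=(4,), tf_degradation=(2.7,),
                               transcription_rate=(120.0,)),
                           regime="saturation")
        net = build_network(cfg)
        assert len(net.conservation_groups) == 1
        assert len(net.conservation_groups[0]) == 4
        # any joint state with >= 1 bound enhancer transcribes at r1
        rates = {r.name: r.rate for r in net.reactions
                 if r.name.startswith("transcribe")}
        assert len(rates) == 3 and all(v == 120.0 for v in rates.values())


class TestTranscriptionRate:
    enh2 = (EnhancerSpec((1, 1)),)

    def test_additive_rate_is_site_weighted_sum(self, table1_params):
        rate = transcription_rate([(1, 1)], self.enh2, table1_params, "additive")
        assert rate == pytest.approx(260.0)

    @pytest.mark.parametrize("regime", ["subadditive", "superadditive"])
    def test_sub_and_superadditivity_do_not_touch_the_rate_formula(
            self, table1_params, regime):
        assert transcription_rate([(1, 1)], self.enh2, table1_params, regime) == \
            transcription_rate([(1, 1)], self.enh2, table1_params, "additive")

    def test_saturation_and_synergy_occupancy_rules(self, table1_params):
        enh4 = tuple(EnhancerSpec((1, 0)) for _ in range(4))
        empty = [(0,)] * 4
        assert transcription_rate(empty, enh4, table1_params, "saturation") == 0.0
        one = [(1,), (0,), (0,), (0,)]
        assert transcription_rate(one, enh4, table1_params, "saturation") == 120.0
        three = [(1,), (1,), (1,), (0,)]
        assert transcription_rate(three, enh4, table1_params, "synergy") == 0.0
        allb = [(1,)] * 4
        assert transcription_rate(allb, enh4, table1_params, "synergy") == 120.0
        # the single rate r is a config knob defaulting to r1
        assert transcription_rate(allb, enh4, table1_params, "synergy",
                                  saturation_rate=77.0) == 77.0

    def test_unknown_regime_is_rejected(self, table1_params):
        with pytest.raises(ModelError):
            transcription_rate([(1, 1)], self.enh2, table1_params, "quadratic")


class TestRateModulation:
    def test_subadditive_shifts_with_default_caption_coefficients(self, table1_params):
        eff = apply_rate_modulation(table1_params, "subadditive", 2)
        assert eff.kon[0] == pytest.approx(0.36 - 2 * SUBADDITIVE_D1[0])  # 0.28
        assert eff.koff[0] == pytest.approx(1.8 + 2 * SUBADDITIVE_D2[0])  # 3.3
        assert eff.kon[1] == pytest.approx(0.19 - 2 * SUBADDITIVE_D1[1])

    def test_superadditive_flips_the_signs(self, table1_params):
        eff = apply_rate_modulation(table1_params, "superadditive", 2)
        assert eff.koff[0] == pytest.approx(1.8 - 2 * SUPERADDITIVE_D2[0])  # 1.0
        assert eff.kon[0] == pytest.approx(0.36 + 2 * 0.01)

    def test_additive_returns_params_unchanged(self, table1_params):
        assert apply_rate_modulation(table1_params, "additive", 3) is table1_params

    def test_negative_modulated_rate_is_an_error_not_a_clamp(self, table1_params):
        with pytest.raises(NegativeRateError):
            apply_rate_modulation(table1_params, "subadditive", 10)

    def test_modulation_guard_forbids_double_application(self, table1_params):
        once = apply_rate_modulation(table1_params, "subadditive", 2)
        assert once.modulated
        with pytest.raises(ModulationError):
            apply_rate_modulation(once, "subadditive", 2)

    def test_subadditive_duplication_series_kon_strictly_decreases(self, table1_params):
        base = SystemConfig(enhancers=((1, 0),), regime="subadditive")
        kons = []
        for copies in range(1, 5):
            dup = duplicate_system(base, copies)
            eff = apply_rate_modulation(dup.params, "subadditive", dup.n_enhancers)
            kons.append(eff.kon[0])
        assert all(a > b for a, b in zip(kons, kons[1:]))


def brute_force_multisets(max_enh, max_sites, n_tf):
    """Independent enumeration oracle: frozen multisets of nonzero vectors."""
    vectors = [v for v in itertools.product(range(max_sites + 1), repeat=n_tf)
               if 0 < sum(v) <= max_sites]
    found = set()
    for n in range(1, max_enh + 1):
        for combo in itertools.product(vectors, repeat=n):
            if sum(sum(v) for v in combo) <= max_sites:
                found.add(tuple(sorted(combo)))
    return found


class TestEnumeration:
    def test_smallest_grid(self):
        configs = enumerate_configurations(1, 1, 2)
        assert [[e.site_counts for e in c.enhancers] for c in configs] == \
            [[(0, 1)], [(1, 0)]]

    def test_counts_match_brute_force_enumeration(self):
        for bounds in [(2, 2, 2), (4, 4, 2), (3, 2, 1)]:
            configs = enumerate_configurations(*bounds)
            assert len(configs) == len(brute_force_multisets(*bounds))
        assert len(enumerate_configurations(2, 2, 2)) == 8

    def test_no_two_configs_equal_up_to_reordering(self):
        configs = enumerate_configurations(4, 4, 2)
        labels = [c.label() for c in configs]
        assert len(labels) == len(set(labels))

    @given(st.integers(1, 3), st.integers(1, 3), st.integers(1, 2))
    @settings(max_examples=10, deadline=None)
    def test_enumeration_is_deterministic_and_within_bounds(self, e, s, t):
        a = enumerate_configurations(e, s, t)
        b = enumerate_configurations(e, s, t)
        assert [c.label() for c in a] == [c.label() for c in b]
        for c in a:
            assert c.n_enhancers <= e and sum(c.total_site_counts) <= s


class TestDuplicationAndSplitting:
    def test_duplication_scales_enhancers_and_sites(self):
        base = SystemConfig(enhancers=((2, 0),))
        dup = duplicate_system(base, 3)
        assert dup.n_enhancers == 3
        assert dup.total_site_counts == (6, 0)
        assert dup.regime == base.regime

    def test_single_copy_is_identity(self):
        base = SystemConfig(enhancers=((2, 0),))
        assert duplicate_system(base, 1) == base

    def test_bad_copy_counts_and_mixed_archetypes_are_rejected(self):
        base = SystemConfig(enhancers=((2, 0),))
        with pytest.raises(ModelError):
            duplicate_system(base, 0)
        mixed = SystemConfig(enhancers=((2, 0), (1, 0)))
        with pytest.raises(ModelError):
            duplicate_system(mixed, 2)

    def test_splitting_preserves_totals_and_spreads_evenly(self):
        cfg = split_system((4, 0), 4)
        assert [e.site_counts for e in cfg.enhancers] == [(1, 0)] * 4
        cfg = split_system((2, 2), 2)
        assert [e.site_counts for e in cfg.enhancers] == [(1, 1)] * 2
        cfg = split_system((2, 1), 3)
        assert cfg.total_site_counts == (2, 1)
        assert all(e.total_sites >= 1 for e in cfg.enhancers)

    def test_splitting_more_enhancers_than_sites_fails(self):
        with pytest.raises(ModelError):
            split_system((1, 0), 2)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SystemConfig(enhancers=((2, 1), (0, 1)), regime="subadditive",
                           d1=(0.05, 0.01), d2=(0.5, 0.5))
        path = tmp_path / "system.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_json_round_trip_with_table_names(self, tmp_path):
        cfg = make_kruppel_config()
        path = tmp_path / "system.json"
        save_config(cfg, path)
        loaded = load_config(path)
        assert loaded == cfg
        d = config_to_dict(cfg)
        assert d["params"]["beta1"] == 0.33 and d["params"]["n2"] == 12
        assert config_from_dict(d) == cfg

    def test_unknown_parameter_name_is_rejected(self):
        with pytest.raises(ModelError):
            config_from_dict({"enhancers": [[1, 0]], "params": {"kof1": 2.0}})
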