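"""Macrocolumn geometry, wiring and the parameter enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iwavesim.config import (
    ConnectionRule,
    LayerSpec,
    default_config,
)
from iwavesim.network import (
    apply_parameter_vector,
    build_macrocolumn,
    conduction_delay,
    generate_lattice,
    load_network,
    save_network,
)

EXPECTED_COUNTS = {
    "L23_IT": 158, "L23_BC": 79, "L5_PTN": 158, "L5_BC": 79,
    "L6_IT": 158, "L6_BC": 79,
}


class TestLattice:
    def test_default_yields_79_sites(self):
        lat = generate_lattice(50.0, 500.0, 79)
        assert lat.n_sites == 79
        r = np.hypot(lat.positions[:, 0], lat.positions[:, 1])
        assert (r <= 250.0 + 1e-9).all()

    def test_single_site_is_center(self):
        lat = generate_lattice(50.0, 500.0, 1)
        assert lat.n_sites == 1
        np.testing.assert_allclose(lat.positions[0], [0.0, 0.0], atol=1e-9)

    def test_interior_sites_have_six_neighbors_at_spacing(self):
        # brute-force pairwise-distance check of triangular packing
        lat = generate_lattice(50.0, 500.0, 79)
        d = np.linalg.norm(
            lat.positions[:, None] - lat.positions[None, :], axis=-1)
        # stay two rings clear of the trim boundary so every geometric
        # neighbor is guaranteed to be among the kept sites
        interior = np.hypot(*lat.positions.T) < 150.0
        for i in np.nonzero(interior)[0]:
            neighbors = np.isclose(d[i], 50.0, atol=1e-6).sum()
            assert neighbors == 6

    def test_deterministic(self):
        a = generate_lattice(50.0, 500.0, 79)
        b = generate_lattice(50.0, 500.0, 79)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_shortfall_error_names_the_gap(self):
        with pytest.raises(ValueError, match="short by"):
            generate_lattice(50.0, 100.0, 79)

    @pytest.mark.parametrize("kwargs", [
        dict(spacing=0.0), dict(n_target=0),
    ])
    def test_invalid_arguments(self, kwargs):
        args = dict(spacing=50.0, footprint_diameter=500.0, n_target=10)
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_lattice(**args)


class TestBuild:
    def test_default_population_counts_and_total(self, default_network):
        counts = default_network.neurons["population"].value_counts()
        for pop, n in EXPECTED_COUNTS.items():
            assert counts[pop] == n
        assert default_network.n_cortical == 711
        for aff in (p for p in counts.index if p.endswith("_AFF")):
            assert counts[aff] == 79

    def test_single_microcolumn_has_nine_cortical_neurons(self):
        net = build_macrocolumn(default_config(n_microcolumns=1), seed=0)
        assert net.n_cortical == 9

    def test_depths_respect_layer_bounds(self, default_network):
        cfg = default_network.config
        for layer in cfg["layers"]:
            for pop in (layer.excitatory_type, layer.inhibitory_type):
                z = default_network.neurons.query(
                    "population == @pop")["z"]
                assert (z >= layer.depth_top).all()
                assert (z <= layer.depth_bottom).all()

    def test_full_probability_rule_connects_every_pair(self):
        # exhaustive count on a 2-microcolumn fixture with p = 1
        cfg = default_config(n_microcolumns=2)
        cfg["rules"] = [ConnectionRule("L23_IT", "L23_IT", 1.0, 1.0)]
        net = build_macrocolumn(cfg, seed=0)
        n = 4  # 2 excitatory per layer x 2 microcolumns
        assert len(net.synapses) == n * n - n  # no autapses
        assert (net.synapses["pre"] != net.synapses["post"]).all()

    def test_empty_rules_error(self):
        cfg = default_config(n_microcolumns=2)
        cfg["rules"] = []
        with pytest.raises(ValueError, match="empty"):
            build_macrocolumn(cfg, seed=0)

    def test_layer_outside_column_error(self):
        cfg = default_config(n_microcolumns=2)
        cfg["layers"][-1] = LayerSpec("L6", 2200.0, 3000.0, "L6_IT", "L6_BC")
        with pytest.raises(ValueError, match="exceeds"):
            build_macrocolumn(cfg, seed=0)

    def test_same_seed_reproduces_wiring(self, small_network):
        again = build_macrocolumn(default_config(n_microcolumns=2), seed=1)
        pd.testing.assert_frame_equal(small_network.synapses, again.synapses)

    def test_connection_frequency_within_binomial_interval(self):
        # empirical p over 10 seeds stays inside a 99% CI of the rule p
        cfg = default_config(n_microcolumns=4)
        p = 0.3
        cfg["rules"] = [ConnectionRule("L23_IT", "L5_PTN", p, 1.0)]
        n_pairs = 8 * 8
        counts = [
            len(build_macrocolumn(cfg, seed=s).synapses) for s in range(10)
        ]
        total = sum(counts)
        lo, hi = stats.binom.interval(0.99, 10 * n_pairs, p)
        assert lo <= total <= hi


class TestConductionDelay:
    def test_zero_distance_gives_synaptic_delay(self):
        assert conduction_delay((0, 0, 0), (0, 0, 0)) == pytest.approx(0.2)

    def test_hand_computed_example(self):
        # 570 um at 0.570 m/s is exactly 1 ms of conduction
        d = conduction_delay((0, 0, 0), (570.0, 0, 0), velocity=0.570)
        assert d == pytest.approx(1.2)

    def test_inverse_proportionality_to_velocity(self):
        d1 = conduction_delay((0, 0, 0), (100.0, 0, 0), velocity=1.0)
        d2 = conduction_delay((0, 0, 0), (100.0, 0, 0), velocity=0.5)
        assert (d2 - 0.2) == pytest.approx(2 * (d1 - 0.2))

    def test_zero_velocity_error(self):
        with pytest.raises(ValueError):
            conduction_delay((0, 0, 0), (1, 0, 0), velocity=0.0)

    def test_all_synapse_delays_consistent(self, small_network):
        syn = small_network.synapses
        assert (syn["delay_ms"] >= 0.2 - 1e-12).all()
        np.testing.assert_allclose(
            syn["delay_ms"], 0.2 + syn["cond_base_ms"], rtol=1e-12)


class TestParameterVector:
    def test_enumeration_has_98_entries(self, default_network):
        space = default_network.parameter_space
        assert len(space) == 98

    def test_category_sizes_match_printed_table(self, default_network):
        space = default_network.parameter_space
        sizes = pd.Series(space.categories).value_counts().to_dict()
        assert sizes == {
            "weight": 38, "velocity": 24, "aff_delay_mean": 6,
            "aff_delay_sd": 6, "activation": 12, "noise_amp": 6,
            "noise_rate": 6,
        }

    def test_printed_bounds(self, default_network):
        space = default_network.parameter_space
        expected = {
            "weight": (0.1, 10.0), "velocity": (0.25, 2.0),
            "aff_delay_mean": (0.2, 2.0), "aff_delay_sd": (0.1, 1.0),
            "activation": (0.0, 1.0), "noise_amp": (1.0, 50.0),
            "noise_rate": (0.0, 1.0),
        }
        for name, lo, hi in zip(space.names, space.lower, space.upper):
            cat = name.split(":")[0]
            assert (lo, hi) == expected[cat]

    def test_identity_vector_leaves_network_unchanged(self, small_network):
        space = small_network.parameter_space
        net2 = apply_parameter_vector(
            small_network, space.default_values(small_network))
        np.testing.assert_allclose(net2.synapses["weight"],
                                   small_network.synapses["weight"])
        np.testing.assert_allclose(net2.synapses["delay_ms"],
                                   small_network.synapses["delay_ms"])

    def test_weight_scalar_touches_only_its_projection(self, small_network):
        space = small_network.parameter_space
        values = space.default_values(small_network)
        proj = "L23_IT->L5_PTN"
        values[space.index(f"weight:{proj}")] = 10.0
        net2 = apply_parameter_vector(small_network, values)
        mask = small_network.synapses["projection"] == proj
        np.testing.assert_allclose(
            net2.synapses.loc[mask, "weight"],
            10.0 * small_network.synapses.loc[mask, "weight"])
        np.testing.assert_allclose(
            net2.synapses.loc[~mask, "weight"],
            small_network.synapses.loc[~mask, "weight"])

    def test_out_of_range_error_names_parameter(self, small_network):
        space = small_network.parameter_space
        values = space.default_values(small_network)
        values[space.index("activation:L5_PTN")] = 1.5
        with pytest.raises(ValueError, match="activation:L5_PTN"):
            apply_parameter_vector(small_network, values)

    def test_wrong_length_error(self, small_network):
        with pytest.raises(ValueError, match="length"):
            apply_parameter_vector(small_network, np.zeros(7))


def test_network_round_trips_through_csv(tmp_path, small_network):
    save_network(small_network, tmp_path)
    back = load_network(tmp_path)
    pd.testing.assert_frame_equal(back.neurons, small_network.neurons)
    pd.testing.assert_frame_equal(back.synapses, small_network.synapses)
    assert back.activation == small_network.activation
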