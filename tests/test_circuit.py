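"""Circuit construction, surgery, anatomy table and serialization."""

import numpy as np
import pytest

import wormloop as wl
from wormloop import io as wio
from wormloop.circuit import match, unit_muscle_map
from wormloop.errors import ConfigurationError

WORM_PARAMS = dict(
    C_n=0.05, g_n=1.0, C_m=0.1, g_m=1.0,
    syn_Vx=-30.0, syn_theta=5.0, act_Vx=-30.0, act_theta=5.0,
    w_m=10.0, k=5.0, c=0.05, C_N=1.0, C_T=0.5,
    nf_Vx=3.0, nf_theta=1.0, pf_Vx=1.0, pf_theta=1.0,
    I_avb=40.0, I_rib=40.0,
    w_rib_d=1.0, w_rib_v=1.2, w_avb_d=1.0, w_avb_v=1.2,
    w_eM_d=1.0, w_eM_v=1.5, w_eI_d=1.0, w_eI_v=1.0,
    w_iM_d=1.0, w_iM_v=1.0, w_ii=0.5,
    w_nf_d=1.0, w_nf_v=1.0, w_nf_head=1.0,
    w_pf=0.3, w_pf_head=0.3,
    w_gap_mm=0.3, w_gap_ee=0.2, w_gap_ii=0.2, w_gap_head=0.2,
)


class TestTwoNodeLoop:
    def test_node_and_edge_counts(self, two_node_config):
        cfg = two_node_config
        assert len(cfg.neurons) == 1
        assert len(cfg.muscles) == 1
        assert len(cfg.chemical_synapses) == 1
        assert len(cfg.feedbacks) == 1
        assert len(cfg.gap_junctions) == 0
        assert cfg.feedbacks[0].polarity == "negative"
        assert cfg.chemical_synapses[0].reversal == "E_Ca"

    def test_zero_feedback_weight_is_valid(self, two_node_params):
        p = dict(two_node_params, w_f=0.0)
        cfg = wl.build_two_node_loop(p)
        assert cfg.feedbacks[0].weight == 0.0

    def test_missing_parameter_names_field(self, two_node_params):
        p = dict(two_node_params)
        del p["w_che"]
        with pytest.raises(ConfigurationError, match="w_che"):
            wl.build_two_node_loop(p)


class TestFunctionalUnit:
    def test_composition(self, unit_config):
        cfg = unit_config
        assert len(cfg.neurons) == 4
        assert len(cfg.muscles) == 2
        classes = {n.neuron_class for n in cfg.neurons}
        assert classes == {"excitatory_motoneuron", "inhibitory_motoneuron"}
        # one negative feedback per side
        sides = sorted(cfg.muscle(f.source_muscle).side for f in cfg.feedbacks)
        assert sides == ["dorsal", "ventral"]

    def test_input_ratio_sets_dorsal_drive(self, unit_params):
        cfg = wl.build_functional_unit(unit_params, input_ratio=2.0)
        u1 = cfg.neuron("VB1").i_external
        u2 = cfg.neuron("DB1").i_external
        assert u2 == pytest.approx(2.0 * u1)

    def test_nonpositive_ratio_rejected(self, unit_params):
        with pytest.raises(ValueError):
            wl.build_functional_unit(unit_params, input_ratio=0.0)

    def test_excitatory_to_inhibitory_ablation(self, unit_config):
        inhib = {n.id for n in unit_config.neurons
                 if n.neuron_class == "inhibitory_motoneuron"}
        sel = lambda e: (getattr(e, "kind", "") == "chemical"  # noqa: E731
                         and e.post in inhib and e.pre not in inhib)
        ablated = wl.modify_connection(unit_config, sel, 0.0)
        ablated.validate()
        weights = [s.weight for s in ablated.chemical_synapses
                   if s.post in inhib and s.pre not in inhib]
        assert weights and all(w == 0.0 for w in weights)
        # original untouched
        assert all(
            s.weight > 0 for s in unit_config.chemical_synapses
            if s.post in inhib and s.pre not in inhib
        )


class TestCoupledUnits:
    def make(self, unit_params, coupling, region="body_body"):
        a = wl.build_functional_unit(unit_params, 1.25, unit_index=1)
        b = wl.build_functional_unit(unit_params, 1.25, unit_index=2)
        return wl.build_coupled_units(a, b, coupling, region)

    def test_body_coupling_adds_expected_junctions(self, unit_params):
        cfg = self.make(unit_params, {
            "muscle_muscle": 0.5, "inhibitory_inhibitory": 0.2,
            "excitatory_excitatory": 0.1, "positive_feedback": 0.3,
        })
        gap_pairs = {frozenset((g.a, g.b)) for g in cfg.gap_junctions}
        assert frozenset(("DM1", "DM2")) in gap_pairs
        assert frozenset(("VM1", "VM2")) in gap_pairs
        assert frozenset(("DD1", "DD2")) in gap_pairs
        assert frozenset(("DB1", "DB2")) in gap_pairs
        pf = [f for f in cfg.feedbacks if f.polarity == "positive"]
        assert {(f.source_muscle, f.target_neuron) for f in pf} == {
            ("DM1", "DB2"), ("VM1", "VB2")
        }

    def test_unknown_coupling_key_rejected(self, unit_params):
        with pytest.raises(ConfigurationError, match="coupling"):
            self.make(unit_params, {"muscle_mucsle": 0.5})

    def test_zero_coupling_keeps_units_disjoint(self, unit_params):
        cfg = self.make(unit_params, {"muscle_muscle": 0.0,
                                      "inhibitory_inhibitory": 0.0,
                                      "excitatory_excitatory": 0.0,
                                      "positive_feedback": 0.0})
        assert len(cfg.gap_junctions) == 0


class TestSimplifiedWorm:
    def test_printed_counts(self):
        cfg = wl.build_simplified_worm(WORM_PARAMS)
        assert len(cfg.neurons) == 42
        assert len(cfg.muscles) == 24

    def test_body_units_contribute_four_motoneurons_each(self):
        cfg = wl.build_simplified_worm(WORM_PARAMS)
        for unit in range(4, 13):
            quartet = [n for n in cfg.neurons if n.unit_index == unit]
            assert len(quartet) == 4
        head = [n for n in cfg.neurons if n.unit_index == 1]
        premotor = [n for n in cfg.neurons if n.neuron_class == "premotor"]
        assert len(head) == 4 and len(premotor) == 2
        assert 9 * 4 + 4 + 2 == len(cfg.neurons)

    def test_unit_map_covers_twelve_units(self):
        cfg = wl.build_simplified_worm(WORM_PARAMS)
        umap = cfg.unit_map
        assert sorted(umap) == list(range(1, 13))
        for u, (d, v, segs) in umap.items():
            assert d == f"DM{u}" and v == f"VM{u}"
            assert segs == (u, u + 1)

    def test_rmd_option_adds_two_neurons(self):
        cfg = wl.build_simplified_worm(WORM_PARAMS, include_rmd=True)
        assert len(cfg.neurons) == 44
        assert {n.id for n in cfg.neurons} >= {"RMDD", "RMDV"}


class TestModifyConnection:
    def test_identity_scale(self, unit_config):
        same = wl.modify_connection(unit_config, match(kind="chemical"), 1.0)
        assert wio.dumps_config(same) == wio.dumps_config(unit_config)

    def test_scales_compose_multiplicatively(self, unit_config):
        sel = match(kind="feedback", polarity="negative")
        twice = wl.modify_connection(
            wl.modify_connection(unit_config, sel, 2.0), sel, 3.0
        )
        direct = wl.modify_connection(unit_config, sel, 6.0)
        assert wio.dumps_config(twice) == wio.dumps_config(direct)

    def test_ratio_bookkeeping(self, unit_config):
        sel = lambda e: (getattr(e, "kind", "") == "chemical"  # noqa: E731
                         and e.pre == "DB1" and e.post == "DM1")
        scaled = wl.modify_connection(unit_config, sel, 2.0)
        w_d = next(s.weight for s in scaled.chemical_synapses
                   if (s.pre, s.post) == ("DB1", "DM1"))
        w_d0 = next(s.weight for s in unit_config.chemical_synapses
                    if (s.pre, s.post) == ("DB1", "DM1"))
        assert w_d == pytest.approx(2.0 * w_d0)

    def test_empty_selection_raises(self, unit_config):
        with pytest.raises(LookupError):
            wl.modify_connection(unit_config, match(kind="gap"), 0.5)

    def test_negative_scale_rejected(self, unit_config):
        with pytest.raises(ValueError):
            wl.modify_connection(unit_config, match(kind="chemical"), -1.0)


class TestSerialization:
    @pytest.mark.parametrize("builder", ["two_node", "unit", "worm"])
    def test_round_trip_identity(self, builder, two_node_params, unit_params):
        if builder == "two_node":
            cfg = wl.build_two_node_loop(two_node_params)
        elif builder == "unit":
            cfg = wl.build_functional_unit(unit_params, 1.25)
        else:
            cfg = wl.build_simplified_worm(WORM_PARAMS)
        text = wio.dumps_config(cfg)
        again = wio.dumps_config(wio.loads_config(text))
        assert text == again

    def test_graph_export_shapes(self, unit_config):
        g = wio.config_to_graph(unit_config)
        assert g.number_of_nodes() == unit_config.n_nodes
        n_edges = (len(unit_config.chemical_synapses)
                   + len(unit_config.gap_junctions)
                   + len(unit_config.feedbacks))
        assert g.number_of_edges() == n_edges

    def test_graph_sanity_no_muscle_presynaptic(self):
        cfg = wl.build_simplified_worm(WORM_PARAMS)
        muscle_ids = set(cfg.muscle_ids)
        assert not any(s.pre in muscle_ids for s in cfg.chemical_synapses)
        assert all(f.source_muscle in muscle_ids for f in cfg.feedbacks)
        assert not any(f.target_neuron in muscle_ids for f in cfg.feedbacks)


class TestUnitMuscleMap:
    def test_twelve_rows_both_sides(self):
        table = unit_muscle_map()
        assert len(table) == 12
        assert table["dorsal_cells"].str.len().gt(0).all()
        assert table["ventral_cells"].str.len().gt(0).all()

    def test_head_to_tail_order_and_segments(self):
        table = unit_muscle_map()
        assert list(table["unit"]) == list(range(1, 13))
        assert list(table["segments"]) == [(u, u + 1) for u in range(1, 13)]

    def test_paired_cells_share_a_unit(self):
        table = unit_muscle_map()
        row = table[table["unit"] == 1].iloc[0]
        assert "vBWM01" in row["ventral_cells"] and "vBWM02" in row["ventral_cells"]
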