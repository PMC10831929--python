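"""Model-file parsing, validation, round trips, and influence graphs."""

import itertools

import pytest

import boolpop as bp
from boolpop import expr, model_io
from boolpop.expr import ParseError
from boolpop.model import ModelError

BND = """\
// three-signal toy
trigger = Trigger;
node Trigger { logic = Trigger; rate_up = 0; rate_down = 0; class = utility; }
node Prol_KC {
  logic = Trigger;
  rate_up = $k_Prol_KC_up;
  rate_down = 0.1;
  class = cell_state;
}
node STAT3 { logic = Prol_KC; rate_up = 1; rate_down = 0.5;
             class = transcription_factor; }
node AMP { logic = Prol_KC AND STAT3; rate_up = $k_AMP_up; rate_down = 1; }
node IL10 { logic = STAT3; rate_up = 1; rate_down = 5; class = ligand; }
node IL10R { logic = IL10; rate_up = 1; rate_down = 1; class = receptor; }
"""

CFG = """\
$k_Prol_KC_up = 0.8;
$k_AMP_up = 1.2;
Trigger.istate = 1;
n_trajectories = 500;
t_max = 20;
window_dt = 1;
seed = 3;
"""

UPP = """\
division = Prol_KC;   // stand-in utility wiring for the round trip
steps = 20;
step_dt = 1.0;
death_precedence = true;
$k_AMP_up u= 2 * p[IL10];
"""


@pytest.fixture()
def parsed():
    net = model_io.parse_logic_file(BND)
    cfg = model_io.parse_config(CFG, net)
    popcfg = model_io.parse_population_file(UPP, net)
    return net, cfg, popcfg


class TestLogicParsing:
    def test_and_rule_requires_both_inputs(self, parsed):
        net, _, _ = parsed
        amp = net.node("AMP")
        assert expr.bool_eval(amp.logic, {"Prol_KC": 1, "STAT3": 1}) == 1
        assert expr.bool_eval(amp.logic, {"Prol_KC": 1, "STAT3": 0}) == 0

    def test_single_input_copy_rule(self, parsed):
        net, _, _ = parsed
        assert expr.bool_eval(net.node("IL10R").logic, {"IL10": 1}) == 1
        assert expr.bool_eval(net.node("IL10R").logic, {"IL10": 0}) == 0

    def test_undeclared_reference_rejected(self):
        bad = BND + "node Extra { logic = XYZ; rate_up = 1; rate_down = 1; }\n"
        with pytest.raises((ParseError, ModelError), match="XYZ"):
            model_io.parse_logic_file(bad)

    def test_duplicate_node_rejected(self):
        bad = BND + "node AMP { logic = STAT3; rate_up = 1; rate_down = 1; }\n"
        with pytest.raises(ParseError, match="duplicate"):
            model_io.parse_logic_file(bad)

    def test_syntax_error_reports_line(self):
        bad = "node A {\n  logic = B AND;\n  rate_up = 1;\n  rate_down = 1;\n}\n" \
              "node B { logic = A; rate_up = 1; rate_down = 1; }\n"
        with pytest.raises(ParseError, match="line 2"):
            model_io.parse_logic_file(bad)

    def test_trigger_designation(self, parsed):
        assert parsed[0].trigger_node == "Trigger"

    def test_druggable_is_function_of_class(self, parsed):
        net, _, _ = parsed
        expected = {
            "Trigger": False, "Prol_KC": False, "STAT3": True,
            "AMP": False, "IL10": True, "IL10R": True,
        }
        assert {d.name: d.druggable for d in net.nodes} == expected


class TestConfigParsing:
    def test_all_symbols_bound(self, parsed):
        _, cfg, _ = parsed
        assert cfg.parameters == {"k_Prol_KC_up": 0.8, "k_AMP_up": 1.2}
        assert cfg.istate == {"Trigger": 1.0}
        assert cfg.n_trajectories == 500 and cfg.seed == 3

    def test_defaults_recorded_when_unset(self):
        net = model_io.parse_logic_file(BND)
        cfg = model_io.parse_config("$k_Prol_KC_up = 1;\n$k_AMP_up = 1;\n", net)
        assert set(cfg.defaults_applied) == {"n_trajectories", "t_max", "window_dt", "seed"}

    def test_unbound_symbol_error(self):
        net = model_io.parse_logic_file(BND)
        with pytest.raises(ModelError, match=r"\$k_AMP_up"):
            model_io.parse_config("$k_Prol_KC_up = 1;\n", net)

    def test_negative_rate_rejected(self):
        net = model_io.parse_logic_file(BND)
        with pytest.raises(ModelError, match="nonnegative"):
            model_io.parse_config("$k_Prol_KC_up = -1;\n$k_AMP_up = 1;\n", net)

    def test_zero_trajectories_rejected(self):
        net = model_io.parse_logic_file(BND)
        text = CFG.replace("n_trajectories = 500;", "n_trajectories = 0;")
        with pytest.raises(ModelError, match="n_trajectories"):
            model_io.parse_config(text, net)


class TestPopulationParsing:
    def test_update_rule_parsed(self, parsed):
        net, cfg, popcfg = parsed
        assert popcfg.division_node == "Prol_KC"
        (param, ast), = popcfg.update_rules
        assert param == "k_AMP_up"
        assert expr.arith_eval(ast, {}, probs={"IL10": 0.4}) == pytest.approx(0.8)

    def test_unknown_node_in_update_rule(self):
        net = model_io.parse_logic_file(BND)
        with pytest.raises(ModelError, match="Ghost"):
            model_io.parse_population_file("$k_AMP_up u= p[Ghost];\n", net)


class TestRoundTrip:
    def _equivalent_rules(self, a, b):
        """Boolean equivalence on all assignments of the union of inputs."""
        names = sorted(set(a.inputs) | set(b.inputs))
        for bits in itertools.product((0, 1), repeat=len(names)):
            env = dict(zip(names, bits))
            if expr.bool_eval(a.logic, env) != expr.bool_eval(b.logic, env):
                return False
        return True

    def test_full_bundle_round_trip(self, parsed, tmp_path):
        net, cfg, popcfg = parsed
        model_io.write_model(net, cfg, popcfg, prefix=str(tmp_path / "m"))
        net2, cfg2, popcfg2 = model_io.read_model(
            tmp_path / "m.bnd", tmp_path / "m.cfg", tmp_path / "m.upp"
        )
        assert net2.names == net.names
        assert net2.trigger_node == net.trigger_node
        for d1, d2 in zip(net.nodes, net2.nodes):
            assert self._equivalent_rules(d1, d2)
            assert d2.node_class == d1.node_class  # annotations preserved
        assert cfg2.parameters == cfg.parameters
        assert cfg2.istate == cfg.istate
        # symbolic update formula text survives
        assert expr.arith_to_str(popcfg2.update_rules[0][1]) == expr.arith_to_str(
            popcfg.update_rules[0][1]
        )

    def test_round_trip_is_fixed_point(self, parsed):
        net, cfg, popcfg = parsed
        once = model_io.write_logic_file(net)
        twice = model_io.write_logic_file(model_io.parse_logic_file(once))
        assert once == twice

    def test_round_trip_preserves_trajectories(self, parsed, tmp_path):
        net, cfg, popcfg = parsed
        model_io.write_model(net, cfg, prefix=str(tmp_path / "m"))
        net2, cfg2, _ = model_io.read_model(tmp_path / "m.bnd", tmp_path / "m.cfg")
        tc1 = bp.ensemble_marginals(net, cfg)
        tc2 = bp.ensemble_marginals(net2, cfg2)
        assert (tc1.probs == tc2.probs).all()


class TestInfluenceGraph:
    def test_edges_and_signs(self):
        net, _ = bp.network_from_rules(
            {"Th0": ("Th0", 1, 1), "RORgamma": ("RORgamma", 1, 1),
             "Th17": ("Th0 AND RORgamma", 1, 1), "X": ("NOT Th17", 1, 1)}
        )
        g = model_io.influence_graph(net)
        signs = {(u, v): d["sign"] for u, v, d in g.edges(data=True)}
        assert signs[("Th0", "Th17")] == 1
        assert signs[("RORgamma", "Th17")] == 1
        assert signs[("Th17", "X")] == -1

    def test_edge_count_equals_distinct_regulator_pairs(self, parsed):
        net, _, _ = parsed
        g = model_io.influence_graph(net)
        expected = sum(
            len(expr.bool_regulators(d.logic)) for d in net.nodes
        )
        assert g.number_of_edges() == expected

    def test_dual_sign_regulator_yields_two_edges(self):
        net, _ = bp.network_from_rules({"A": ("A OR NOT A", 1, 1)})
        g = model_io.influence_graph(net)
        assert sorted(d["sign"] for _, _, d in g.edges(data=True)) == [-1, 1]

    def test_utility_exclusion(self, toy_model):
        net, _, _ = toy_model
        g_all = model_io.influence_graph(net, include_utility=True)
        g_dis = model_io.influence_graph(net, include_utility=False)
        assert "Division" in g_all and "Division" not in g_dis
        assert "Trigger" not in g_dis

    def test_sif_round_trip(self, parsed, tmp_path):
        net, _, _ = parsed
        g = model_io.influence_graph(net)
        model_io.write_sif(g, tmp_path / "g.sif")
        g2 = model_io.read_sif(tmp_path / "g.sif")
        assert sorted(g2.nodes) == sorted(g.nodes)
        e1 = sorted((u, v, d["sign"]) for u, v, d in g.edges(data=True))
        e2 = sorted((u, v, d["sign"]) for u, v, d in g2.edges(data=True))
        assert e1 == e2

    def test_graphml_written(self, parsed, tmp_path):
        net, _, _ = parsed
        model_io.write_graphml(model_io.influence_graph(net), tmp_path / "g.graphml")
        assert (tmp_path / "g.graphml").stat().st_size > 0


class TestAnnotations:
    def test_round_trip(self, parsed, tmp_path):
        net, _, _ = parsed
        model_io.write_annotations(net, tmp_path / "n.tsv")
        classes = model_io.read_annotations(tmp_path / "n.tsv")
        assert classes == {d.name: d.node_class for d in net.nodes}

    def test_inconsistent_druggable_flag_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text(
            "node\tnode_class\tdruggable\nIL10\tligand\tfalse\n"
        )
        with pytest.raises(ParseError, match="inconsistent"):
            model_io.read_annotations(tmp_path / "bad.tsv")
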