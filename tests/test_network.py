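"""Network representation, tabular/SBML I/O, coupling and crowding rows."""

import numpy as np
import pytest

import crowdflux as cf
from crowdflux.network import BIG, NetworkParseError, Reaction, read_sbml

# A tiny valid SBML Level 2 model: A_in -> A, conv: A <-> B, B_out: B ->
SBML_TOY = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="toy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="c"/>
   <species id="B" compartment="c"/>
   <species id="X" compartment="c" boundaryCondition="true"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="A_in" reversible="false">
    <listOfReactants><speciesReference species="X"/></listOfReactants>
    <listOfProducts><speciesReference species="A"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="0"/>
      <parameter id="UPPER_BOUND" value="5"/>
      <parameter id="FLUX_VALUE" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="conv" reversible="true">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1"/></listOfProducts>
   </reaction>
   <reaction id="B_out" reversible="false">
    <listOfReactants><speciesReference species="B"/></listOfReactants>
    <listOfProducts><speciesReference species="X"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


def toy_network():
    return cf.MetabolicNetwork([
        Reaction("A_in", {"A": 1.0}, 0.0, 5.0, False),
        Reaction("conv", {"A": -1.0, "B": 1.0}, -BIG, BIG, True),
        Reaction("B_out", {"B": -1.0}, 0.0, BIG, False),
    ])


class TestConstruction:
    def test_counts(self):
        net = toy_network()
        assert net.n_species == 2
        assert net.n_reactions == 3
        assert net.n_reversible == 1

    def test_duplicate_ids_rejected(self):
        r = Reaction("r", {"A": 1.0}, 0, 1, False)
        with pytest.raises(NetworkParseError, match="duplicate"):
            cf.MetabolicNetwork([r, r])

    def test_bad_reaction_records(self):
        with pytest.raises(NetworkParseError, match="bad coefficient"):
            Reaction("r", {"A": 0.0}, 0, 1, False)
        with pytest.raises(NetworkParseError, match="lower bound"):
            Reaction("r", {"A": 1.0}, 2, 1, False)
        with pytest.raises(NetworkParseError, match="irreversible"):
            Reaction("r", {"A": 1.0}, -1, 1, False)

    def test_unknown_role_rejected(self):
        with pytest.raises(NetworkParseError, match="unknown reaction"):
            cf.MetabolicNetwork(
                [Reaction("r", {"A": 1.0}, 0, 1, False)],
                {"atp_demand": "missing"},
            )


class TestTabularIO:
    def test_round_trip_lossless(self, tmp_path, params):
        net = cf.minimal_as_network(params, U_G=2.5, atp_min=0.5)
        path = tmp_path / "net.tsv"
        cf.write_tabular(net, path)
        back = cf.read_tabular(path)
        assert back.reaction_ids == net.reaction_ids
        assert back.named_roles == net.named_roles
        for r1, r2 in zip(net.reactions, back.reactions):
            assert r1.stoichiometry == r2.stoichiometry
            assert (r1.lb, r1.ub, r1.reversible) == (r2.lb, r2.ub, r2.reversible)

    def test_three_reaction_toy(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(
            "A_in\t0\t0.0\t5.0\t --> A\n"
            "conv\t1\t-10\t10\tA <=> B\n"
            "B_out\t0\t0\t10\tB --> \n"
        )
        net = cf.read_tabular(path)
        assert net.n_species == 2
        assert net.n_reactions == 3

    def test_flag_arrow_mismatch(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("r\t0\t-1\t1\tA <=> B\n")
        with pytest.raises(NetworkParseError, match="disagree"):
            cf.read_tabular(path)

    def test_malformed_line_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("r1\t0\t0\t1\tA + B\n")
        with pytest.raises(NetworkParseError, match="r1"):
            cf.read_tabular(path)


class TestSBML:
    def test_reads_level2_with_kinetic_law_bounds(self, tmp_path):
        path = tmp_path / "toy.xml"
        path.write_text(SBML_TOY)
        net = read_sbml(path)
        assert net.n_species == 2  # boundary species X excluded
        assert net.n_reactions == 3
        assert net.n_reversible == 1
        a_in = net.reactions[net.index_of("A_in")]
        assert (a_in.lb, a_in.ub) == (0.0, 5.0)

    def test_dispatches_on_suffix(self, tmp_path):
        path = tmp_path / "toy.xml"
        path.write_text(SBML_TOY)
        assert cf.read_network(path).n_reactions == 3


class TestMinimalFixtureNetwork:
    def test_structure(self, params):
        net = cf.minimal_as_network(params)
        assert net.n_species == 4  # glc, pyr, lac, atp
        assert net.n_reactions == 6
        assert set(net.named_roles) >= {
            "glucose_uptake", "hexokinase", "PDH", "LDH",
            "lactate_exchange", "atp_demand",
        }

    def test_lp_reproduces_closed_form(self, minimal_poly):
        net, spec, poly = minimal_poly
        w = cf.atp_objective(net)
        val, f = poly.lp_optimum(w)
        assert val == pytest.approx(19.0, rel=1e-9)
        assert cf.validate_flux(net, f, crowding=spec).ok

    def test_zero_glucose_forces_zero_flux(self, params):
        net = cf.minimal_as_network(params, U_G=0.0)
        poly = cf.rref_reduce(net, crowding=cf.default_crowding_spec(params))
        val, f = poly.lp_optimum(cf.atp_objective(net))
        assert val == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(f, 0.0, atol=1e-9)


class TestCoupling:
    def test_structure(self, two_cell_params):
        base = cf.minimal_as_network(two_cell_params, U_G=3.0)
        cn = cf.couple_cells(base, 3.0)
        assert cn.n_reactions == 12
        assert cn.shared_rows.shape == (2, 12)
        don_lac = cn.donor.reactions[cn.donor.role_index("lactate_exchange")]
        acc_lac = cn.acceptor.reactions[
            cn.acceptor.role_index("lactate_exchange")
        ]
        assert don_lac.lb == 0.0 and not don_lac.reversible
        assert acc_lac.lb < 0 and acc_lac.reversible

    def test_replicas_preserve_stoichiometry(self, two_cell_params):
        base = cf.minimal_as_network(two_cell_params, U_G=3.0)
        cn = cf.couple_cells(base, 3.0)
        S = cn.stoichiometric_matrix()
        Sd = cn.donor.stoichiometric_matrix()
        n_s, n_r = Sd.shape
        assert np.array_equal(S[:n_s, :n_r], Sd)
        assert np.all(S[:n_s, n_r:] == 0)  # block diagonal
        assert np.all(S[n_s:, :n_r] == 0)
        for rd, rb in zip(cn.donor.reactions, base.reactions):
            assert list(rd.stoichiometry.values()) == list(
                rb.stoichiometry.values()
            )

    def test_missing_role_is_config_error(self):
        net = toy_network()
        with pytest.raises(KeyError, match="glucose_uptake"):
            cf.couple_cells(net, 1.0)

    def test_symmetric_variant(self, two_cell_params):
        base = cf.minimal_as_network(two_cell_params, U_G=3.0)
        cn = cf.couple_cells(base, 3.0, symmetric=True)
        don_lac = cn.donor.reactions[cn.donor.role_index("lactate_exchange")]
        assert don_lac.reversible


class TestCrowdingRows:
    def test_two_row_absolute_value_encoding(self, params):
        net = cf.minimal_as_network(params, reversible_ldh=True)
        spec = cf.default_crowding_spec(params)
        A, b = cf.crowding_rows(net, spec)
        assert A.shape[0] == 2  # one |f| role -> two rows
        rng = np.random.default_rng(42)
        idx = {r: net.role_index(r) for r in ("hexokinase", "PDH", "LDH")}
        for _ in range(200):
            f = rng.uniform(-3, 3, net.n_reactions)
            direct = (
                params.a_glyc * f[idx["hexokinase"]]
                + params.a_ox * f[idx["PDH"]]
                + params.a_LDH * abs(f[idx["LDH"]])
            ) <= params.phi_ATP
            encoded = np.all(A @ f <= b)
            assert direct == encoded

    def test_pure_lactate_intake_bound(self, params):
        net = cf.minimal_as_network(params, reversible_ldh=True)
        spec = cf.default_crowding_spec(params)
        A, b = cf.crowding_rows(net, spec)
        f = np.zeros(net.n_reactions)
        x_max = params.phi_ATP / params.a_LDH
        f[net.role_index("LDH")] = -0.999 * x_max
        assert np.all(A @ f <= b)
        f[net.role_index("LDH")] = -1.001 * x_max
        assert not np.all(A @ f <= b)

    def test_zero_flux_slack_is_phi(self, params):
        net = cf.minimal_as_network(params)
        spec = cf.default_crowding_spec(params)
        A, b = cf.crowding_rows(net, spec)
        assert np.all(b - A @ np.zeros(net.n_reactions) == params.phi_ATP)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cf.CrowdingSpec({"LDH": -1.0}, phi=0.4)

    def test_coupled_gets_per_cell_rows(self, two_cell_params):
        base = cf.minimal_as_network(two_cell_params, U_G=3.0)
        cn = cf.couple_cells(base, 3.0)
        spec = cf.default_crowding_spec(two_cell_params)
        A, b = cf.crowding_rows(cn, spec)
        # donor keeps secretion-only LDH (1 row), acceptor reversible (2 rows)
        assert A.shape == (3, 12)


class TestValidateFlux:
    def test_zero_vector_passes(self, params):
        net = cf.minimal_as_network(params)
        assert cf.validate_flux(net, np.zeros(net.n_reactions)).ok

    def test_bound_violation_names_reaction(self, params):
        net = cf.minimal_as_network(params, U_G=1.0)
        f = np.zeros(net.n_reactions)
        f[net.role_index("glucose_uptake")] = 1.001
        rep = cf.validate_flux(net, f, tol=1e-4)
        assert not rep.ok
        assert rep.bound_violations[0][0] == "GLC_in"

    def test_balanced_vector_passes(self, params, th):
        net = cf.minimal_as_network(params, U_G=2.0)
        s = cf.single_cell_optimum(params, 2.0)
        f = np.array([s.U_G_in, s.f_glyc, s.f_ox, s.f_LDH, s.f_LDH, s.f_ATP])
        rep = cf.validate_flux(
            net, f, crowding=cf.default_crowding_spec(params)
        )
        assert rep.ok
        assert rep.max_balance_residual <= 1e-10

    def test_wrong_length_rejected(self, params):
        net = cf.minimal_as_network(params)
        with pytest.raises(ValueError, match="shape"):
            cf.validate_flux(net, np.zeros(3))
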