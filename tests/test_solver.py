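"""Flux solver: oracle equivalence, conservation, infeasibility, uniqueness."""

from fractions import Fraction as F

import pytest

from acetoflux import (
    ConditionSpec,
    GenotypeSpec,
    InfeasibilityReport,
    ProductTarget,
    UnderdeterminedSystemError,
    atp_yield,
    build_model,
    carrier_ledger,
    explain,
    solve_steady_state,
    substrate_product_ratios,
)
from acetoflux.network import exchange_reaction, _core_reactions, ModelParameters
from acetoflux.scenarios import scenario_spec
from acetoflux.solver import FluxSolution

from conftest import FEASIBLE_SCENARIOS, ORACLE_LEDGERS


@pytest.mark.parametrize("name", FEASIBLE_SCENARIOS)
def test_solver_matches_hand_ledger(name, scenario_reports):
    """Reaction-by-reaction equality with the independently derived carrier
    ledgers of each bioenergetic scheme (exact rationals)."""
    report = scenario_reports[name]
    assert report.feasible, name
    assert dict(report.solution.fluxes) == ORACLE_LEDGERS[name]


@pytest.mark.parametrize("name", FEASIBLE_SCENARIOS)
def test_internal_balances_close_exactly(name, scenario_reports):
    sol = scenario_reports[name].solution
    assert all(v == 0 for v in sol.balances.values())


@pytest.mark.parametrize("name", FEASIBLE_SCENARIOS)
def test_carbon_conservation(name, scenario_reports):
    """Carbon consumed equals carbon in products + CO2 exported, exactly."""
    sol = scenario_reports[name].solution
    species = sol.model.species_by_id
    c_in = sum(
        (v * species[s].carbon_atoms for s, v in sol.substrate_consumed.items()),
        F(0),
    )
    c_out = sum(
        (v * species[s].carbon_atoms for s, v in sol.product_formed.items()),
        F(0),
    )
    assert c_in == c_out


def test_yield_equality_formate_vs_h2co2(scenario_reports):
    """Acetogenesis from formate gives the same ATP as from H2 + CO2."""
    assert (
        scenario_reports["wt_formate"].atp_yield
        == scenario_reports["wt_h2co2"].atp_yield
        == F(10, 33)
    )


def test_solution_scales_linearly_with_target_flux():
    spec = scenario_spec("mut_co")
    model = spec.build()
    one = solve_steady_state(model, ProductTarget("acetate", F(1)))
    three = solve_steady_state(model, ProductTarget("acetate", F(3)))
    assert {k: 3 * v for k, v in one.fluxes.items()} == dict(three.fluxes)
    # per-product ledgers are invariant under scaling
    assert one.atp_yield == three.atp_yield
    assert one.substrate_consumed == three.substrate_consumed


def test_mixed_product_solution_interpolates_linearly_in_phi():
    spec = scenario_spec("resting_mixed_co")
    model = spec.build()
    acet = solve_steady_state(model, ProductTarget("acetate", F(1)))
    form = solve_steady_state(model, ProductTarget("formate", F(1)))
    for phi in (F(0), F(1, 4), F(1, 2), F(1)):
        mixed = solve_steady_state(
            model, ProductTarget("acetate", F(1), formate_fraction=phi)
        )
        for rid, v in mixed.fluxes.items():
            expected = (1 - phi) * acet.fluxes.get(rid, F(0)) + phi * form.fluxes.get(
                rid, F(0)
            )
            assert v == expected, rid


class TestInfeasibility:
    def test_mutant_on_h2_co2_lacks_h2_oxidation(self):
        spec = scenario_spec("mut_h2co2")
        result = solve_steady_state(spec.build(), spec.target)
        assert isinstance(result, InfeasibilityReport)
        assert {"fd_red", "nadh"} & set(result.unbalanceable_species)
        assert "electron carriers" in result.missing_capability

    def test_na_depletion_blocks_acetogenesis(self):
        """Without Rnf there is no NADH source for the methyl branch."""
        model = build_model(
            GenotypeSpec(),  # wild type
            ConditionSpec(substrates_available={"co"}, na_available=False),
        )
        result = solve_steady_state(model, ProductTarget("acetate", F(1)))
        assert isinstance(result, InfeasibilityReport)
        assert "nadh" in result.unbalanceable_species

    def test_removing_rnf_breaks_every_acetate_scenario(self):
        for cond in ("co", "formate", "h2_co2"):
            for geno_name in ("wild_type", "hydrogenase_free"):
                from acetoflux import condition_preset, genotype_preset
                from dataclasses import replace

                genotype = replace(genotype_preset(geno_name), rnf_present=False)
                condition = condition_preset(cond)
                if cond == "h2_co2" and geno_name == "hydrogenase_free":
                    continue  # infeasible already for a different reason
                model = build_model(genotype, condition)
                result = solve_steady_state(model, ProductTarget("acetate", F(1)))
                assert isinstance(result, InfeasibilityReport), (cond, geno_name)

    def test_irreversible_reaction_forced_backwards(self):
        """A normalization that can only be met by running an irreversible
        reaction in reverse yields a signed-flux diagnostic."""
        model = build_model(
            GenotypeSpec(), ConditionSpec(substrates_available={"co"})
        )
        from acetoflux.network import Reaction as Rxn

        rxns = (
            Rxn("sink", "pta_ack", {"formate": F(-1), "co": F(1)}),
            exchange_reaction("co", "in"),
            exchange_reaction("formate", "out"),
        )
        tiny = model.with_reactions(rxns)
        result = solve_steady_state(tiny, ProductTarget("formate", F(1)))
        assert isinstance(result, InfeasibilityReport)
        assert result.negative_fluxes == {"sink": F(-1)}
        assert "run backwards" in result.missing_capability
        assert result.unbalanceable_species  # never empty


def test_two_carbonyl_entries_create_free_direction():
    """CooS + CODH-carbonyl + direct CO entry form a futile cycle; the
    solver must refuse to pick a flux silently."""
    spec = scenario_spec("mut_co")
    model = spec.build()
    extra = _core_reactions(ModelParameters())["codh_carbonyl"]
    doubled = model.with_reactions(list(model.reactions) + [extra])
    with pytest.raises(UnderdeterminedSystemError) as err:
        solve_steady_state(doubled, spec.target)
    (direction,) = err.value.directions
    assert {"coos", "codh_carbonyl", "acs_carbonyl_co"} <= set(direction)


class TestDerivedQuantities:
    def test_atp_yield_identity(self, scenario_reports):
        for name in FEASIBLE_SCENARIOS:
            sol = scenario_reports[name].solution
            assert (
                atp_yield(sol)
                == sol.slp_net + sol.na_pumped / sol.model.parameters.na_per_atp
            )

    def test_atp_yield_rejects_infeasibility(self):
        with pytest.raises(TypeError):
            atp_yield(InfeasibilityReport(("nadh",), "x"))

    def test_ratios_normalize_to_first_product(self, scenario_reports):
        ratios = substrate_product_ratios(scenario_reports["wt_formate"].solution)
        assert ratios == {"formate": F(4), "acetate": F(1)}
        ratios = substrate_product_ratios(scenario_reports["mut_co"].solution)
        assert ratios == {"co": F(4), "acetate": F(1)}

    def test_ratios_require_product_flux(self, scenario_reports):
        from dataclasses import replace

        sol = scenario_reports["mut_co"].solution
        empty = replace(sol, product_formed={})
        with pytest.raises(ValueError, match="product flux"):
            substrate_product_ratios(empty)

    def test_carrier_ledger_wt_formate(self, scenario_reports):
        """Fd2-: +3/2 from HydABC, -1 into the carbonyl branch, -1/2 via Rnf."""
        ledger = carrier_ledger(scenario_reports["wt_formate"].solution)
        assert dict(ledger["fd_red"]) == {
            "hydabc": F(3, 2),
            "codh_carbonyl": F(-1),
            "rnf": F(-1, 2),
        }
        # entries of every carrier sum to zero
        for entries in ledger.values():
            assert sum(v for _, v in entries) == 0

    def test_carrier_ledger_mut_formate(self, scenario_reports):
        ledger = carrier_ledger(scenario_reports["mut_formate"].solution)
        assert dict(ledger["fd_red"]) == {
            "hdcr_fd": F(3),
            "codh_carbonyl": F(-1),
            "rnf": F(-2),
        }

    def test_explain_renders_both_outcomes(self, scenario_reports):
        text = explain(scenario_reports["wt_formate"].solution)
        assert "fd_red" in text and "ATP yield" in text and "0.3" in text
        text = explain(InfeasibilityReport(("nadh",), "no NADH route"))
        assert "infeasible" in text and "nadh" in text


def test_h2_escape_increases_formate_demand():
    """Losing a fraction of HDCR-produced H2 forces extra formate oxidation
    but leaves the Rnf ledger (and hence the ATP yield) unchanged."""
    spec = scenario_spec("wt_formate")
    model = build_model(
        spec.genotype,
        spec.condition,
        ModelParameters(h2_escape_fraction=F(1, 4)),
    )
    sol = solve_steady_state(model, spec.target)
    assert isinstance(sol, FluxSolution)
    assert sol.fluxes["hdcr_h2"] == F(-4)  # 3 / (1 - 1/4)
    assert sol.fluxes["ex_h2"] == F(1)
    assert sol.fluxes["rnf"] == F(1, 2)
    assert sol.substrate_consumed["formate"] == F(5)
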