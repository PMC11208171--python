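"""Named scenario registry: one entry per bioenergetic scheme.

Each scenario pairs a genotype preset with a condition preset and a product
normalization, reproducing one of the calculated electron-flow schemes
(wild type or hydrogenase-free mutant on CO, formate, H2+CO2 or fructose)
or one resting-cell condition (Na+ depletion, bicarbonate uncoupling, the
mixed acetate/formate split). Scenarios are data, not code: the registry
ships as YAML and runs end-to-end through build_model + solve_steady_state.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from ._rational import (
    format_rational,
    parse_rational,
    round_fraction_half_up,
)
from .network import (
    ConditionSpec,
    GenotypeSpec,
    ModelParameters,
    StoichiometricModel,
    _load_yaml_resource,
    build_model,
    condition_preset,
    genotype_preset,
    load_presets,
)
from .solver import (
    FluxSolution,
    InfeasibilityReport,
    ProductTarget,
    carrier_ledger,
    solution_to_dict,
    solve_steady_state,
    substrate_product_ratios,
)


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    genotype: GenotypeSpec
    condition: ConditionSpec
    target: ProductTarget
    notes: str = ""

    def build(self, parameters: ModelParameters | None = None) -> StoichiometricModel:
        return build_model(self.genotype, self.condition, parameters)


@dataclass(frozen=True)
class ScenarioReport:
    """Quantitative outcome of one scenario run."""

    name: str
    feasible: bool
    solution: FluxSolution | None
    infeasibility: InfeasibilityReport | None
    atp_yield: Fraction | None
    atp_yield_reported: float | None
    ratios: Mapping[str, Fraction] | None
    carrier_ledger: Mapping[str, list] | None
    na_pumped: Fraction | None
    notes: str = ""

    def to_dict(self) -> dict:
        d: dict = {"scenario": self.name, "feasible": self.feasible}
        if self.feasible:
            assert self.solution is not None
            d.update(solution_to_dict(self.solution))
            d["ratios"] = {
                k: {
                    "exact": format_rational(v),
                    "reported": round_fraction_half_up(v, 1),
                }
                for k, v in (self.ratios or {}).items()
            }
            d["carrier_ledger"] = {
                s: [[rid, format_rational(v)] for rid, v in entries]
                for s, entries in (self.carrier_ledger or {}).items()
            }
        else:
            assert self.infeasibility is not None
            d["unbalanceable_species"] = list(
                self.infeasibility.unbalanceable_species
            )
            d["missing_capability"] = self.infeasibility.missing_capability
        if self.notes:
            d["notes"] = self.notes
        return d


def _load_registry() -> dict:
    return _load_yaml_resource("scenarios.yaml")["scenarios"]


def list_scenarios() -> list[str]:
    """Names of all registered scenarios, in registry order."""
    return list(_load_registry())


def scenario_spec(name: str, phi: Fraction | None = None) -> ScenarioSpec:
    """Resolve a registry entry into a ScenarioSpec.

    ``phi`` overrides the registered formate fraction of a mixed-product
    scenario (it is an error to pass phi for a single-product scenario).
    """
    registry = _load_registry()
    if name not in registry:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(registry)}"
        )
    entry = registry[name]
    presets = load_presets()
    genotype = genotype_preset(entry["genotype"], presets)
    condition = condition_preset(entry["condition"], presets)
    tgt = entry["target"]
    registered_phi = (
        parse_rational(tgt["phi"]) if "phi" in tgt else None
    )
    if phi is not None and registered_phi is None:
        raise ValueError(
            f"scenario {name!r} is single-product; phi is not applicable"
        )
    target = ProductTarget(
        product_species=tgt["product"],
        flux=parse_rational(tgt.get("flux", "1")),
        formate_fraction=phi if phi is not None else registered_phi,
    )
    return ScenarioSpec(
        name=name,
        genotype=genotype,
        condition=condition,
        target=target,
        notes=" ".join(str(entry.get("notes", "")).split()),
    )


def run_scenario(
    name: str,
    phi: Fraction | None = None,
    parameters: ModelParameters | None = None,
) -> ScenarioReport:
    """Build, solve and summarize one named scenario."""
    spec = scenario_spec(name, phi=phi)
    model = spec.build(parameters)
    result = solve_steady_state(model, spec.target)
    if isinstance(result, InfeasibilityReport):
        return ScenarioReport(
            name=name,
            feasible=False,
            solution=None,
            infeasibility=result,
            atp_yield=None,
            atp_yield_reported=None,
            ratios=None,
            carrier_ledger=None,
            na_pumped=None,
            notes=spec.notes,
        )
    return ScenarioReport(
        name=name,
        feasible=True,
        solution=result,
        infeasibility=None,
        atp_yield=result.atp_yield,
        atp_yield_reported=result.atp_yield_reported,
        ratios=substrate_product_ratios(result),
        carrier_ledger=carrier_ledger(result),
        na_pumped=result.na_pumped,
        notes=spec.notes,
    )


def compare_scenarios(name_a: str, name_b: str) -> dict:
    """ATP-yield delta of scenario a relative to scenario b.

    Percent change = (yield_a - yield_b) / yield_b * 100, computed on exact
    rationals and rounded half-up to the nearest integer percent.
    """
    rep_a = run_scenario(name_a)
    rep_b = run_scenario(name_b)
    for rep in (rep_a, rep_b):
        if not rep.feasible:
            raise ValueError(
                f"scenario {rep.name!r} is infeasible; cannot compare yields"
            )
    assert rep_a.atp_yield is not None and rep_b.atp_yield is not None
    delta = rep_a.atp_yield - rep_b.atp_yield
    percent = (delta / rep_b.atp_yield) * 100
    return {
        "a": name_a,
        "b": name_b,
        "yield_a": rep_a.atp_yield,
        "yield_b": rep_b.atp_yield,
        "delta": delta,
        "percent_change": int(round_fraction_half_up(percent, 0)),
    }
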