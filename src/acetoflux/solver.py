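"""Exact steady-state flux solving over the assembled network.

The network is tiny (at most ~16 reactions), so instead of linear
programming the solver assembles the internal-species balance matrix over
exact rationals, appends the product-normalization row(s), and solves by
Gauss-Jordan elimination. The constrained system must be uniquely
determined: a residual null space is reported as an error naming the
reactions in the free direction, never silently resolved. Infeasibility is
certified by a left-null-space vector (a combination of species balances
that contradicts the requested product flux) and reported as the set of
species whose balances cannot close.

Irreversibility is checked after the unique solution is found: a negative
flux through an irreversible reaction turns the solution into an
infeasibility report carrying a signed-flux diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import sympy

from ._rational import format_rational, round_fraction_half_up
from .network import StoichiometricModel

_PRODUCT_EXCHANGES = ("ex_acetate", "ex_formate")


class UnderdeterminedSystemError(RuntimeError):
    """The constrained balance system has a residual free direction."""

    def __init__(self, directions: list[dict[str, Fraction]]):
        self.directions = directions
        names = [sorted(d) for d in directions]
        super().__init__(
            f"steady-state system is under-determined; free direction(s) "
            f"involve reactions {names}"
        )


@dataclass(frozen=True)
class ProductTarget:
    """Normalization of the flux solution.

    For a single product, ``product_species`` (acetate or formate) is fixed
    at ``flux``. When ``formate_fraction`` (phi) is given, both product
    exports stay open and the total product flux is split as
    acetate : formate = (1 - phi) : phi.
    """

    product_species: str = "acetate"
    flux: Fraction = Fraction(1)
    formate_fraction: Fraction | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "flux", Fraction(self.flux))
        if self.formate_fraction is not None:
            phi = Fraction(self.formate_fraction)
            if not (0 <= phi <= 1):
                raise ValueError("formate_fraction must lie in [0, 1]")
            object.__setattr__(self, "formate_fraction", phi)
        if self.product_species not in ("acetate", "formate"):
            raise ValueError("product_species must be 'acetate' or 'formate'")
        if self.flux <= 0:
            raise ValueError("target flux must be > 0")


@dataclass(frozen=True)
class FluxSolution:
    """Steady-state fluxes per unit product, with ledgers.

    All quantities are exact rationals; ledger quantities (na_pumped,
    slp_net, atp_yield, substrate_consumed, product ratios) are normalized
    to one unit of total product flux.
    """

    model: StoichiometricModel
    target: ProductTarget
    fluxes: Mapping[str, Fraction]
    balances: Mapping[str, Fraction]
    na_pumped: Fraction
    slp_net: Fraction
    atp_yield: Fraction
    substrate_consumed: Mapping[str, Fraction]
    product_formed: Mapping[str, Fraction]

    @property
    def feasible(self) -> bool:
        return True

    @property
    def atp_yield_reported(self) -> float:
        return round_fraction_half_up(self.atp_yield, 1)


@dataclass(frozen=True)
class InfeasibilityReport:
    """Explanation of why no steady state exists for the request."""

    unbalanceable_species: tuple[str, ...]
    missing_capability: str
    negative_fluxes: Mapping[str, Fraction] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        return False


def _to_rational(x: Fraction) -> sympy.Rational:
    return sympy.Rational(x.numerator, x.denominator)


def _to_fraction(x) -> Fraction:
    x = sympy.Rational(x)
    return Fraction(int(x.p), int(x.q))


def _active_reactions(model: StoichiometricModel, target: ProductTarget):
    """Close the product exports the target does not use.

    Substrate imports (positive exchange coefficient) always stay open;
    only the acetate/formate *export* not named by the target is removed,
    since an unconstrained second product export is a free direction.
    """
    exports = {
        r.id
        for r in model.reactions
        if r.id in _PRODUCT_EXCHANGES
        and next(iter(r.stoichiometry.values())) < 0
    }
    if target.formate_fraction is None:
        wanted = f"ex_{target.product_species}"
        if wanted not in exports:
            raise ValueError(
                f"model has no {wanted} export; cannot normalize on "
                f"{target.product_species}"
            )
        drop = exports - {wanted}
    else:
        missing = [e for e in _PRODUCT_EXCHANGES if e not in exports]
        if missing:
            raise ValueError(
                f"phi-split target needs both product exports; missing {missing}"
            )
        drop = set()
    return [r for r in model.reactions if r.id not in drop]


def solve_steady_state(
    model: StoichiometricModel, target: ProductTarget | None = None
) -> FluxSolution | InfeasibilityReport:
    """Solve for the unique flux distribution per unit product.

    Internal balances close exactly (rational arithmetic, no tolerance).
    Returns an :class:`InfeasibilityReport` when no steady state satisfies
    the normalization, naming a set of species whose balances conflict.
    Raises :class:`UnderdeterminedSystemError` if the constrained system has
    a free direction (other than the phi split, which the target fixes).
    """
    target = target or ProductTarget()
    reactions = _active_reactions(model, target)
    species = model.species_by_id
    balanced = [
        sp.id
        for sp in model.species
        if sp.role != "energy_ledger"
        and any(sp.id in r.stoichiometry for r in reactions)
    ]
    row_index = {s: i for i, s in enumerate(balanced)}
    n_rows = len(balanced)
    cols = [r.id for r in reactions]

    rows: list[list[sympy.Rational]] = [
        [sympy.Integer(0)] * len(cols) for _ in range(n_rows)
    ]
    for j, r in enumerate(reactions):
        for s, c in r.stoichiometry.items():
            if s in row_index:
                rows[row_index[s]][j] = _to_rational(c)
    b: list[sympy.Rational] = [sympy.Integer(0)] * n_rows
    norm_labels: list[str] = []

    def add_row(coeffs: dict[str, Fraction], rhs: Fraction, label: str) -> None:
        row = [sympy.Integer(0)] * len(cols)
        for rid, c in coeffs.items():
            row[cols.index(rid)] = _to_rational(c)
        rows.append(row)
        b.append(_to_rational(rhs))
        norm_labels.append(label)

    if target.formate_fraction is None:
        add_row(
            {f"ex_{target.product_species}": Fraction(1)},
            target.flux,
            f"normalization[{target.product_species}]",
        )
    else:
        phi = target.formate_fraction
        add_row(
            {"ex_acetate": Fraction(1)},
            (1 - phi) * target.flux,
            "normalization[acetate]",
        )
        add_row(
            {"ex_formate": Fraction(1)}, phi * target.flux, "normalization[formate]"
        )

    escape = model.parameters.h2_escape_fraction
    if escape > 0 and "ex_h2" in cols and "hdcr_h2" in cols:
        # escaped H2 is a fixed fraction of HDCR-produced H2 (formate
        # oxidation runs the reaction in reverse, hence the sign)
        add_row(
            {"ex_h2": Fraction(1), "hdcr_h2": escape},
            Fraction(0),
            "h2-escape coupling",
        )

    M = sympy.Matrix(rows)
    rhs = sympy.Matrix(len(b), 1, b)

    try:
        sol, params = M.gauss_jordan_solve(rhs)
    except ValueError:
        return _infeasibility_certificate(M, rhs, balanced, norm_labels)

    if params.rows * params.cols > 0:
        directions = []
        for vec in M.nullspace():
            directions.append(
                {
                    cols[i]: _to_fraction(vec[i])
                    for i in range(len(cols))
                    if vec[i] != 0
                }
            )
        raise UnderdeterminedSystemError(directions)

    fluxes = {cols[i]: _to_fraction(sol[i]) for i in range(len(cols))}

    # post-hoc irreversibility check on the unique solution
    negative = {
        r.id: fluxes[r.id]
        for r in reactions
        if not r.reversible and fluxes[r.id] < 0
    }
    if negative:
        involved = sorted(
            {
                s
                for r in reactions
                if r.id in negative
                for s in r.stoichiometry
                if species[s].role not in ("ion_ledger", "energy_ledger")
            }
        )
        detail = ", ".join(
            f"{rid}={format_rational(v)}" for rid, v in sorted(negative.items())
        )
        return InfeasibilityReport(
            unbalanceable_species=tuple(involved),
            missing_capability=(
                "the unique steady state requires irreversible reaction(s) to "
                f"run backwards ({detail})"
            ),
            negative_fluxes=negative,
        )

    return _build_solution(model, target, reactions, fluxes, balanced)


def _build_solution(model, target, reactions, fluxes, balanced) -> FluxSolution:
    total = target.flux
    balances: dict[str, Fraction] = {}
    for s in balanced:
        acc = Fraction(0)
        for r in reactions:
            c = r.stoichiometry.get(s)
            if c is not None:
                acc += c * fluxes[r.id]
        balances[s] = acc
    assert all(v == 0 for v in balances.values()), "internal balance residual"

    na_pumped = sum(
        (
            r.na_translocated_per_unit_flux * fluxes[r.id]
            for r in reactions
            if r.na_translocated_per_unit_flux > 0
        ),
        Fraction(0),
    )
    slp_net = sum(
        (
            r.stoichiometry.get("atp", Fraction(0)) * fluxes[r.id]
            for r in reactions
            if r.enzyme_tag != "atp_synthase"
        ),
        Fraction(0),
    )
    atp_yield = (slp_net + na_pumped / model.parameters.na_per_atp) / total

    consumed: dict[str, Fraction] = {}
    formed: dict[str, Fraction] = {}
    for r in reactions:
        if not r.is_exchange:
            continue
        ((sid, coeff),) = r.stoichiometry.items()
        # exchange adds coeff*flux of sid to the internal pool: a positive
        # net is uptake from the environment, a negative net is export
        net = coeff * fluxes[r.id]
        if net > 0:
            consumed[sid] = net / total
        elif net < 0:
            formed[sid] = -net / total
    return FluxSolution(
        model=model,
        target=target,
        fluxes=fluxes,
        balances=balances,
        na_pumped=na_pumped / total,
        slp_net=slp_net / total,
        atp_yield=atp_yield,
        substrate_consumed=consumed,
        product_formed=formed,
    )


def _infeasibility_certificate(M, rhs, balanced, norm_labels) -> InfeasibilityReport:
    """Name species whose balances conflict with the normalization.

    Any left-null-space vector y of the system matrix with y.b != 0 proves
    inconsistency; the species rows in its support are a set of balances
    that cannot simultaneously close. The basis vector with the smallest
    support is chosen (a heuristic for minimality; the certificate is exact
    either way).
    """
    best: list[int] | None = None
    for y in M.T.nullspace():
        if (y.T * rhs)[0, 0] == 0:
            continue
        support = [i for i in range(M.rows) if y[i] != 0]
        if best is None or len(support) < len(best):
            best = support
    if best is None:  # pragma: no cover - gauss_jordan_solve said inconsistent
        best = list(range(M.rows))
    labels = balanced + norm_labels
    species_support = tuple(labels[i] for i in best if i < len(balanced))
    norm_support = [labels[i] for i in best if i >= len(balanced)]
    if not species_support:
        # conflict purely among normalization rows (e.g. product exchange
        # closed); fall back to the normalized product species
        species_support = tuple(
            lbl.split("[", 1)[1].rstrip("]") for lbl in norm_support
        )
    return InfeasibilityReport(
        unbalanceable_species=species_support,
        missing_capability=_describe_missing(species_support),
    )


def _describe_missing(species_ids: tuple[str, ...]) -> str:
    s = set(species_ids)
    hints = []
    if {"fd_red", "nadh"} & s:
        hints.append(
            "no route to regenerate the soluble electron carriers "
            "(reduced ferredoxin / NADH) at the required rate"
        )
    if "h2" in s:
        hints.append("no H2-oxidizing reaction is present")
    if not hints:
        hints.append("the listed species balances cannot close")
    return "; ".join(hints) + f" [species: {', '.join(species_ids)}]"


# ---------------------------------------------------------------------------
# derived quantities


def atp_yield(solution: FluxSolution) -> Fraction:
    """Net ATP per unit product: substrate-level net + chemiosmotic share."""
    if not isinstance(solution, FluxSolution):
        raise TypeError("atp_yield requires a feasible FluxSolution")
    return solution.atp_yield


def substrate_product_ratios(solution: FluxSolution) -> dict[str, Fraction]:
    """Consumption/formation ratios normalized to the first product.

    Acetate is the reference product when formed, otherwise formate. The
    returned map contains every consumed substrate and every formed product
    (reference product = 1). Exact rationals; round at the reporting
    boundary with :func:`acetoflux._rational.round_fraction_half_up`.
    """
    if not isinstance(solution, FluxSolution):
        raise TypeError("ratios require a feasible FluxSolution")
    products = {
        s: v
        for s, v in solution.product_formed.items()
        if s in ("acetate", "formate") and v > 0
    }
    if not products:
        raise ValueError("no acetate/formate product flux to normalize on")
    reference = "acetate" if products.get("acetate") else "formate"
    ref = products[reference]
    ratios: dict[str, Fraction] = {}
    for s, v in solution.substrate_consumed.items():
        ratios[s] = v / ref
    for s, v in products.items():
        ratios[s] = v / ref
    return ratios


def carrier_ledger(
    solution: FluxSolution,
) -> dict[str, list[tuple[str, Fraction]]]:
    """Per-carrier production/consumption contributions, per unit product.

    Maps each soluble carrier / THF intermediate (and internal H2) to the
    list of (reaction id, contribution) pairs with nonzero contribution, in
    model reaction order. Contributions of each species sum to zero.
    """
    if not isinstance(solution, FluxSolution):
        raise TypeError("ledger requires a feasible FluxSolution")
    species = solution.model.species_by_id
    total = solution.target.flux
    ledger: dict[str, list[tuple[str, Fraction]]] = {}
    for sid, sp in species.items():
        if sp.role not in ("internal_carrier", "thf_intermediate"):
            # H2 is ledger-worthy when cycled internally (no exchange)
            if not (sid == "h2" and f"ex_{sid}" not in solution.fluxes):
                continue
        entries = []
        for r in solution.model.reactions:
            if r.id not in solution.fluxes:
                continue
            c = r.stoichiometry.get(sid)
            if c is None:
                continue
            contribution = c * solution.fluxes[r.id] / total
            if contribution != 0:
                entries.append((r.id, contribution))
        if entries:
            ledger[sid] = entries
    return ledger


def explain(solution: FluxSolution | InfeasibilityReport) -> str:
    """Render a human-readable ledger of the solution.

    For a feasible solution: a per-carrier production/consumption table plus
    the Na+/ATP summary. For an infeasibility report: the diagnosis.
    """
    if isinstance(solution, InfeasibilityReport):
        lines = ["infeasible:"]
        lines.append(f"  unbalanceable species: {', '.join(solution.unbalanceable_species)}")
        lines.append(f"  {solution.missing_capability}")
        return "\n".join(lines)
    lines = []
    ledger = carrier_ledger(solution)
    for sid, entries in ledger.items():
        parts = " ".join(
            f"{'+' if v > 0 else ''}{format_rational(v)} ({rid})"
            for rid, v in entries
        )
        lines.append(f"{sid}: {parts}")
    lines.append(f"Na+ pumped per product: {format_rational(solution.na_pumped)}")
    lines.append(f"SLP net ATP per product: {format_rational(solution.slp_net)}")
    lines.append(
        f"ATP yield per product: {format_rational(solution.atp_yield)} "
        f"(reported {solution.atp_yield_reported})"
    )
    return "\n".join(lines)


def solution_to_dict(solution: FluxSolution) -> dict:
    """JSON-ready rendering with rationals as "p/q" plus decimal reports."""
    return {
        "fluxes": {k: format_rational(v) for k, v in solution.fluxes.items()},
        "na_pumped": format_rational(solution.na_pumped),
        "slp_net": format_rational(solution.slp_net),
        "atp_yield": format_rational(solution.atp_yield),
        "atp_yield_reported": solution.atp_yield_reported,
        "substrate_consumed": {
            k: format_rational(v) for k, v in solution.substrate_consumed.items()
        },
        "product_formed": {
            k: format_rational(v) for k, v in solution.product_formed.items()
        },
    }
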