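"""Reaction network of acetogenic electron flow in *Acetobacterium woodii*.

The model is a small, exactly balanced stoichiometric network covering the
Wood-Ljungdahl pathway (methyl and carbonyl branches), the two [FeFe]
hydrogenases (electron-bifurcating HydABC and the HydA2 module of the
hydrogen-dependent CO2 reductase, HDCR), the monofunctional CO dehydrogenase
CooS, the Na+-translocating Rnf complex and the Na+-driven ATP synthase.
Genotype flags (which hydrogenase/FDH modules are present) and condition
flags (available substrates, Na+, ATP coupling) select the subset of
reactions that exists in a given scenario; disabled reactions are absent
from the assembled model, not merely bounded to zero.

Electron bookkeeping uses degrees of reduction relative to the fully
oxidized reference states (CO2, NAD+, oxidized ferredoxin, THF = 0; each
2-electron reduction adds 2). Carbon and electrons must balance exactly, in
rational arithmetic, for every non-exchange reaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

import yaml

from ._rational import format_rational, parse_rational

SCHEMA_VERSION = 1

#: species ids usable as growth substrates in a ConditionSpec
SUBSTRATE_IDS = frozenset({"co", "h2", "co2", "formate", "fructose"})

#: species that may leave the system as products
PRODUCT_IDS = ("acetate", "formate", "co2", "h2")


class ModelValidationError(ValueError):
    """A genotype/condition/model combination violates its invariants."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Species:
    id: str
    role: str  # external_substrate | external_product | internal_carrier |
    #            thf_intermediate | ion_ledger | energy_ledger
    carbon_atoms: int = 0
    degree_of_reduction: int = 0

    def __post_init__(self) -> None:
        if self.carbon_atoms < 0:
            raise ModelValidationError(f"{self.id}: carbon_atoms must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """One reaction with exact rational stoichiometry.

    ``stoichiometry`` maps species id -> coefficient (negative = consumed).
    ``na_translocated_per_unit_flux`` is positive when Na+ is pumped out of
    the cell (Rnf) and negative when the gradient is consumed (ATP synthase).
    """

    id: str
    enzyme_tag: str
    stoichiometry: Mapping[str, Fraction]
    na_translocated_per_unit_flux: Fraction = Fraction(0)
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "stoichiometry",
            {s: Fraction(c) for s, c in self.stoichiometry.items()},
        )

    @property
    def is_exchange(self) -> bool:
        return self.enzyme_tag == "exchange"

    def carbon_balance(self, species: Mapping[str, Species]) -> Fraction:
        return sum(
            (c * species[s].carbon_atoms for s, c in self.stoichiometry.items()),
            Fraction(0),
        )

    def electron_balance(self, species: Mapping[str, Species]) -> Fraction:
        return sum(
            (c * species[s].degree_of_reduction for s, c in self.stoichiometry.items()),
            Fraction(0),
        )


@dataclass(frozen=True)
class ModelParameters:
    """Chemiosmotic coupling parameters.

    na_per_atp: Na+ consumed by the ATP synthase per ATP (default 33/10,
        i.e. a c-ring driven stoichiometry of 3.3 Na+/ATP).
    na_per_fd2_rnf: Na+ pumped by Rnf per reduced ferredoxin oxidized
        (default 2; one Na+ per electron).
    h2_escape_fraction: fraction of HDCR-produced H2 lost to the headspace
        instead of being recaptured by HydABC (default 0: closed ledger).
    """

    na_per_atp: Fraction = Fraction(33, 10)
    na_per_fd2_rnf: Fraction = Fraction(2)
    h2_escape_fraction: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "na_per_atp", parse_rational(self.na_per_atp))
        object.__setattr__(self, "na_per_fd2_rnf", parse_rational(self.na_per_fd2_rnf))
        object.__setattr__(
            self, "h2_escape_fraction", parse_rational(self.h2_escape_fraction)
        )
        if self.na_per_atp <= 0:
            raise ModelValidationError("na_per_atp must be > 0")
        if self.na_per_fd2_rnf < 0:
            raise ModelValidationError("na_per_fd2_rnf must be >= 0")
        if not (0 <= self.h2_escape_fraction <= 1):
            raise ModelValidationError("h2_escape_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GenotypeSpec:
    hydABC_present: bool = True
    hdcr_hydrogenase_module_present: bool = True
    hdcr_fdh_module_present: bool = True
    fd_hdcr_enabled: bool = False
    cooS_present: bool = True
    rnf_present: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.fd_hdcr_enabled and not self.hdcr_fdh_module_present:
            raise ModelValidationError(
                "fd_hdcr_enabled requires hdcr_fdh_module_present "
                "(ferredoxin-mode HDCR needs the FDH module)"
            )


@dataclass(frozen=True)
class ConditionSpec:
    substrates_available: frozenset[str] = frozenset()
    na_available: bool = True
    atp_coupling_available: bool = True
    co2_available_as_acceptor: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "substrates_available",
            frozenset(s.lower() for s in self.substrates_available),
        )
        unknown = self.substrates_available - SUBSTRATE_IDS
        if unknown:
            raise ModelValidationError(
                f"unknown substrates {sorted(unknown)}; "
                f"allowed: {sorted(SUBSTRATE_IDS)}"
            )
        if not self.substrates_available:
            raise ModelValidationError(
                "substrates_available must be non-empty for a solvable scenario"
            )


@dataclass(frozen=True)
class StoichiometricModel:
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    parameters: ModelParameters
    genotype: GenotypeSpec
    condition: ConditionSpec

    @property
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def with_reactions(self, reactions: Iterable[Reaction]) -> "StoichiometricModel":
        return replace(self, reactions=tuple(reactions))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "species": [
                {
                    "id": s.id,
                    "role": s.role,
                    "carbon_atoms": s.carbon_atoms,
                    "degree_of_reduction": s.degree_of_reduction,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "enzyme_tag": r.enzyme_tag,
                    "stoichiometry": {
                        s: format_rational(c) for s, c in r.stoichiometry.items()
                    },
                    "na_translocated_per_unit_flux": format_rational(
                        r.na_translocated_per_unit_flux
                    ),
                    "reversible": r.reversible,
                }
                for r in self.reactions
            ],
            "parameters": {
                "na_per_atp": format_rational(self.parameters.na_per_atp),
                "na_per_fd2_rnf": format_rational(self.parameters.na_per_fd2_rnf),
                "h2_escape_fraction": format_rational(
                    self.parameters.h2_escape_fraction
                ),
            },
            "genotype": {
                "hydABC_present": self.genotype.hydABC_present,
                "hdcr_hydrogenase_module_present": self.genotype.hdcr_hydrogenase_module_present,
                "hdcr_fdh_module_present": self.genotype.hdcr_fdh_module_present,
                "fd_hdcr_enabled": self.genotype.fd_hdcr_enabled,
                "cooS_present": self.genotype.cooS_present,
                "rnf_present": self.genotype.rnf_present,
                "label": self.genotype.label,
            },
            "condition": {
                "substrates_available": sorted(self.condition.substrates_available),
                "na_available": self.condition.na_available,
                "atp_coupling_available": self.condition.atp_coupling_available,
                "co2_available_as_acceptor": self.condition.co2_available_as_acceptor,
            },
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StoichiometricModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ModelValidationError(
                f"unsupported schema_version {d.get('schema_version')!r}"
            )
        species = tuple(
            Species(
                id=s["id"],
                role=s["role"],
                carbon_atoms=int(s["carbon_atoms"]),
                degree_of_reduction=int(s["degree_of_reduction"]),
            )
            for s in d["species"]
        )
        reactions = tuple(
            Reaction(
                id=r["id"],
                enzyme_tag=r["enzyme_tag"],
                stoichiometry={
                    s: parse_rational(c) for s, c in r["stoichiometry"].items()
                },
                na_translocated_per_unit_flux=parse_rational(
                    r["na_translocated_per_unit_flux"]
                ),
                reversible=bool(r["reversible"]),
            )
            for r in d["reactions"]
        )
        params = ModelParameters(
            na_per_atp=parse_rational(d["parameters"]["na_per_atp"]),
            na_per_fd2_rnf=parse_rational(d["parameters"]["na_per_fd2_rnf"]),
            h2_escape_fraction=parse_rational(d["parameters"]["h2_escape_fraction"]),
        )
        genotype = GenotypeSpec(**d["genotype"])
        condition = ConditionSpec(
            substrates_available=frozenset(d["condition"]["substrates_available"]),
            na_available=d["condition"]["na_available"],
            atp_coupling_available=d["condition"]["atp_coupling_available"],
            co2_available_as_acceptor=d["condition"]["co2_available_as_acceptor"],
        )
        return cls(species, reactions, params, genotype, condition)

    @classmethod
    def from_json(cls, text: str) -> "StoichiometricModel":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# canonical species and reactions

_SPECIES_TABLE: tuple[Species, ...] = (
    Species("co2", "external_substrate", 1, 0),
    Species("co", "external_substrate", 1, 2),
    Species("formate", "external_substrate", 1, 2),
    Species("h2", "external_substrate", 0, 2),
    Species("fructose", "external_substrate", 6, 24),
    Species("acetate", "external_product", 2, 8),
    Species("fd_red", "internal_carrier", 0, 2),  # reduced ferredoxin, 2 e-
    Species("nadh", "internal_carrier", 0, 2),
    Species("formyl_thf", "thf_intermediate", 1, 2),
    Species("methylene_thf", "thf_intermediate", 1, 4),
    Species("methyl_thf", "thf_intermediate", 1, 6),
    Species("co_bound", "internal_carrier", 1, 2),  # enzyme-bound [CO]
    Species("acetyl_coa", "internal_carrier", 2, 8),
    Species("na_out", "ion_ledger", 0, 0),  # Na+ translocated across the membrane
    Species("atp", "energy_ledger", 0, 0),
)

SPECIES: dict[str, Species] = {s.id: s for s in _SPECIES_TABLE}


def _core_reactions(p: ModelParameters) -> dict[str, Reaction]:
    F = Fraction
    return {
        "coos": Reaction(
            "coos", "cooS", {"co": F(-1), "co2": F(1), "fd_red": F(1)}
        ),
        "codh_carbonyl": Reaction(
            "codh_carbonyl",
            "codh_acs_carbonyl_from_co2",
            {"co2": F(-1), "fd_red": F(-1), "co_bound": F(1)},
        ),
        "acs_carbonyl_co": Reaction(
            "acs_carbonyl_co",
            "acs_carbonyl_direct_co",
            {"co": F(-1), "co_bound": F(1)},
        ),
        # one unit = oxidation of 2 H2, bifurcating 4 e- onto Fd and NAD+
        "hydabc": Reaction(
            "hydabc",
            "hydABC",
            {"h2": F(-2), "fd_red": F(1), "nadh": F(1)},
            reversible=True,
        ),
        "hdcr_h2": Reaction(
            "hdcr_h2",
            "hdcr_h2",
            {"h2": F(-1), "co2": F(-1), "formate": F(1)},
            reversible=True,
        ),
        "hdcr_fd": Reaction(
            "hdcr_fd",
            "hdcr_fd",
            {"fd_red": F(-1), "co2": F(-1), "formate": F(1)},
            reversible=True,
        ),
        "fhs": Reaction(
            "fhs",
            "fhs",
            {"formate": F(-1), "atp": F(-1), "formyl_thf": F(1)},
        ),
        # formyl-THF -> methylene-THF, lumped with the cyclohydrolase
        "mtd": Reaction(
            "mtd",
            "mtd_lumped",
            {"formyl_thf": F(-1), "nadh": F(-1), "methylene_thf": F(1)},
        ),
        "mtr": Reaction(
            "mtr",
            "mtr",
            {"methylene_thf": F(-1), "nadh": F(-1), "methyl_thf": F(1)},
        ),
        "acs": Reaction(
            "acs",
            "acs_condensation",
            {"methyl_thf": F(-1), "co_bound": F(-1), "acetyl_coa": F(1)},
        ),
        "pta_ack": Reaction(
            "pta_ack",
            "pta_ack",
            {"acetyl_coa": F(-1), "acetate": F(1), "atp": F(1)},
        ),
        "rnf": Reaction(
            "rnf",
            "rnf",
            {"fd_red": F(-1), "nadh": F(1), "na_out": p.na_per_fd2_rnf},
            na_translocated_per_unit_flux=p.na_per_fd2_rnf,
        ),
        "atp_synthase": Reaction(
            "atp_synthase",
            "atp_synthase",
            {"na_out": -p.na_per_atp, "atp": F(1)},
            na_translocated_per_unit_flux=-p.na_per_atp,
        ),
        # glycolysis + PFOR + Pta/Ack, lumped
        "fructose_cat": Reaction(
            "fructose_cat",
            "fructose_catabolism_lumped",
            {
                "fructose": F(-1),
                "acetate": F(2),
                "co2": F(2),
                "nadh": F(2),
                "fd_red": F(2),
                "atp": F(4),
            },
        ),
    }


def exchange_reaction(species_id: str, direction: str, reversible: bool = False) -> Reaction:
    """Build an exchange (boundary) reaction.

    direction "in": positive flux = uptake; "out": positive flux = export.
    A reversible exchange uses the export sign convention (negative = uptake).
    """
    coeff = Fraction(1) if direction == "in" else Fraction(-1)
    return Reaction(
        f"ex_{species_id}",
        "exchange",
        {species_id: coeff},
        reversible=reversible,
    )


# ---------------------------------------------------------------------------
# assembly


def build_model(
    genotype: GenotypeSpec,
    condition: ConditionSpec,
    parameters: ModelParameters | None = None,
) -> StoichiometricModel:
    """Assemble the network active under a genotype x condition.

    Reactions disabled by the genotype (e.g. HydABC in the hydrogenase-free
    mutant) or by the condition (e.g. Rnf and the ATP synthase under Na+
    depletion, formyl-THF synthetase under bicarbonate uncoupling) are left
    out of the model entirely.
    """
    parameters = parameters or ModelParameters()
    core = _core_reactions(parameters)
    subs = condition.substrates_available
    co_available = "co" in subs

    if "h2" in subs and parameters.h2_escape_fraction > 0:
        raise ModelValidationError(
            "h2_escape_fraction > 0 is only meaningful when H2 is not a substrate"
        )

    reactions: list[Reaction] = []
    if "fructose" in subs:
        reactions.append(core["fructose_cat"])
    if genotype.cooS_present and co_available:
        reactions.append(core["coos"])
    # carbonyl-branch entry: direct from CO when CO is present, otherwise the
    # CODH of the CODH/ACS complex reduces CO2; never both (their combination
    # with CooS would be a futile cycle with no observable consequence)
    if co_available:
        reactions.append(core["acs_carbonyl_co"])
    else:
        reactions.append(core["codh_carbonyl"])
    if genotype.hydABC_present:
        reactions.append(core["hydabc"])
    if genotype.hdcr_hydrogenase_module_present and genotype.hdcr_fdh_module_present:
        reactions.append(core["hdcr_h2"])
    if genotype.fd_hdcr_enabled:
        reactions.append(core["hdcr_fd"])
    if condition.atp_coupling_available:
        reactions.append(core["fhs"])
    reactions += [core["mtd"], core["mtr"], core["acs"], core["pta_ack"]]
    if genotype.rnf_present and condition.na_available:
        reactions.append(core["rnf"])
    if condition.na_available:
        reactions.append(core["atp_synthase"])

    # exchanges: substrates import; acetate/formate export; CO2 reversible
    # when it may serve as external acceptor, else export-only
    for s in sorted(subs - {"co2"}):
        reactions.append(exchange_reaction(s, "in"))
    if "co2" in subs or condition.co2_available_as_acceptor:
        reactions.append(exchange_reaction("co2", "out", reversible=True))
    else:
        reactions.append(exchange_reaction("co2", "out"))
    reactions.append(exchange_reaction("acetate", "out"))
    if "formate" not in subs:
        reactions.append(exchange_reaction("formate", "out"))
    if "h2" not in subs and parameters.h2_escape_fraction > 0:
        reactions.append(exchange_reaction("h2", "out"))

    used = {s for r in reactions for s in r.stoichiometry}
    species = tuple(sp for sp in _SPECIES_TABLE if sp.id in used)
    return StoichiometricModel(
        species=species,
        reactions=tuple(reactions),
        parameters=parameters,
        genotype=genotype,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# validation


def validate_model(
    model: StoichiometricModel, check_connectivity: bool = True
) -> list[str]:
    """Return one diagnostic string per violated balance/convention.

    An empty list means every non-exchange reaction is carbon- and
    electron-balanced and the Na+ ledger follows the assumed coupling
    stoichiometries (Rnf pumps na_per_fd2_rnf per Fd2- oxidized; the ATP
    synthase consumes na_per_atp per ATP; no other reaction moves Na+).

    With ``check_connectivity`` (default) the list additionally flags soluble
    carriers or THF intermediates that occur in fewer than two reactions:
    such species can only ever carry zero flux. Deliberately truncated
    models (e.g. bicarbonate-uncoupled cells lacking the formyl-THF
    synthetase) trigger these flags by construction; pass
    ``check_connectivity=False`` to restrict validation to balances.
    """
    diagnostics: list[str] = []
    species = model.species_by_id
    seen_ids: set[str] = set()
    for sp in model.species:
        if sp.id in seen_ids:
            diagnostics.append(f"species {sp.id!r} duplicated")
        seen_ids.add(sp.id)

    p = model.parameters
    for r in model.reactions:
        unknown = set(r.stoichiometry) - set(species)
        if unknown:
            diagnostics.append(
                f"reaction {r.id!r}: unknown species {sorted(unknown)}"
            )
            continue
        if not r.is_exchange:
            cb = r.carbon_balance(species)
            if cb != 0:
                diagnostics.append(
                    f"reaction {r.id!r}: carbon imbalance of "
                    f"{format_rational(cb)} atoms per unit flux"
                )
            eb = r.electron_balance(species)
            if eb != 0:
                diagnostics.append(
                    f"reaction {r.id!r}: electron imbalance of "
                    f"{format_rational(eb)} e- per unit flux"
                )
        if r.enzyme_tag == "rnf":
            if r.na_translocated_per_unit_flux != p.na_per_fd2_rnf:
                diagnostics.append(
                    f"reaction {r.id!r}: na_translocated "
                    f"{format_rational(r.na_translocated_per_unit_flux)} violates "
                    f"the {format_rational(p.na_per_fd2_rnf)} Na+ per Fd2- "
                    "(2 Na+/2 e-) convention"
                )
        elif r.enzyme_tag == "atp_synthase":
            if r.na_translocated_per_unit_flux != -p.na_per_atp:
                diagnostics.append(
                    f"reaction {r.id!r}: na_translocated "
                    f"{format_rational(r.na_translocated_per_unit_flux)} violates "
                    f"the {format_rational(p.na_per_atp)} Na+ per ATP convention"
                )
        elif r.na_translocated_per_unit_flux != 0:
            diagnostics.append(
                f"reaction {r.id!r}: only rnf and atp_synthase may translocate Na+"
            )

    if not check_connectivity:
        return diagnostics

    # soluble carriers and THF intermediates must be regenerable in principle
    counts: dict[str, int] = {}
    for r in model.reactions:
        for s in r.stoichiometry:
            counts[s] = counts.get(s, 0) + 1
    for sp in model.species:
        if sp.role in ("internal_carrier", "thf_intermediate"):
            if counts.get(sp.id, 0) < 2:
                diagnostics.append(
                    f"species {sp.id!r} ({sp.role}) appears in fewer than two "
                    "reactions and cannot be balanced"
                )
    return diagnostics


# ---------------------------------------------------------------------------
# presets


def _load_yaml_resource(name: str) -> dict:
    with resources.files("acetoflux.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def load_presets() -> dict:
    """Load the genotype/condition presets shipped with the package."""
    return _load_yaml_resource("presets.yaml")


def genotype_preset(name: str, presets: dict | None = None) -> GenotypeSpec:
    presets = presets or load_presets()
    try:
        entry = presets["genotypes"][name]
    except KeyError:
        raise KeyError(
            f"unknown genotype preset {name!r}; "
            f"available: {sorted(load_presets()['genotypes'])}"
        ) from None
    return GenotypeSpec(**entry)


def condition_preset(name: str, presets: dict | None = None) -> ConditionSpec:
    presets = presets or load_presets()
    try:
        entry = dict(presets["conditions"][name])
    except KeyError:
        raise KeyError(
            f"unknown condition preset {name!r}; "
            f"available: {sorted(load_presets()['conditions'])}"
        ) from None
    entry["substrates_available"] = frozenset(entry["substrates_available"])
    return ConditionSpec(**entry)
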