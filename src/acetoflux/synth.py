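"""Seeded synthetic data emulating the package's experimental inputs.

Three generators: logistic-with-lag growth curves (OD600), metabolite
conversion time courses whose endpoint stoichiometry is taken from a flux
solution, and SNP population-frequency tables with one sweeping locus.
Noise is multiplicative lognormal (concentrations and ODs are positive
quantities) with a configurable coefficient of variation; every generator
takes an explicit integer seed and is bit-for-bit reproducible.

These emulate the *shapes* of batch growth and resting-cell conversions
(lag, exponential phase, saturation; linear substrate consumption at a
fixed specific rate until exhaustion). They deliberately do not model CO
toxicity, the six-month adaptation lag, gas-liquid transfer or replicate
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .solver import FluxSolution
from .timecourse import SNPRecord, TimeCourse

DEFAULT_NOISE_CV = 0.05


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a logistic batch growth curve with lag.

    mu: maximum specific growth rate (1/h); lag: time shift (h) before
    growth starts; od0: inoculum OD600; od_max: carrying capacity OD600;
    noise_cv: fractional multiplicative noise per sample; times: sampling
    grid in hours (defaults to 0-168 h every 3 h, the cadence of a
    week-long batch culture).
    """

    mu: float = 0.05
    lag: float = 0.0
    od0: float = 0.05
    od_max: float = 1.0
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 168.0 + 1e-9, 3.0)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.od0 <= 0:
            raise ValueError("od0 must be > 0")
        if self.od_max < self.od0:
            raise ValueError("od_max must be >= od0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_growth(p: GrowthParams) -> TimeCourse:
    """Logistic OD600 curve delayed by the lag, with seeded noise.

    OD(t) = od_max * od0 / (od0 + (od_max - od0) * exp(-mu (t - lag))) for
    t >= lag, od0 before. With noise_cv = 0 the curve is deterministic; the
    early exponential phase has specific rate mu * (1 - od0/od_max), which
    approaches mu for od_max >> od0.
    """
    t = p.times
    shifted = np.maximum(t - p.lag, 0.0)
    denom = p.od0 + (p.od_max - p.od0) * np.exp(-p.mu * shifted)
    od = p.od_max * p.od0 / denom
    rng = np.random.default_rng(p.seed)
    od = od * _lognormal_factors(rng, p.noise_cv, len(t))
    return TimeCourse(times=t, values=od, label="OD600", unit="OD600")


# ---------------------------------------------------------------------------
# conversion time courses


@dataclass(frozen=True)
class ConversionParams:
    """Parameters of a resting-cell substrate conversion.

    solution: feasible flux solution fixing the product:substrate
    stoichiometry; substrate: id of the consumed substrate (defaults to the
    solution's largest consumption term); substrate0: initial concentration
    (mM); rate: specific substrate consumption rate (nmol min^-1 mg^-1);
    protein_conc: mg/mL of the suspension; times: sampling grid (h).
    """

    solution: FluxSolution
    substrate0: float = 250.0
    rate: float = 800.0
    protein_conc: float = 1.0
    substrate: str | None = None
    noise_cv: float = DEFAULT_NOISE_CV
    seed: int = 0
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 24.0 + 1e-9, 1.0)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if not isinstance(self.solution, FluxSolution):
            raise ValueError(
                "simulate_conversion requires a feasible FluxSolution"
            )
        if self.substrate0 <= 0:
            raise ValueError("substrate0 must be > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be > 0")
        sub = self.substrate
        if sub is None:
            if not self.solution.substrate_consumed:
                raise ValueError("solution consumes no substrate")
            sub = max(
                self.solution.substrate_consumed,
                key=lambda s: self.solution.substrate_consumed[s],
            )
            object.__setattr__(self, "substrate", sub)
        if sub not in self.solution.substrate_consumed:
            raise ValueError(
                f"{sub!r} is not consumed by the solution "
                f"(consumed: {sorted(self.solution.substrate_consumed)})"
            )


def simulate_conversion(p: ConversionParams) -> dict[str, TimeCourse]:
    """Substrate decline and product rise at fixed stoichiometric coupling.

    The substrate falls linearly at the configured specific rate until
    exhaustion; each product (acetate and/or formate) rises with slope =
    substrate slope x (product : substrate ratio of the flux solution), so
    noiseless endpoint ratios equal the solution's ratios exactly. Returns
    a map series-label -> TimeCourse (substrate plus each liquid product).
    """
    assert p.substrate is not None
    # nmol min^-1 mg^-1 * mg/mL -> nmol mL^-1 min^-1 = uM/min; x60/1000 -> mM/h
    decline_mm_h = p.rate * p.protein_conc * 60.0 / 1000.0
    t = p.times
    substrate_mm = np.maximum(p.substrate0 - decline_mm_h * t, 0.0)
    consumed_mm = p.substrate0 - substrate_mm

    per_substrate = p.solution.substrate_consumed[p.substrate]
    series: dict[str, np.ndarray] = {p.substrate: substrate_mm}
    # every exported product is emitted, including gases (CO2, H2), so the
    # noiseless trajectories conserve carbon point by point; analyses of
    # liquid-phase measurements can simply ignore the gas series
    for product, formed in p.solution.product_formed.items():
        ratio = float(Fraction(formed) / Fraction(per_substrate))
        series[product] = consumed_mm * ratio

    rng = np.random.default_rng(p.seed)
    out: dict[str, TimeCourse] = {}
    for label, values in series.items():
        noisy = values * _lognormal_factors(rng, p.noise_cv, len(t))
        out[label] = TimeCourse(
            times=t,
            values=noisy,
            label=label,
            unit="mM",
            protein_conc=p.protein_conc,
        )
    return out


# ---------------------------------------------------------------------------
# SNP tables


def simulate_snp_table(
    loci: int,
    sweep_locus: int = 0,
    timepoints: tuple[str, ...] = (
        "before adaptation",
        "after adaptation",
        "10th transfer",
    ),
    seed: int = 0,
) -> list[SNPRecord]:
    """Synthetic adaptive-evolution SNP table with one sweeping locus.

    The sweep locus rises monotonically to 100% at the final timepoint;
    the remaining loci fluctuate in [0, 90). Positions, base changes and
    frequencies are drawn from the seeded generator, so equal seeds give
    identical tables.
    """
    if loci < 1:
        raise ValueError("loci must be >= 1")
    if not (0 <= sweep_locus < loci):
        raise ValueError("sweep_locus out of range")
    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(10_000, 4_000_000), size=loci, replace=False)
    )
    bases = "ACGT"
    records = []
    for i in range(loci):
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        n_tp = len(timepoints)
        if i == sweep_locus:
            # monotone trajectory ending fixed at 100%
            raw = np.sort(rng.uniform(20.0, 99.0, size=max(n_tp - 1, 0)))
            freqs = np.append(raw, 100.0) if n_tp > 1 else np.array([100.0])
        else:
            freqs = rng.uniform(0.0, 90.0, size=n_tp)
        records.append(
            SNPRecord(
                position=int(positions[i]),
                mutation=f"{ref}->{alt}",
                frequencies={
                    tp: float(round(f, 1)) for tp, f in zip(timepoints, freqs)
                },
                amino_acid_change="",
                gene=f"locus_{i:03d}",
                annotation="synthetic variant",
            )
        )
    return records
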