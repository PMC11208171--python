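"""Quantitative reduction of growth and conversion experiments.

Covers the arithmetic a bench scientist applies to batch cultures and
resting-cell suspensions: endpoint substrate:product ratios, fold changes
of enzyme activities, exponential growth rates from OD600 series
(log-linear fit over a sliding window), specific conversion rates in
nmol min^-1 mg^-1, and filtering/sorting of SNP population-frequency
tables from adaptive laboratory evolution.

Reported values are rounded half-up at the stated number of decimals to
match printed laboratory precision; raw values are always available.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from importlib import resources

from ._rational import round_half_up

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TimeCourse:
    """A (time, value) series: OD600 or a metabolite concentration.

    times are hours (strictly increasing); values are mM for metabolites or
    dimensionless for OD600. ``protein_conc`` (mg/mL) is carried for
    specific-rate calculations on resting-cell suspensions.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    unit: str = "mM"
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("a time course needs at least 2 points")
        if not np.all(np.isfinite(times)):
            raise ValueError("times must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.unit == "mM" and np.any(values < -1e-12):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SNPRecord:
    """One row of a SNP population-frequency table.

    ``frequencies`` maps a timepoint label to percent of the population
    carrying the variant; blank table cells are stored as 0 with the label
    recorded in ``undetected`` (the variant was simply not observed).
    """

    position: int
    mutation: str
    frequencies: Mapping[str, float]
    amino_acid_change: str = ""
    gene: str = ""
    annotation: str = ""
    undetected: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError("position must be > 0")
        for tp, f in self.frequencies.items():
            if not (0.0 <= f <= 100.0):
                raise ValueError(
                    f"frequency {f!r} at {tp!r} outside [0, 100]"
                )

    def frequency_at(self, timepoint: str) -> float:
        """Frequency at a timepoint; absent timepoints count as 0%."""
        return float(self.frequencies.get(timepoint, 0.0))


@dataclass(frozen=True)
class GrowthRateFit:
    """Result of the log-linear growth-rate fit."""

    mu: float  # 1/h
    window: tuple[float, float]  # (t_start, t_end) of the fitted window
    n_points: int
    r_squared: float | None  # None for a degenerate (flat) series
    degenerate: bool = False

    @property
    def doubling_time(self) -> float:
        return math.inf if self.mu == 0 else math.log(2) / self.mu


# ---------------------------------------------------------------------------
# CSV / TSV I/O

_META_RE = re.compile(r"^#\s*(\w+)\s*:\s*(.+?)\s*$")

#: column order of the SNP table dialect (mirrors the published table)
SNP_COLUMNS = [
    "position",
    "mutation",
    "freq_before",
    "freq_adapted",
    "freq_10th",
    "aa_change",
    "gene",
    "annotation",
]

#: mapping of the table's frequency columns to timepoint labels
SNP_TIMEPOINTS = {
    "freq_before": "before adaptation",
    "freq_adapted": "after adaptation",
    "freq_10th": "10th transfer",
}


def read_timecourse_csv(path: str | Path | io.TextIOBase) -> list[TimeCourse]:
    """Read the package's time-course CSV dialect.

    Header ``time_h,value[,series]`` preceded by optional metadata comments
    (``# protein_mg_per_ml: 1.0``, ``# unit: mM``). Returns one TimeCourse
    per distinct series label (a missing series column yields one course).
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        m = _META_RE.match(line)
        if m:
            meta[m.group(1)] = m.group(2)
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if "time_h" not in df.columns or "value" not in df.columns:
        raise ValueError("expected columns time_h,value[,series]")
    protein = float(meta["protein_mg_per_ml"]) if "protein_mg_per_ml" in meta else None
    unit = meta.get("unit", "mM")
    courses = []
    if "series" in df.columns:
        groups = [(str(k), g) for k, g in df.groupby("series", sort=False)]
    else:
        groups = [("", df)]
    for label, g in groups:
        g = g.sort_values("time_h")
        courses.append(
            TimeCourse(
                times=g["time_h"].to_numpy(float),
                values=g["value"].to_numpy(float),
                label=label,
                unit=unit,
                protein_conc=protein,
            )
        )
    return courses


def write_timecourse_csv(
    courses: Iterable[TimeCourse], path: str | Path
) -> None:
    """Write time courses in the dialect read_timecourse_csv expects."""
    courses = list(courses)
    lines = []
    protein = next(
        (c.protein_conc for c in courses if c.protein_conc is not None), None
    )
    if protein is not None:
        lines.append(f"# protein_mg_per_ml: {protein}")
    units = {c.unit for c in courses}
    if len(units) == 1:
        lines.append(f"# unit: {units.pop()}")
    multi = len(courses) > 1 or any(c.label for c in courses)
    lines.append("time_h,value,series" if multi else "time_h,value")
    for c in courses:
        for t, v in zip(c.times, c.values):
            row = f"{t:g},{v:.6g}"
            if multi:
                row += f",{c.label}"
            lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_table(path: str | Path | io.TextIOBase) -> list[SNPRecord]:
    """Read a TSV SNP table in the published column layout.

    Blank frequency cells become 0% flagged as undetected. Malformed
    frequencies raise a parse error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        freqs: dict[str, float] = {}
        undetected = set()
        for col, tp in SNP_TIMEPOINTS.items():
            cell = str(row[col]).strip().rstrip("%")
            if not cell:
                freqs[tp] = 0.0
                undetected.add(tp)
                continue
            try:
                freqs[tp] = float(cell)
            except ValueError:
                raise ValueError(
                    f"row {i + 2}: malformed frequency {row[col]!r} in {col}"
                ) from None
        try:
            records.append(
                SNPRecord(
                    position=int(str(row["position"]).replace(",", "")),
                    mutation=row["mutation"],
                    frequencies=freqs,
                    amino_acid_change=row["aa_change"],
                    gene=row["gene"],
                    annotation=row["annotation"],
                    undetected=frozenset(undetected),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 2}: {exc}") from None
    return records


def load_adaptation_snp_table() -> list[SNPRecord]:
    """The packaged SNP table of the CO-adaptation experiment.

    Population frequencies of the variants observed in the hydrogenase-free
    mutant before adaptation, after the six-month adaptation on CO, and
    after the tenth transfer.
    """
    ref = resources.files("acetoflux.data").joinpath("co_adaptation_snps.tsv")
    with ref.open("r") as fh:
        return read_snp_table(fh)


def write_snp_table(records: Iterable[SNPRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "position": r.position,
            "mutation": r.mutation,
            "aa_change": r.amino_acid_change,
            "gene": r.gene,
            "annotation": r.annotation,
        }
        for col, tp in SNP_TIMEPOINTS.items():
            row[col] = (
                "" if tp in r.undetected else f"{r.frequency_at(tp):g}"
            )
        rows.append(row)
    pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# operations


def endpoint_ratio(
    consumed: float,
    produced: float,
    decimals: int = 1,
    orientation: str = "produced_per_consumed",
) -> float:
    """Endpoint stoichiometric ratio of a conversion experiment.

    orientation "produced_per_consumed" (default) reports mol product per
    mol substrate (fructose:acetate 1:x); "consumed_per_produced" reports
    the inverse (CO:formate x:1).
    """
    if consumed <= 0 or produced <= 0:
        raise ValueError("consumed and produced must both be > 0")
    if orientation == "produced_per_consumed":
        value = produced / consumed
    elif orientation == "consumed_per_produced":
        value = consumed / produced
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return round_half_up(value, decimals)


def fold_change(a: float, b: float, decimals: int = 1) -> float:
    """a relative to b, rounded half-up; integers once the fold is >= 10.

    Matches how activity comparisons are conventionally printed
    (6.7-fold, but 25-fold rather than 25.1-fold).
    """
    if b <= 0:
        raise ValueError("reference value b must be > 0")
    value = a / b
    if abs(value) >= 10:
        return round_half_up(value, 0)
    return round_half_up(value, decimals)


def growth_rate(od: TimeCourse, window_min_points: int = 4) -> GrowthRateFit:
    """Exponential growth rate from an OD600 series.

    Fits ln(OD) vs time by least squares over every contiguous window of at
    least ``window_min_points`` points and keeps the window with the
    highest R-squared. R-squared values are compared at two decimals:
    differences smaller than 0.01 are not meaningful evidence that one
    window is more exponential than another, so such near-ties resolve to
    the longer (better-determined), then the earlier window. A noiseless
    exponential therefore fits over the whole series and is recovered
    exactly, and short windows cannot win on fitting luck alone. A flat
    (constant) series has no defined R-squared and is reported as a
    degenerate fit with mu = 0.
    """
    mask = od.values > 0
    if mask.sum() < window_min_points:
        raise ValueError(
            f"need at least {window_min_points} positive OD values, "
            f"got {int(mask.sum())}"
        )
    t = od.times[mask]
    y = np.log(od.values[mask])
    n = len(t)

    if np.allclose(y, y[0]):
        return GrowthRateFit(
            mu=0.0,
            window=(float(t[0]), float(t[-1])),
            n_points=n,
            r_squared=None,
            degenerate=True,
        )

    best: tuple[float, int, float] | None = None  # (r2, length, -t_start)
    best_fit: GrowthRateFit | None = None
    for length in range(window_min_points, n + 1):
        for start in range(0, n - length + 1):
            tw = t[start : start + length]
            yw = y[start : start + length]
            ss_tot = float(np.sum((yw - yw.mean()) ** 2))
            if ss_tot == 0.0:
                continue  # flat sub-window: no exponential information
            slope, intercept = np.polyfit(tw, yw, 1)
            resid = yw - (slope * tw + intercept)
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
            key = (round(r2, 2), length, -tw[0])
            if best is None or key > best:
                best = key
                best_fit = GrowthRateFit(
                    mu=float(slope),
                    window=(float(tw[0]), float(tw[-1])),
                    n_points=length,
                    r_squared=r2,
                )
    assert best_fit is not None
    return best_fit


def specific_rate(
    tc: TimeCourse, window: tuple[float, float] | None = None
) -> float:
    """Specific conversion rate in nmol min^-1 mg^-1 over a time window.

    Uses |delta concentration| / delta time between the first and last
    samples inside the window. Concentrations are mM in a fixed-volume
    suspension (mM == nmol/uL), so mM/h converts via x1000/60 and division
    by the protein concentration (mg/mL).
    """
    if tc.protein_conc is None:
        raise ValueError("specific_rate requires protein_conc (mg/mL)")
    if tc.protein_conc <= 0:
        raise ValueError("protein_conc must be > 0")
    if window is None:
        window = (float(tc.times[0]), float(tc.times[-1]))
    t0, t1 = window
    mask = (tc.times >= t0 - 1e-12) & (tc.times <= t1 + 1e-12)
    if mask.sum() < 2:
        raise ValueError(f"window {window} contains fewer than 2 samples")
    t = tc.times[mask]
    v = tc.values[mask]
    dt_h = float(t[-1] - t[0])
    dc_mm = abs(float(v[-1] - v[0]))
    return dc_mm / dt_h * 1000.0 / 60.0 / tc.protein_conc


def snp_report(
    records: Sequence[SNPRecord],
    timepoint: str,
    min_frequency: float = 0.0,
) -> list[SNPRecord]:
    """Variants at or above ``min_frequency`` percent at ``timepoint``.

    Sorted by descending frequency, then ascending genome position; the
    ordering is total, so repeated reports are identical. Records lacking
    the timepoint count as 0% (undetected).
    """
    hits = [
        r for r in records if r.frequency_at(timepoint) >= min_frequency
    ]
    return sorted(
        hits, key=lambda r: (-r.frequency_at(timepoint), r.position)
    )
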