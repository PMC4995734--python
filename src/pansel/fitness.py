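"""Relative fitness from serially propagated (back-slopped) competitions.

Strain abundances come from plate counts or from qPCR: threshold cycles are
converted to gene copies per gram through a standard curve (Ct linear in
log10 copies), copies to CFU through a strain-specific calibration line in
log10 space, and values below the assay's detection limit are censored.
The per-cycle relative fitness of strain x versus strain y is the ratio of
their realized Malthusian growth,

    w = ln(x_F / x_0) / ln(y_F / y_0),

so w = 1 means equal realized growth over the cycle, and w > 1 means x
out-grew y.  Per-cycle values are pooled across cycles and replicate
experiments into a mean +/- sample standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DETECTION_LIMIT_DEFAULT = 1e2  # copies per g


# --------------------------------------------------------------------------- qPCR curves
@dataclass
class StandardCurve:
    """Ct = intercept + slope * log10(copies); slope < 0 for a valid assay."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_to_copies(self, ct: float) -> float:
        return 10.0 ** ((ct - self.intercept) / self.slope)

    def copies_to_ct(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Least squares of Ct on log10 copies from a dilution series.

    Needs >= 3 points spanning >= 2 log10 units; a positive slope (invalid
    assay) produces a warning, not an error.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) < 2.0:
        raise ValueError("dilution series must span at least 2 log10 units")
    if len(np.unique(x)) < 2:
        raise ValueError("rank-deficient dilution series (all concentrations equal)")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    if slope >= 0:
        warnings.warn(f"standard-curve slope {slope:.3f} >= 0: invalid assay")
    return StandardCurve(float(slope), float(intercept), r2)


class BelowDetection(float):
    """A censored measurement; carries the limit it fell under."""

    def __new__(cls, value: float, limit: float):
        obj = super().__new__(cls, value)
        obj.limit = limit
        return obj


def apply_detection_limit(copies_per_g: float, limit: float = DETECTION_LIMIT_DEFAULT):
    """Censor values below the detection limit (inclusive boundary retained)."""
    if limit <= 0:
        raise ValueError("detection limit must be positive")
    if copies_per_g < limit:
        return BelowDetection(copies_per_g, limit)
    return float(copies_per_g)


@dataclass
class Calibration:
    """log10 CFU/g = intercept + slope * log10 copies/g, valid on fit_range."""

    slope: float
    intercept: float
    fit_range: tuple[float, float] = (0.0, 12.0)  # log10 copies


def fit_calibration(points: list[tuple[float, float]]) -> Calibration:
    """OLS of log10 CFU on log10 copies from single-strain fermentations."""
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return Calibration(float(slope), float(intercept), (float(x.min()), float(x.max())))


def copies_to_cfu(copies_per_g: float, cal: Calibration) -> float:
    if isinstance(copies_per_g, BelowDetection):
        raise ValueError("censored measurement: apply_detection_limit flagged it; "
                         "exclude the cycle instead of converting")
    if copies_per_g <= 0:
        raise ValueError("copies must be positive")
    lx = math.log10(copies_per_g)
    if not cal.fit_range[0] <= lx <= cal.fit_range[1]:
        warnings.warn(f"log10 copies {lx:.2f} outside calibration range {cal.fit_range}")
    return 10.0 ** (cal.intercept + cal.slope * lx)


# --------------------------------------------------------------------------- series
@dataclass
class CompetitionSeries:
    """Start/end abundances of two competing strains over fermentation cycles.

    ``start`` and ``end`` map strain name -> list over cycles; censored
    cycles hold ``BelowDetection`` (never 0).
    """

    strain_x: str
    strain_y: str
    start: dict[str, list[float]]
    end: dict[str, list[float]]
    source: str = "plate_count"  # or "qpcr"
    detection_limit: float = DETECTION_LIMIT_DEFAULT
    truncated: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.end[self.strain_x])


@dataclass
class FitnessEstimate:
    per_cycle_w: list[float]  # NaN marks censored/undefined cycles
    mean: float
    sd: float
    n_replicates: int


def relative_fitness(x_0: float, x_f: float, y_0: float, y_f: float) -> float:
    """w = ln(x_F/x_0) / ln(y_F/y_0); w = 1 iff equal realized growth."""
    for name, v in (("x_0", x_0), ("x_F", x_f), ("y_0", y_0), ("y_F", y_f)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    denom = math.log(y_f / y_0)
    if denom == 0:
        raise ValueError("y_F equals y_0: reference strain did not grow; w undefined")
    return math.log(x_f / x_0) / denom


def series_fitness(series: CompetitionSeries) -> list[float]:
    """Per-cycle w of strain x vs strain y; censored cycles yield NaN."""
    out = []
    for c in range(series.n_cycles):
        vals = [series.start[series.strain_x][c], series.end[series.strain_x][c],
                series.start[series.strain_y][c], series.end[series.strain_y][c]]
        if any(v is None or isinstance(v, BelowDetection) for v in vals):
            out.append(float("nan"))
            continue
        try:
            out.append(relative_fitness(vals[0], vals[1], vals[2], vals[3]))
        except ValueError:
            out.append(float("nan"))
    return out


def aggregate_fitness(all_series: list[CompetitionSeries]) -> FitnessEstimate:
    """Pool finite per-cycle w values across cycles and replicates."""
    w = [v for s in all_series for v in series_fitness(s)]
    finite = [v for v in w if math.isfinite(v)]
    if not finite:
        raise ValueError("no finite per-cycle fitness values to aggregate")
    mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    return FitnessEstimate(w, mean, sd, len(finite))


def proportion_series(series: CompetitionSeries, *, log10_scale: bool = False
                      ) -> dict[str, list[float]]:
    """Per-cycle end-of-cycle strain proportions of the summed abundance."""
    out = {series.strain_x: [], series.strain_y: []}
    for c in range(series.n_cycles):
        vals = {s: float(series.end[s][c]) for s in (series.strain_x, series.strain_y)}
        total = sum(vals.values())
        if total <= 0:
            raise ValueError(f"zero total abundance at cycle {c + 1}")
        for s, v in vals.items():
            p = v / total
            out[s].append(math.log10(p) if log10_scale else p)
    return out


# --------------------------------------------------------------------------- IO
def read_competition_tsv(path, *, detection_limit: float = DETECTION_LIMIT_DEFAULT
                         ) -> list[CompetitionSeries]:
    """Long-format TSV: replicate, cycle, strain, stage (start|end), abundance,
    unit (cfu|copies).  Returns one series per replicate (first two strains)."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "cycle", "strain", "stage", "abundance", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"competition TSV missing columns: {sorted(missing)}")
    out = []
    for rep, grp in df.groupby("replicate"):
        strains = sorted(grp["strain"].unique())
        if len(strains) != 2:
            raise ValueError(f"replicate {rep}: expected 2 strains, got {strains}")
        sx, sy = strains
        cycles = sorted(grp["cycle"].unique())
        start = {s: [] for s in strains}
        end = {s: [] for s in strains}
        unit = grp["unit"].iloc[0]
        for c in cycles:
            for s in strains:
                for stage, store in (("start", start), ("end", end)):
                    sel = grp[(grp.cycle == c) & (grp.strain == s) & (grp.stage == stage)]
                    if sel.empty:
                        store[s].append(None)
                    else:
                        v = float(sel["abundance"].iloc[0])
                        store[s].append(apply_detection_limit(v, detection_limit)
                                        if unit == "copies" else v)
        out.append(CompetitionSeries(sx, sy, start, end,
                                     source="qpcr" if unit == "copies" else "plate_count",
                                     detection_limit=detection_limit))
    return out


def write_fitness_tsv(estimate: FitnessEstimate, path, *, label: str = "w") -> None:
    with open(path, "w") as fh:
        fh.write("cycle\tw\n")
        for i, v in enumerate(estimate.per_cycle_w, start=1):
            fh.write(f"{i}\t{v:.6g}\n")
        fh.write(f"# mean={estimate.mean:.6g}\tsd={estimate.sd:.6g}"
                 f"\tn={estimate.n_replicates}\n")
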