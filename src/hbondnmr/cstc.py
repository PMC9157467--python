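"""Amide-proton chemical-shift temperature coefficients (CSTC).

An amide proton whose chemical shift falls only gently with temperature
(slope above about -4.6 ppb/K) is interpreted as intramolecularly hydrogen
bonded; a steeper slope indicates a solvent-exposed amide. The slope is fit
per residue by ordinary least squares of the 1H shift (in ppb) on
temperature (K).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from hbondnmr.structio import ShiftTable


class InsufficientDataError(ValueError):
    pass


class SingularFitError(ValueError):
    pass


class HBClass(enum.Enum):
    HBONDED = "HBONDED"
    NOT_HBONDED = "NOT_HBONDED"
    UNCLASSIFIED = "UNCLASSIFIED"
    PROLINE = "PROLINE"


@dataclass(frozen=True)
class TempSeries:
    """Amide 1H shifts of one residue across temperatures (K, ppm)."""

    residue_number: int
    residue_type: str
    points: tuple[tuple[float, float], ...]  # (temperature K, dH ppm)
    dn_points: tuple[tuple[float, float], ...] = ()  # bookkeeping only

    def __post_init__(self):
        temps = [t for t, _ in self.points]
        if len(self.points) >= 2 and any(
            t2 <= t1 for t1, t2 in zip(temps, temps[1:])
        ):
            raise ValueError(
                f"residue {self.residue_number}: temperatures must be strictly increasing"
            )


@dataclass(frozen=True)
class TempCoefficient:
    """OLS fit of one residue's amide 1H shift versus temperature.

    slope is in ppb/K (more negative = more solvent exposed); intercept is the
    predicted shift in ppm at the 298 K reference temperature.
    """

    residue_number: int
    slope: float
    intercept: float
    slope_stderr: float
    n_points: int
    r_squared: float

    REFERENCE_T: float = field(default=298.0, repr=False)


@dataclass(frozen=True)
class CstcConfig:
    threshold: float = -4.6  # ppb/K
    min_points: int = 3
    ci_multiplier: float = 1.96
    use_ci_band: bool = True

    def __post_init__(self):
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


def fit_temp_coefficient(series: TempSeries, min_points: int = 3) -> TempCoefficient:
    """Fit slope (ppb/K) of the amide 1H shift against temperature by OLS.

    The slope is invariant to adding a constant to all temperatures or all
    shifts; the standard error comes from the residual variance (zero for an
    exact fit or for fewer points than residual degrees of freedom allow).
    """
    if len(series.points) < min_points:
        raise InsufficientDataError(
            f"residue {series.residue_number}: {len(series.points)} points "
            f"< min_points {min_points}"
        )
    temps = np.array([t for t, _ in series.points], dtype=float)
    shifts_ppb = np.array([s for _, s in series.points], dtype=float) * 1000.0
    if np.ptp(temps) == 0:
        raise SingularFitError(f"residue {series.residue_number}: identical temperatures")
    if np.ptp(shifts_ppb) == 0.0:
        # constant series: slope 0 with zero uncertainty; r^2 undefined, report 1
        dh298 = shifts_ppb[0] / 1000.0
        return TempCoefficient(series.residue_number, 0.0, dh298, 0.0,
                               len(temps), 1.0)
    fit = stats.linregress(temps, shifts_ppb)
    intercept_298 = (fit.intercept + fit.slope * 298.0) / 1000.0
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
    return TempCoefficient(
        residue_number=series.residue_number,
        slope=float(fit.slope),
        intercept=float(intercept_298),
        slope_stderr=stderr,
        n_points=len(temps),
        r_squared=float(fit.rvalue) ** 2,
    )


def classify(
    coef: TempCoefficient, config: CstcConfig = CstcConfig(), is_proline: bool = False
) -> HBClass:
    """Assign a hydrogen-bond class from the fitted temperature coefficient.

    Slopes above the threshold are hydrogen bonded, below it exposed. When the
    confidence band slope +/- ci_multiplier*stderr straddles the threshold the
    residue is left unclassified, as is an exact tie (the strict >/< rule
    covers neither).
    """
    if is_proline:
        return HBClass.PROLINE
    thr = config.threshold
    if config.use_ci_band and coef.slope_stderr > 0:
        half = config.ci_multiplier * coef.slope_stderr
        if coef.slope - half <= thr <= coef.slope + half:
            return HBClass.UNCLASSIFIED
    if coef.slope > thr:
        return HBClass.HBONDED
    if coef.slope < thr:
        return HBClass.NOT_HBONDED
    return HBClass.UNCLASSIFIED


def summarize_classes(classes: Iterable[HBClass]) -> dict[str, int]:
    """Count residues per class; labels partition the total."""
    counts = Counter(c.value for c in classes)
    summary = {label.value: counts.get(label.value, 0) for label in HBClass}
    summary["total"] = sum(counts.values())
    return summary


def series_from_tables(tables: Sequence[ShiftTable]) -> list[TempSeries]:
    """Assemble per-residue temperature series from single-temperature tables.

    Each table must carry its acquisition temperature; residues missing from
    some tables contribute only the points they have. Prolines (blank amide
    shifts) yield empty series retained for bookkeeping.
    """
    if any(t.temperature is None for t in tables):
        raise ValueError("every shift table needs a temperature_K to build series")
    tables = sorted(tables, key=lambda t: t.temperature)
    residues: dict[int, dict] = {}
    for table in tables:
        for row in table.data.itertuples(index=False):
            rec = residues.setdefault(
                row.residue_number,
                {"type": row.residue_type, "h": [], "n": []},
            )
            if np.isfinite(row.dH_ppm):
                rec["h"].append((table.temperature, float(row.dH_ppm)))
            if np.isfinite(row.dN_ppm):
                rec["n"].append((table.temperature, float(row.dN_ppm)))
    return [
        TempSeries(
            residue_number=num,
            residue_type=rec["type"],
            points=tuple(rec["h"]),
            dn_points=tuple(rec["n"]),
        )
        for num, rec in sorted(residues.items())
    ]


def classify_tables(
    tables: Sequence[ShiftTable], config: CstcConfig = CstcConfig()
) -> tuple[dict[int, HBClass], dict[int, TempCoefficient], dict[int, str]]:
    """End-to-end CSTC: tables -> per-residue class, coefficient and type maps."""
    classes: dict[int, HBClass] = {}
    coefs: dict[int, TempCoefficient] = {}
    types: dict[int, str] = {}
    for series in series_from_tables(tables):
        types[series.residue_number] = series.residue_type
        if series.residue_type == "P":
            classes[series.residue_number] = HBClass.PROLINE
            continue
        coef = fit_temp_coefficient(series, min_points=config.min_points)
        coefs[series.residue_number] = coef
        classes[series.residue_number] = classify(coef, config)
    return classes, coefs, types


def classification_accuracy(
    classes: Mapping[int, HBClass], truth: Mapping[int, HBClass]
) -> float:
    """Fraction of residues whose class matches the planted truth."""
    shared = sorted(set(classes) & set(truth))
    if not shared:
        raise ValueError("no residues shared between classes and truth")
    hits = sum(classes[r] == truth[r] for r in shared)
    return hits / len(shared)
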