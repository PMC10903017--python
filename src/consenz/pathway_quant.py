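"""Quantitative arithmetic for the Phe → tCA → styrene pathway.

The two enzymatic steps (phenylalanine ammonia lyase, then trans-cinnamic
acid decarboxylase) convert one mole of L-phenylalanine into one mole of
trans-cinnamic acid and then one mole of styrene.  Mass concentrations are
interconverted through molar-mass ratios under this 1:1:1 stoichiometry;
initial consumption/formation rates are the least-squares slope of a
concentration time course over the earliest assay window (default: the
first two hours, boundary inclusive).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Standard molar masses (g/mol) of the pathway compounds.
DEFAULT_MOLAR_MASSES: dict[str, float] = {
    "L-Phe": 165.19,
    "tCA": 148.16,
    "styrene": 104.15,
}

_ALIASES = {
    "l-phe": "L-Phe", "phe": "L-Phe", "l-phenylalanine": "L-Phe",
    "phenylalanine": "L-Phe",
    "tca": "tCA", "trans-cinnamic acid": "tCA", "cinnamate": "tCA",
    "styrene": "styrene",
}


@dataclass(frozen=True)
class PathwayStoichiometry:
    """Molar masses plus the 1:1:1 molar mapping along the pathway."""

    molar_mass: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOLAR_MASSES)
    )

    def __post_init__(self) -> None:
        for compound, mass in self.molar_mass.items():
            if mass <= 0:
                raise InputError(f"molar mass for {compound} must be positive")

    def resolve(self, compound: str) -> str:
        if compound in self.molar_mass:
            return compound
        canon = _ALIASES.get(compound.lower())
        if canon in self.molar_mass:
            return canon
        raise InputError(
            f"unknown compound {compound!r}; known: {sorted(self.molar_mass)}"
        )

    def mass(self, compound: str) -> float:
        return self.molar_mass[self.resolve(compound)]


DEFAULT_STOICHIOMETRY = PathwayStoichiometry()


@dataclass(frozen=True)
class BioconversionSeries:
    """Timestamped concentrations of one analyte (h, mg/L)."""

    analyte: str
    samples: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.samples]
        if any(t < 0 for t in times):
            raise InputError("sample times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("sample times must be strictly increasing")
        if any(c < 0 for _, c in self.samples):
            raise InputError("concentrations must be non-negative")

    @property
    def times(self) -> list[float]:
        return [t for t, _ in self.samples]

    @property
    def concentrations(self) -> list[float]:
        return [c for _, c in self.samples]


def stoich_convert(
    conc_mg_per_l: float,
    from_compound: str,
    to_compound: str,
    stoich: PathwayStoichiometry = DEFAULT_STOICHIOMETRY,
) -> float:
    """Convert a mass concentration between pathway compounds (1:1 molar)."""
    return conc_mg_per_l * stoich.mass(to_compound) / stoich.mass(from_compound)


def yield_per_substrate(product_mg_per_l: float, substrate_g_per_l: float) -> float:
    """Product yield in mg product per g substrate (e.g. mg styrene / g glucose)."""
    if substrate_g_per_l <= 0:
        raise InputError("substrate concentration must be positive")
    return product_mg_per_l / substrate_g_per_l


def initial_rate(series: BioconversionSeries, window_h: float = 2.0) -> float:
    """Initial rate as the OLS slope over samples with time <= window (mg/L/h).

    The sign is retained: negative slopes indicate consumption.  The window
    boundary is inclusive ("the first two hours").
    """
    in_window = [(t, c) for t, c in series.samples if t <= window_h]
    if len(in_window) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples within [0, {window_h}] h, got {len(in_window)}"
        )
    times = [t for t, _ in in_window]
    concs = [c for _, c in in_window]
    if len(set(times)) < 2:
        raise InsufficientDataError("in-window samples share a single time point")
    result = stats.linregress(times, concs)
    return float(result.slope)


def conversion_fraction(
    substrate_consumed_mg_per_l: float,
    product_formed_mg_per_l: float,
    from_compound: str,
    to_compound: str,
    stoich: PathwayStoichiometry = DEFAULT_STOICHIOMETRY,
) -> float:
    """Fraction of consumed substrate recovered as product, stoichiometrically.

    A value above 1 can only arise from measurement noise; it is flagged via
    a warning but never clamped.
    """
    if substrate_consumed_mg_per_l <= 0:
        raise InputError("substrate consumption must be positive")
    expected = stoich_convert(
        substrate_consumed_mg_per_l, from_compound, to_compound, stoich
    )
    frac = product_formed_mg_per_l / expected
    if frac > 1.0:
        logger.warning(
            "conversion fraction %.3f exceeds 1: product exceeds the "
            "stoichiometric maximum (measurement noise?)", frac
        )
    return frac


def round_sig(value: float, sig_figs: int) -> float:
    """Round to a number of significant figures."""
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, -magnitude + sig_figs - 1)


def annualize(daily_tons: float, days: int = 365, sig_figs: int | None = 2) -> float:
    """Annual production from a daily rate, rounded to significant figures."""
    if daily_tons < 0:
        raise InputError("daily production must be non-negative")
    total = daily_tons * days
    if sig_figs is None:
        return total
    return round_sig(total, sig_figs)


def read_series_csv(path: str | Path) -> dict[str, BioconversionSeries]:
    """Load time series from CSV columns (time_h, analyte, conc_mg_L)."""
    df = pd.read_csv(path)
    required = {"time_h", "analyte", "conc_mg_L"}
    if not required <= set(df.columns):
        raise InputError(f"series CSV needs columns {sorted(required)}")
    out = {}
    for analyte, grp in df.groupby("analyte", sort=False):
        grp = grp.sort_values("time_h")
        out[str(analyte)] = BioconversionSeries(
            analyte=str(analyte),
            samples=tuple(zip(grp["time_h"].astype(float), grp["conc_mg_L"].astype(float))),
        )
    return out


def write_series_csv(series_list: Sequence[BioconversionSeries], path: str | Path) -> None:
    rows = [
        {"time_h": t, "analyte": s.analyte, "conc_mg_L": c}
        for s in series_list
        for t, c in s.samples
    ]
    pd.DataFrame(rows, columns=["time_h", "analyte", "conc_mg_L"]).to_csv(path, index=False)
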