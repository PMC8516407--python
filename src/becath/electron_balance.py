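"""Electron-equivalent balance and Coulombic-efficiency accounting.

A polarized biocathode supplies electrons that are recovered in several
competing reduction processes: reductive dechlorination of chlorinated
ethenes (RD), Cr(VI)-to-Cr(III) reduction, and hydrogenotrophic
methanogenesis (CO2 -> CH4).  This module turns steady-state effluent
concentrations and the cell current into

* volumetric process rates in electron equivalents (ueq L-1 d-1,
  referenced to the empty cathode-chamber volume),
* per-process Coulombic efficiencies (CE, % of the supplied current), and
* the residual "CE excess" closing the balance to 100 %.

Stoichiometry: producing one mole of cis-DCE, VC, ethene or ethane from
TCE consumes 2, 4, 6 or 8 moles of electrons respectively; Cr(VI)->Cr(III)
consumes 3; CO2->CH4 consumes 8.

Internal canonical units are umol/L, L/d, uA and days; the Faraday
constant is 96,485 C per mole of electrons and a day has 86,400 s.  All
unit plumbing lives in the helpers here, nowhere else.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ANALYTES",
    "RD_PRODUCTS",
    "ReactorConfig",
    "ElectronEquivalentCatalog",
    "RateResult",
    "EfficiencyReport",
    "MonitoringSeries",
    "ConfigurationError",
    "OpenCircuitError",
    "rd_rate",
    "cr_rate",
    "ch4_rate",
    "ch4_current",
    "rate_to_current",
    "coulombic_efficiency",
    "ce_excess",
    "removal_efficiency",
    "henry_liquid_conc",
    "summarize_run",
]

SECONDS_PER_DAY = 86400.0

#: Analytes tracked in monitoring series (liquid phase, umol/L).
ANALYTES = ("TCE", "cisDCE", "VC", "ETH", "ETA", "CH4", "CrVI")

#: Dechlorination products in order of increasing electron demand.
RD_PRODUCTS = ("cisDCE", "VC", "ETH", "ETA")


class ConfigurationError(ValueError):
    """Reactor configuration is missing or physically impossible."""


class OpenCircuitError(ValueError):
    """No (positive) cell current: Coulombic efficiency is undefined."""


class ReactorConfig(BaseModel):
    """Geometry and physical constants of the continuous-flow biocathode.

    Parameters
    ----------
    flow_rate_Q:
        Liquid flow rate through the cathode chamber, L d-1.
    cathode_empty_volume_Vc:
        Empty volume of the cathode chamber (without the electrode), L.
        All volumetric rates are referenced to this volume.
    faraday_F:
        Faraday constant, C per mole of electrons.
    temperature_C:
        Operating temperature, degC (only documents the Henry constant).
    henry_constant_CH4:
        Henry solubility of methane, mol L-1 atm-1, used to convert a
        headspace partial pressure into a dissolved concentration.
    """

    flow_rate_Q: float = Field(gt=0, default=0.58)
    cathode_empty_volume_Vc: float = Field(gt=0, default=0.821)
    faraday_F: float = Field(gt=0, default=96485.0)
    temperature_C: float = 25.0
    henry_constant_CH4: float | None = 1.4e-3

    @property
    def hydraulic_retention_time_d(self) -> float:
        """Cathodic HRT = Vc / Q, days."""
        return self.cathode_empty_volume_Vc / self.flow_rate_Q

    @property
    def dilution_rate_per_d(self) -> float:
        """Q / Vc, d-1 — the factor turning umol/L into umol L-1 d-1."""
        return self.flow_rate_Q / self.cathode_empty_volume_Vc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReactorConfig":
        """Load a ``reactor:`` mapping from a YAML config file."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        section = doc.get("reactor", doc)
        mapping = {
            "Q_L_per_d": "flow_rate_Q",
            "Vc_L": "cathode_empty_volume_Vc",
            "faraday": "faraday_F",
            "henry_CH4": "henry_constant_CH4",
            "temperature_C": "temperature_C",
        }
        kwargs = {mapping.get(k, k): v for k, v in section.items()}
        return cls(**kwargs)


class ElectronEquivalentCatalog(BaseModel):
    """Moles of electrons consumed per mole of each reduction product."""

    rd_factors: dict[str, int] = Field(
        default_factory=lambda: {"cisDCE": 2, "VC": 4, "ETH": 6, "ETA": 8}
    )
    cr_factor: int = 3
    ch4_factor: int = 8

    @model_validator(mode="after")
    def _check_factors(self) -> "ElectronEquivalentCatalog":
        if self.cr_factor <= 0 or self.ch4_factor <= 0:
            raise ValueError("electron-equivalent factors must be positive")
        series = [self.rd_factors.get(p) for p in RD_PRODUCTS if p in self.rd_factors]
        if any(f is None or f <= 0 for f in self.rd_factors.values()):
            raise ValueError("rd_factors must be positive")
        if series != sorted(series) or len(set(series)) != len(series):
            raise ValueError(
                "rd_factors must increase strictly along the dechlorination "
                "series cisDCE < VC < ETH < ETA"
            )
        return self


@dataclass(frozen=True)
class RateResult:
    """A volumetric process rate in electron equivalents.

    ``rate`` is in ueq L-1 d-1, referenced to the empty cathode volume.
    """

    process: str
    rate: float
    window: tuple[float, float] | None = None
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"{self.process} rate must be >= 0, got {self.rate}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _validate_conc(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"negative concentration for {name}: {value}")
    return value


def rd_rate(
    conc: Mapping[str, float],
    config: ReactorConfig,
    catalog: ElectronEquivalentCatalog | None = None,
    *,
    window: tuple[float, float] | None = None,
    n_samples: int = 1,
) -> RateResult:
    """Reductive-dechlorination rate from product concentrations.

    rate = (2*[cisDCE] + 4*[VC] + 6*[ETH] + 8*[ETA]) * Q / Vc

    Missing products are treated as zero; negative values raise.
    """
    catalog = catalog or ElectronEquivalentCatalog()
    ueq_per_L = sum(
        factor * _validate_conc(product, conc.get(product, 0.0))
        for product, factor in catalog.rd_factors.items()
    )
    return RateResult("RD", ueq_per_L * config.dilution_rate_per_d, window, n_samples)


def cr_rate(
    conc_CrVI_removed: float,
    config: ReactorConfig,
    catalog: ElectronEquivalentCatalog | None = None,
    *,
    window: tuple[float, float] | None = None,
    n_samples: int = 1,
) -> RateResult:
    """Cr(VI)-reduction rate: 3 * [Cr(VI) removed] * Q / Vc."""
    catalog = catalog or ElectronEquivalentCatalog()
    removed = _validate_conc("CrVI", conc_CrVI_removed)
    return RateResult(
        "CrVI", catalog.cr_factor * removed * config.dilution_rate_per_d, window, n_samples
    )


def ch4_rate(
    conc_CH4: float,
    config: ReactorConfig,
    catalog: ElectronEquivalentCatalog | None = None,
    *,
    window: tuple[float, float] | None = None,
    n_samples: int = 1,
) -> RateResult:
    """Methane production rate: 8 * [CH4] * Q / Vc."""
    catalog = catalog or ElectronEquivalentCatalog()
    conc = _validate_conc("CH4", conc_CH4)
    return RateResult(
        "CH4", catalog.ch4_factor * conc * config.dilution_rate_per_d, window, n_samples
    )


def rate_to_current(rate: float | RateResult, config: ReactorConfig) -> float:
    """Current equivalent (uA) of an electron-equivalent rate.

    I[uA] = rate[ueq L-1 d-1] * Vc[L] * F[C mol-1] / 86400[s d-1]

    (ueq d-1 is umol e- d-1; multiplying by F gives uC d-1, dividing by
    the seconds in a day gives uC s-1 = uA.)
    """
    r = rate.rate if isinstance(rate, RateResult) else float(rate)
    if r < 0:
        raise ValueError("rate must be >= 0")
    return r * config.cathode_empty_volume_Vc * config.faraday_F / SECONDS_PER_DAY


def ch4_current(conc_CH4: float, config: ReactorConfig,
                catalog: ElectronEquivalentCatalog | None = None) -> float:
    """Current equivalent of methane production, in mA.

    I[mA] = Q[L d-1] * 8 * [CH4][mol L-1] * F / 86400.  Identical to
    ``rate_to_current(ch4_rate(...)) / 1000`` because Vc cancels.
    """
    catalog = catalog or ElectronEquivalentCatalog()
    conc_mol_per_L = _validate_conc("CH4", conc_CH4) * 1e-6
    amperes = (
        config.flow_rate_Q * catalog.ch4_factor * conc_mol_per_L
        * config.faraday_F / SECONDS_PER_DAY
    )
    return amperes * 1e3


def coulombic_efficiency(
    rate: float | RateResult, mean_current_uA: float, config: ReactorConfig
) -> float:
    """Fraction (%) of the supplied current recovered in one process.

    CE% = rate_to_current(rate) / I * 100.
    """
    if mean_current_uA <= 0:
        raise OpenCircuitError(
            "mean current must be positive; zero/negative current indicates "
            "an open-circuit condition under which CE is undefined"
        )
    return rate_to_current(rate, config) / mean_current_uA * 100.0


def _dec(x: float | int | str | Decimal) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def ce_excess(ce_components: Mapping[str, float]) -> float:
    """Unaccounted fraction of the current: 100 - sum of CE components.

    Computed in decimal arithmetic so the closure is exact at the
    components' printed precision (e.g. {2.7, 31, 0} -> 66.3, never
    66.30000000000001).  A negative excess (over-closure from measurement
    error) is returned as-is with a warning, not clipped.
    """
    total = Decimal("100")
    for name, value in ce_components.items():
        if value < 0:
            raise ValueError(f"CE component {name} must be >= 0, got {value}")
        total -= _dec(value)
    if total < 0:
        warnings.warn(
            f"CE components sum to more than 100% (excess {total}); "
            "the electron balance is over-closed",
            stacklevel=2,
        )
    return float(total)


def removal_efficiency(
    influent: float, effluent: float, *, allow_negative_removal: bool = False
) -> float:
    """Percent removal, 100 * (influent - effluent) / influent.

    Effluent below detection is entered as 0 (giving 100 %).  An effluent
    above the influent raises unless ``allow_negative_removal`` is set, in
    which case the result is floored at 0.
    """
    if influent <= 0:
        raise ValueError(f"influent concentration must be > 0, got {influent}")
    if effluent < 0:
        raise ValueError(f"effluent concentration must be >= 0, got {effluent}")
    value = 100.0 * (influent - effluent) / influent
    if value < 0:
        if not allow_negative_removal:
            raise ValueError(
                f"effluent ({effluent}) exceeds influent ({influent}); pass "
                "allow_negative_removal=True to floor at 0"
            )
        return 0.0
    return value


def henry_liquid_conc(headspace_partial_pressure_atm: float,
                      config: ReactorConfig) -> float:
    """Dissolved CH4 (umol/L) in equilibrium with a headspace pressure.

    conc = KH [mol L-1 atm-1] * p [atm], returned in umol/L.
    """
    if headspace_partial_pressure_atm < 0:
        raise ValueError("partial pressure must be >= 0")
    if config.henry_constant_CH4 is None:
        raise ConfigurationError("henry_constant_CH4 is not set in the reactor config")
    return config.henry_constant_CH4 * headspace_partial_pressure_atm * 1e6


class MonitoringSeries:
    """Timestamped effluent concentrations and cell current.

    Thin wrapper over a :class:`pandas.DataFrame` with columns ``time_d``,
    ``<analyte>_uM`` for each analyte present, and optionally
    ``current_uA``.  Missing analytes are simply absent; negative values
    are rejected at construction.
    """

    TIME_COL = "time_d"
    CURRENT_COL = "current_uA"

    def __init__(self, frame: pd.DataFrame):
        if self.TIME_COL not in frame.columns:
            raise ValueError(f"monitoring table needs a '{self.TIME_COL}' column")
        known = {f"{a}_uM" for a in ANALYTES} | {self.TIME_COL, self.CURRENT_COL}
        unknown = set(frame.columns) - known
        if unknown:
            raise ValueError(f"unknown columns in monitoring table: {sorted(unknown)}")
        numeric = frame.apply(pd.to_numeric)
        value_cols = [c for c in numeric.columns if c != self.TIME_COL]
        if value_cols and (numeric[value_cols] < 0).any().any():
            raise ValueError("monitoring table contains negative values")
        self.frame = numeric.sort_values(self.TIME_COL).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(a for a in ANALYTES if f"{a}_uM" in self.frame.columns)

    @property
    def has_current(self) -> bool:
        return self.CURRENT_COL in self.frame.columns

    @classmethod
    def from_samples(
        cls,
        times: Sequence[float],
        conc: Mapping[str, Sequence[float] | float],
        current: Sequence[float] | float | None = None,
    ) -> "MonitoringSeries":
        """Build a series from per-analyte vectors (scalars broadcast)."""
        n = len(times)
        data: dict[str, object] = {cls.TIME_COL: list(times)}
        for analyte, values in conc.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")
            data[f"{analyte}_uM"] = [values] * n if pd.api.types.is_number(values) else list(values)
        if current is not None:
            data[cls.CURRENT_COL] = [current] * n if pd.api.types.is_number(current) else list(current)
        return cls(pd.DataFrame(data))

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "MonitoringSeries":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    def window(self, start: float | None = None, end: float | None = None) -> "MonitoringSeries":
        """Sub-series with start <= time_d <= end (inclusive bounds)."""
        t = self.frame[self.TIME_COL]
        mask = pd.Series(True, index=self.frame.index)
        if start is not None:
            mask &= t >= start
        if end is not None:
            mask &= t <= end
        sub = self.frame[mask]
        if sub.empty:
            raise ValueError(f"no samples in window [{start}, {end}]")
        return MonitoringSeries(sub)

    def mean_concentrations(self) -> dict[str, float]:
        """Equal-weight arithmetic mean of each analyte over the series."""
        return {a: float(self.frame[f"{a}_uM"].mean()) for a in self.analytes}

    def mean_current(self) -> float | None:
        if not self.has_current:
            return None
        return float(self.frame[self.CURRENT_COL].mean())


@dataclass
class EfficiencyReport:
    """Machine twin of a run-performance table.

    ``ce`` holds Coulombic efficiencies quantized to ``ce_decimals``
    decimal places (the resolution the balance is reported at), ``ce_raw``
    the unrounded values; ``ce_excess`` is 100 minus the quantized
    components, computed in decimal arithmetic so the closure is exact.
    """

    rates: dict[str, float]
    ce: dict[str, float] | None
    ce_excess: float | None
    ce_raw: dict[str, float] | None
    mean_current: float | None
    removal_efficiency: dict[str, float] = field(default_factory=dict)
    window: tuple[float, float] | None = None
    n_samples: int = 0
    ce_decimals: int = 2

    def to_dict(self) -> dict:
        d = {
            "RD (ueq/Ld)": self.rates.get("RD"),
            "CH4 production rate (ueq/Ld)": self.rates.get("CH4"),
            "Cr(VI) reduction rate (ueq/Ld)": self.rates.get("CrVI"),
            "CE-RD (%)": None if self.ce is None else self.ce.get("RD"),
            "CE-CH4 (%)": None if self.ce is None else self.ce.get("CH4"),
            "CE-Cr(VI) (%)": None if self.ce is None else self.ce.get("CrVI"),
            "CE-excess (%)": self.ce_excess,
            "mean current (uA)": self.mean_current,
            "n_samples": self.n_samples,
        }
        for contaminant, value in self.removal_efficiency.items():
            d[f"{contaminant} removal efficiency (%)"] = value
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _quantize(value: float, decimals: int) -> float:
    return float(round(_dec(value), decimals))


def summarize_run(
    series: MonitoringSeries,
    config: ReactorConfig,
    catalog: ElectronEquivalentCatalog | None = None,
    window: tuple[float | None, float | None] | None = None,
    influent: Mapping[str, float] | None = None,
    *,
    ce_decimals: int = 2,
    allow_negative_removal: bool = False,
) -> EfficiencyReport:
    """Window-average a monitoring series into rates, CEs and closure.

    Analyte concentrations and current are averaged with equal weight per
    sample over the window, then fed through the pointwise rate and CE
    operations.  Without a current column the report carries rates only
    (CE fields are None).  ``influent`` maps contaminants (TCE, CrVI) to
    feed concentrations for removal efficiencies; the Cr(VI) reduction
    rate uses influent minus effluent Cr(VI) when an influent is given,
    otherwise the effluent column is interpreted as Cr(VI) removed.
    """
    catalog = catalog or ElectronEquivalentCatalog()
    sub = series.window(*window) if window else series
    if len(sub) == 0:
        raise ValueError("empty monitoring window")
    times = sub.frame[MonitoringSeries.TIME_COL]
    win = (float(times.min()), float(times.max()))
    n = len(sub)
    means = sub.mean_concentrations()

    rates: dict[str, float] = {}
    rates["RD"] = rd_rate(means, config, catalog, window=win, n_samples=n).rate
    cr_removed = 0.0
    if influent and "CrVI" in influent:
        cr_removed = max(influent["CrVI"] - means.get("CrVI", 0.0), 0.0)
    elif "CrVI" in means:
        cr_removed = means["CrVI"]
    rates["CrVI"] = cr_rate(cr_removed, config, catalog, window=win, n_samples=n).rate
    rates["CH4"] = ch4_rate(means.get("CH4", 0.0), config, catalog, window=win, n_samples=n).rate

    current = sub.mean_current()
    if current is not None and current > 0:
        ce_raw = {p: coulombic_efficiency(r, current, config) for p, r in rates.items()}
        ce_q = {p: _quantize(v, ce_decimals) for p, v in ce_raw.items()}
        excess = ce_excess(ce_q)
    else:
        ce_raw = ce_q = excess = None

    removal: dict[str, float] = {}
    for contaminant, feed in (influent or {}).items():
        removal[contaminant] = removal_efficiency(
            feed, means.get(contaminant, 0.0),
            allow_negative_removal=allow_negative_removal,
        )

    return EfficiencyReport(
        rates=rates,
        ce=ce_q,
        ce_excess=excess,
        ce_raw=ce_raw,
        mean_current=current,
        removal_efficiency=removal,
        window=win,
        n_samples=n,
        ce_decimals=ce_decimals,
    )
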