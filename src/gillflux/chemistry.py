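"""Compound properties, Henderson-Hasselbalch speciation and unit conversions.

Everything downstream (the kinetic simulator, the permeability estimators,
the dose-response fits) works on molar amounts of ionizable pharmaceuticals
measured by beta counting, so this module owns three things:

* :class:`CompoundRecord` -- the physicochemical and radiolabel properties of
  one drug (molecular weight, acid/base pKa sites, log Kow, specific
  activity of the tritiated or 14C label);
* Henderson-Hasselbalch speciation: the ionized / neutral fractions of a
  weak acid or base at a given pH, and the pH-corrected partition
  coefficient log Dow = log Kow + log10(f_neutral);
* conversions between mass concentration (ug/L), molar concentration (nM),
  counted radioactivity (dpm) and molar amount (pmol), using
  1 Ci = 2.22e12 dpm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, NamedTuple, Optional

import pandas as pd

__all__ = [
    "DPM_PER_CI",
    "PkaSite",
    "CompoundRecord",
    "SpeciationResult",
    "ionized_fraction",
    "neutral_fraction",
    "percent_ionized",
    "log_dow_at_ph",
    "mass_conc_to_molar",
    "molar_to_mass_conc",
    "dpm_to_amount",
    "amount_to_dpm",
    "speciate",
    "load_compound_table",
]

#: Disintegrations per minute in one Curie.
DPM_PER_CI = 2.22e12

PkaKind = Literal["acid", "base"]


class PkaSite(NamedTuple):
    """One ionizable site: a pKa value and whether it is acidic or basic."""

    value: float
    kind: PkaKind


def _check_kind(kind: str) -> str:
    if kind not in ("acid", "base"):
        raise ValueError(f"pKa kind must be 'acid' or 'base', got {kind!r}")
    return kind


def ionized_fraction(pka: float, ph: float, kind: PkaKind) -> float:
    """Fraction of a single-site acid or base carrying charge at ``ph``.

    For a base the protonated (cationic) fraction is ``1/(1 + 10**(ph - pka))``;
    for an acid the deprotonated (anionic) fraction is ``1/(1 + 10**(pka - ph))``.
    """
    _check_kind(kind)
    if not (math.isfinite(pka) and math.isfinite(ph)):
        raise ValueError("pka and ph must be finite")
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def neutral_fraction(pka: float, ph: float, kind: PkaKind) -> float:
    """Uncharged fraction of a single ionizable site at ``ph``."""
    _check_kind(kind)
    # complement computed in closed form to avoid cancellation at extreme pH
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def percent_ionized(pka: float, ph: float, kind: PkaKind) -> int:
    """Ionized fraction as an integer percent, rounded half-up."""
    return int(math.floor(100.0 * ionized_fraction(pka, ph, kind) + 0.5))


def log_dow_at_ph(log_kow: float, pka: float, ph: float, kind: PkaKind) -> float:
    """pH-corrected octanol-water partition coefficient of a monoprotic compound.

    Assumes only the neutral species partitions into octanol:
    ``log Dow = log Kow + log10(f_neutral(ph))``, hence always <= log Kow.
    """
    return log_kow + math.log10(neutral_fraction(pka, ph, kind))


def mass_conc_to_molar(conc_ug_per_l: float, mw: float) -> float:
    """ug/L -> nmol/L. E.g. 1 ug/L propranolol (MW 259.34) = 3.86 nM."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_ug_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ug_per_l / mw * 1000.0


def molar_to_mass_conc(conc_nm: float, mw: float) -> float:
    """nmol/L -> ug/L (inverse of :func:`mass_conc_to_molar`)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return conc_nm * mw / 1000.0


def dpm_to_amount(dpm: float, specific_activity: float) -> float:
    """Counted dpm -> pmol, given the label's specific activity in Ci/mmol.

    1 Ci/mmol corresponds to 2.22e12 dpm/mmol = 2220 dpm/pmol.
    """
    if specific_activity <= 0:
        raise ValueError("specific activity must be positive")
    if dpm < 0:
        raise ValueError("dpm must be non-negative")
    return dpm / (DPM_PER_CI * 1e-9 * specific_activity)


def amount_to_dpm(pmol: float, specific_activity: float) -> float:
    """pmol -> dpm (exact inverse of :func:`dpm_to_amount`)."""
    if specific_activity <= 0:
        raise ValueError("specific activity must be positive")
    return pmol * (DPM_PER_CI * 1e-9 * specific_activity)


@dataclass(frozen=True)
class CompoundRecord:
    """Physicochemical and radiolabel properties of one test compound.

    Parameters
    ----------
    name : str
    molecular_weight : float, g/mol
    pka_values : tuple of PkaSite
        One entry per ionizable site; multiprotic compounds (formoterol,
        terbutaline) list both their acidic and basic sites.
    log_kow : float
        Octanol-water partition coefficient of the neutral species.
    specific_activity : float, Ci/mmol
        Specific radioactivity of the labelled stock.
    environmental_level : float or None, ng/L
        Reported surface-water level (informational).
    log_kow_ph_adjusted : float or None
        Externally reported pH-adjusted log Kow, stored verbatim; kept
        separate from the computed :func:`log_dow_at_ph`.
    """

    name: str
    molecular_weight: float
    pka_values: tuple[PkaSite, ...]
    log_kow: float
    specific_activity: float
    environmental_level: Optional[float] = None
    log_kow_ph_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.specific_activity <= 0:
            raise ValueError("specific_activity must be positive")
        if not self.pka_values:
            raise ValueError("at least one pKa site is required")
        for site in self.pka_values:
            if not (0.0 < site.value < 14.0):
                raise ValueError(f"pKa {site.value} outside (0, 14)")
            _check_kind(site.kind)

    @property
    def is_base(self) -> bool:
        """True when every ionizable site is basic (a pure cation-former)."""
        return all(s.kind == "base" for s in self.pka_values)

    def neutral_fraction(self, ph: float) -> float:
        """Fully-neutral fraction at ``ph``.

        Sites are treated as independent, so the neutral fraction is the
        product of the per-site neutral fractions (a standard
        microspeciation-free approximation for multiprotic compounds).
        """
        f = 1.0
        for site in self.pka_values:
            f *= neutral_fraction(site.value, ph, site.kind)
        return f

    def ionized_fraction(self, ph: float) -> float:
        """Fraction carrying at least one charge at ``ph``."""
        return 1.0 - self.neutral_fraction(ph)


@dataclass(frozen=True)
class SpeciationResult:
    """Speciation of one compound at one pH."""

    ph: float
    ionized_fraction: float
    neutral_fraction: float
    log_dow: float


def speciate(compound: CompoundRecord, ph: float) -> SpeciationResult:
    """Full speciation summary of ``compound`` at ``ph``."""
    fn = compound.neutral_fraction(ph)
    return SpeciationResult(
        ph=ph,
        ionized_fraction=1.0 - fn,
        neutral_fraction=fn,
        log_dow=compound.log_kow + math.log10(fn),
    )


def _parse_sites(pka: str, kinds: str) -> tuple[PkaSite, ...]:
    values = [float(v) for v in str(pka).split(";")]
    kind_list = [k.strip() for k in str(kinds).split(";")]
    if len(values) != len(kind_list):
        raise ValueError("pka and pka_kind must list the same number of sites")
    return tuple(PkaSite(v, _check_kind(k)) for v, k in zip(values, kind_list))


def load_compound_table(path: Optional[str] = None) -> dict[str, CompoundRecord]:
    """Load a compound property CSV into a name-keyed dict of records.

    Columns: ``name, mw_g_per_mol, pka, pka_kind, log_kow,
    specific_activity_ci_per_mmol`` plus optional ``log_kow_ph_adjusted`` and
    ``environmental_ng_per_L``. Multi-site pKa entries are
    semicolon-separated. With no ``path`` the packaged table of the seven
    assayed pharmaceuticals plus the mannitol tracer is used.
    """
    if path is None:
        source = resources.files("gillflux.data").joinpath("compounds.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out: dict[str, CompoundRecord] = {}
    for row in df.itertuples(index=False):
        rec = CompoundRecord(
            name=row.name,
            molecular_weight=float(row.mw_g_per_mol),
            pka_values=_parse_sites(row.pka, row.pka_kind),
            log_kow=float(row.log_kow),
            specific_activity=float(row.specific_activity_ci_per_mmol),
            environmental_level=(
                float(row.environmental_ng_per_L)
                if "environmental_ng_per_L" in df.columns
                and pd.notna(row.environmental_ng_per_L)
                else None
            ),
            log_kow_ph_adjusted=(
                float(row.log_kow_ph_adjusted)
                if "log_kow_ph_adjusted" in df.columns
                and pd.notna(row.log_kow_ph_adjusted)
                else None
            ),
        )
        out[rec.name] = rec
    return out
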