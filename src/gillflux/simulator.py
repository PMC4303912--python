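"""Two-compartment kinetic simulator of the cultured gill epithelium.

The physical system is a Transwell insert: an apical compartment (default
1.5 mL of culture medium or freshwater) and a basal compartment (default
2.0 mL of L-15 medium) separated by a 0.9 cm^2 double-seeded primary gill
cell epithelium. Drug moves between the compartments through four parallel
pathways, all expressed as signed fluxes (pmol/s, apical->basal positive):

* passive transcellular diffusion of the neutral species, driven by the
  difference of neutral-species concentrations on the two sides
  (pH-partition / ion-trapping behaviour falls out of this term);
* a paracellular leak whose permeability is anchored to the measured
  mannitol-vs-TER relationship (leaky at 0 resistance, ~0.1e-6 cm/s once
  the epithelium is electrically tight);
* a saturable (Michaelis-Menten) uptake carrier on the apical side and a
  saturable efflux carrier on the basal side;
* a multiplicative bias on the passive term for cationic (basic) drugs when
  the apical medium is freshwater, standing in for the basolateral-negative
  transepithelial potential that favours cation entry.

The simulator integrates amounts between sampling times, withdraws a 100 uL
aliquot from each compartment at every sampling time (the aliquot is
counted, not returned: mass leaves the system and the compartment volume
shrinks), and emits one :class:`SamplingRecord` row per compartment per
time with the counted dpm, optionally perturbed by pipetting and Poisson
counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import CompoundRecord, amount_to_dpm, dpm_to_amount, mass_conc_to_molar

__all__ = [
    "InsertConfig",
    "CarrierKinetics",
    "TransportParams",
    "InhibitorDose",
    "AssayDesign",
    "NoiseModel",
    "SimulationResult",
    "paracellular_permeability",
    "flux_terms",
    "simulate",
    "RECORD_COLUMNS",
]

#: Columns of the SamplingRecord table emitted by :func:`simulate`.
RECORD_COLUMNS = [
    "insert_id",
    "replicate_id",
    "scenario",
    "drug",
    "condition",
    "mode",
    "donor_side",
    "compartment",
    "time_h",
    "aliquot_volume_ml",
    "dpm",
    "ter_kohm_cm2",
    "apical_ph",
    "inhibitor",
    "inhibitor_side",
]

_MEDIUM_PH = {"L15": 7.4, "freshwater": 7.7}


@dataclass
class InsertConfig:
    """Geometry, media and electrical state of one cultured insert.

    ``apical_ph`` defaults from the medium (L-15 at 7.4; the artificial
    freshwater recipe sits at 7.7 and may be titrated to 6.0/8.0/9.5 for the
    pH series). ``tep`` (mV) is informational only; its kinetic effect is
    carried by :attr:`TransportParams.asym_bias`.
    """

    insert_id: str = "insert-1"
    apical_volume: float = 1.5  # mL
    basal_volume: float = 2.0  # mL
    area: float = 0.9  # cm^2
    apical_medium: Literal["L15", "freshwater"] = "L15"
    apical_ph: Optional[float] = None
    basal_ph: float = 7.4
    ter: float = 18.1  # kOhm cm^2
    tep: Optional[float] = None  # mV

    def __post_init__(self) -> None:
        if self.apical_volume <= 0 or self.basal_volume <= 0:
            raise ValueError("compartment volumes must be positive")
        if self.area <= 0:
            raise ValueError("membrane area must be positive")
        if self.ter < 0:
            raise ValueError("TER must be non-negative")
        if self.apical_medium not in _MEDIUM_PH:
            raise ValueError(f"unknown apical medium {self.apical_medium!r}")
        if self.apical_ph is None:
            self.apical_ph = _MEDIUM_PH[self.apical_medium]

    @property
    def condition(self) -> str:
        return "asymmetric" if self.apical_medium == "freshwater" else "symmetric"


@dataclass(frozen=True)
class CarrierKinetics:
    """Michaelis-Menten kinetics of one membrane carrier."""

    jmax: float  # pmol cm^-2 s^-1
    km: float  # nmol/L

    def __post_init__(self) -> None:
        if self.jmax < 0:
            raise ValueError("jmax must be non-negative")
        if self.km <= 0:
            raise ValueError("km must be positive")


@dataclass
class TransportParams:
    """Kinetic parameters of one compound on one epithelium.

    ``inhibitor_sensitivity`` maps an inhibitor name to the targeted carrier
    ("uptake" or "efflux") and the fraction of that carrier's jmax remaining
    when the inhibitor is present (side-independent: apical and basal
    application inhibit equally).
    """

    p_trans: float = 0.0  # cm/s, neutral-species transcellular permeability
    carrier_uptake: Optional[CarrierKinetics] = None  # apical -> basal
    carrier_efflux: Optional[CarrierKinetics] = None  # basal -> apical
    asym_bias: float = 1.0  # >= 1, cation passive enhancement under apical FW
    paracellular_scale: float = 1.0  # 0 disables the TER-anchored leak
    inhibitor_sensitivity: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_trans < 0:
            raise ValueError("p_trans must be non-negative")
        if self.paracellular_scale < 0:
            raise ValueError("paracellular_scale must be non-negative")
        if self.asym_bias < 1.0:
            raise ValueError("asym_bias must be >= 1")
        for name, (target, frac) in self.inhibitor_sensitivity.items():
            if target not in ("uptake", "efflux"):
                raise ValueError(f"unknown carrier target {target!r} for {name}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction_remaining must be in [0, 1]")


@dataclass(frozen=True)
class InhibitorDose:
    """One inhibitor application (name, side it is applied to, nM)."""

    name: str
    side: Literal["apical", "basal"] = "apical"
    concentration: float = 400.0  # nmol/L


@dataclass
class AssayDesign:
    """One assay layout: what is dosed where and when samples are drawn."""

    mode: Literal["BTA", "CETA", "mannitol"] = "BTA"
    donor_side: Literal["apical", "basal"] = "apical"
    dose_concentration: float = 1.0  # ug/L
    dose_dpm: Optional[float] = None  # mannitol dosing is by radioactivity
    sampling_times: tuple[float, ...] = (0.0, 6.0, 24.0, 30.0, 48.0)
    aliquot_volume: float = 0.1  # mL
    inhibitor: Optional[InhibitorDose] = None
    n_inserts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sampling_times)
        if len(times) < 2 or times[0] != 0.0:
            raise ValueError("sampling times must start at 0 and have >= 2 points")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        self.sampling_times = times
        if self.mode not in ("BTA", "CETA", "mannitol"):
            raise ValueError(f"unknown assay mode {self.mode!r}")
        if self.aliquot_volume <= 0:
            raise ValueError("aliquot volume must be positive")


@dataclass
class NoiseModel:
    """Measurement noise: lognormal pipetting error and Poisson counting."""

    pipetting_cv: float = 0.05
    counting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pipetting_cv < 0:
            raise ValueError("pipetting CV must be non-negative")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(pipetting_cv=0.0, counting=False)

    @property
    def enabled(self) -> bool:
        return self.pipetting_cv > 0 or self.counting

    def perturb_dpm(self, dpm: float, rng: np.random.Generator) -> float:
        out = dpm
        if self.pipetting_cv > 0:
            sigma = math.sqrt(math.log1p(self.pipetting_cv**2))
            out *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        if self.counting:
            out = float(rng.poisson(out))
        return out


# Printed mannitol-permeability tiers versus TER (kOhm cm^2 -> cm/s):
# cell-free inserts at 0, intermediate epithelia on [0.2, 1.0], tight >= 2.
_PARA_ANCHORS = ((0.0, 3.6e-6), (0.2, 1.1e-6), (1.0, 1.1e-6), (2.0, 0.1e-6))


def paracellular_permeability(ter: float) -> float:
    """Paracellular (mannitol-scale) permeability in cm/s for a given TER.

    Monotone non-increasing, anchored at the measured tiers and log-linearly
    interpolated (linear in TER, linear in log permeability) between them.
    """
    if ter < 0:
        raise ValueError("TER must be non-negative")
    anchors = _PARA_ANCHORS
    if ter >= anchors[-1][0]:
        return anchors[-1][1]
    for (t0, p0), (t1, p1) in zip(anchors, anchors[1:]):
        if t0 <= ter <= t1:
            if p0 == p1 or ter == t0:
                return p0
            if ter == t1:
                return p1
            w = (ter - t0) / (t1 - t0)
            return 10.0 ** ((1 - w) * math.log10(p0) + w * math.log10(p1))
    raise AssertionError("unreachable")


def _effective_carriers(
    params: TransportParams, inhibitor: Optional[InhibitorDose]
) -> tuple[Optional[CarrierKinetics], Optional[CarrierKinetics]]:
    up, eff = params.carrier_uptake, params.carrier_efflux
    if inhibitor is not None and inhibitor.name in params.inhibitor_sensitivity:
        target, frac = params.inhibitor_sensitivity[inhibitor.name]
        if target == "uptake" and up is not None:
            up = CarrierKinetics(up.jmax * frac, up.km) if frac > 0 else None
        elif target == "efflux" and eff is not None:
            eff = CarrierKinetics(eff.jmax * frac, eff.km) if frac > 0 else None
    return up, eff


def flux_terms(
    c_apical: float,
    c_basal: float,
    insert: InsertConfig,
    params: TransportParams,
    compound: CompoundRecord,
    inhibitor: Optional[InhibitorDose] = None,
) -> dict[str, float]:
    """Per-pathway fluxes (pmol/s, apical->basal positive) at given state.

    Concentrations are total molar concentrations in pmol/mL (== nmol/L).
    The passive term moves the neutral species only; the TEP bias multiplies
    it when the apical medium is freshwater and the compound is a base.
    """
    if c_apical < 0 or c_basal < 0:
        raise ValueError("concentrations must be non-negative")
    area = insert.area
    fn_a = compound.neutral_fraction(insert.apical_ph)
    fn_b = compound.neutral_fraction(insert.basal_ph)
    bias = (
        params.asym_bias
        if insert.apical_medium == "freshwater" and compound.is_base
        else 1.0
    )
    j_passive = params.p_trans * area * bias * (fn_a * c_apical - fn_b * c_basal)
    j_para = (
        params.paracellular_scale
        * paracellular_permeability(insert.ter)
        * area
        * (c_apical - c_basal)
    )
    up, eff = _effective_carriers(params, inhibitor)
    j_uptake = up.jmax * area * c_apical / (up.km + c_apical) if up else 0.0
    j_efflux = -eff.jmax * area * c_basal / (eff.km + c_basal) if eff else 0.0
    return {
        "passive": j_passive,
        "paracellular": j_para,
        "uptake": j_uptake,
        "efflux": j_efflux,
        "net": j_passive + j_para + j_uptake + j_efflux,
    }


@dataclass
class SimulationResult:
    """Trajectories, emitted sampling records and the mass ledger of one run."""

    insert: InsertConfig
    design: AssayDesign
    compound: CompoundRecord
    times: np.ndarray  # sampling times, h
    apical_conc: np.ndarray  # pmol/mL at sampling times, before aliquot removal
    basal_conc: np.ndarray
    apical_volume: np.ndarray  # mL, before aliquot removal at each time
    basal_volume: np.ndarray
    removed_apical: np.ndarray  # cumulative pmol withdrawn by sampling
    removed_basal: np.ndarray
    dosed_amount: float  # pmol
    records: pd.DataFrame = field(repr=False, default=None)
    cell_associated: float = 0.0

    def mass_balance_error(self) -> float:
        """Max relative deviation of (in-system + removed) from the dose."""
        in_system = (
            self.apical_conc * self.apical_volume
            + self.basal_conc * self.basal_volume
        )
        # removed ledgers are cumulative *after* sampling at each time; at the
        # pre-removal instant only strictly earlier withdrawals have occurred
        prior_a = np.concatenate(([0.0], self.removed_apical[:-1]))
        prior_b = np.concatenate(([0.0], self.removed_basal[:-1]))
        total = in_system + prior_a + prior_b + self.cell_associated
        return float(np.max(np.abs(total - self.dosed_amount)) / self.dosed_amount)


def _initial_amounts(
    design: AssayDesign, insert: InsertConfig, compound: CompoundRecord
) -> tuple[float, float]:
    """Dosed amounts (pmol) in (apical, basal) at t=0."""
    if design.mode == "mannitol":
        dpm = design.dose_dpm if design.dose_dpm is not None else 2.2e5
        return dpm_to_amount(dpm, compound.specific_activity), 0.0
    c0 = mass_conc_to_molar(design.dose_concentration, compound.molecular_weight)
    n_ap = c0 * insert.apical_volume
    n_bl = c0 * insert.basal_volume
    if design.mode == "CETA":
        return n_ap, n_bl
    if design.donor_side == "apical":
        return n_ap, 0.0
    return 0.0, n_bl


def simulate(
    insert: InsertConfig,
    params: TransportParams,
    design: AssayDesign,
    compound: CompoundRecord,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    scenario: str = "",
    replicate_id: str = "",
) -> SimulationResult:
    """Run one insert through one assay design.

    Integrates the compartment amounts with an adaptive ODE solver between
    sampling times (rtol 1e-9, atol 1e-12 on the pmol scale), withdraws the
    aliquots at each sampling time, and emits one record per compartment per
    time. With ``noise`` off (or None) the result is deterministic.
    """
    if noise is None:
        noise = NoiseModel.off()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    if design.aliquot_volume >= min(insert.apical_volume, insert.basal_volume):
        raise ValueError("aliquot volume must be smaller than both compartments")

    n_a, n_b = _initial_amounts(design, insert, compound)
    dosed = n_a + n_b
    v_a, v_b = insert.apical_volume, insert.basal_volume
    times = np.asarray(design.sampling_times, dtype=float)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        j = flux_terms(
            max(y[0], 0.0) / v_a,
            max(y[1], 0.0) / v_b,
            insert,
            params,
            compound,
            design.inhibitor,
        )["net"]
        return [-j, j]

    conc_a = np.empty_like(times)
    conc_b = np.empty_like(times)
    vol_a = np.empty_like(times)
    vol_b = np.empty_like(times)
    rem_a = np.empty_like(times)
    rem_b = np.empty_like(times)
    removed_a = removed_b = 0.0
    rows: list[dict] = []

    for k, t in enumerate(times):
        if k > 0:
            t0, t1 = times[k - 1] * 3600.0, t * 3600.0
            if np.allclose([n_a, n_b], 0.0) or (
                params.p_trans == 0.0
                and params.carrier_uptake is None
                and params.carrier_efflux is None
                and params.paracellular_scale == 0.0
            ):
                pass  # nothing moves; skip the integrator
            else:
                sol = solve_ivp(
                    rhs,
                    (t0, t1),
                    [n_a, n_b],
                    method="LSODA",
                    rtol=1e-9,
                    atol=1e-12,
                )
                if not sol.success:
                    raise RuntimeError(
                        f"integration failed on [{t0 / 3600}, {t1 / 3600}] h: "
                        f"{sol.message}"
                    )
                n_a, n_b = float(sol.y[0, -1]), float(sol.y[1, -1])
        if n_a < -1e-9 * dosed or n_b < -1e-9 * dosed:
            raise RuntimeError("negative compartment amount: invariant breach")
        n_a, n_b = max(n_a, 0.0), max(n_b, 0.0)

        c_a, c_b = n_a / v_a, n_b / v_b
        conc_a[k], conc_b[k] = c_a, c_b
        vol_a[k], vol_b[k] = v_a, v_b

        for compartment, conc in (("apical", c_a), ("basal", c_b)):
            aliquot_amount = conc * design.aliquot_volume
            dpm = amount_to_dpm(aliquot_amount, compound.specific_activity)
            if noise.enabled:
                dpm = noise.perturb_dpm(dpm, rng)
            rows.append(
                {
                    "insert_id": insert.insert_id,
                    "replicate_id": replicate_id or insert.insert_id,
                    "scenario": scenario,
                    "drug": compound.name,
                    "condition": insert.condition,
                    "mode": design.mode,
                    "donor_side": design.donor_side if design.mode == "BTA" else "",
                    "compartment": compartment,
                    "time_h": t,
                    "aliquot_volume_ml": design.aliquot_volume,
                    "dpm": dpm,
                    "ter_kohm_cm2": insert.ter,
                    "apical_ph": insert.apical_ph,
                    "inhibitor": design.inhibitor.name if design.inhibitor else "",
                    "inhibitor_side": design.inhibitor.side if design.inhibitor else "",
                }
            )

        # withdraw the counted aliquots: mass leaves, volumes shrink
        take_a = c_a * design.aliquot_volume
        take_b = c_b * design.aliquot_volume
        n_a -= take_a
        n_b -= take_b
        removed_a += take_a
        removed_b += take_b
        v_a -= design.aliquot_volume
        v_b -= design.aliquot_volume
        rem_a[k], rem_b[k] = removed_a, removed_b

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return SimulationResult(
        insert=insert,
        design=design,
        compound=compound,
        times=times,
        apical_conc=conc_a,
        basal_conc=conc_b,
        apical_volume=vol_a,
        basal_volume=vol_b,
        removed_apical=rem_a,
        removed_basal=rem_b,
        dosed_amount=dosed,
        records=records,
    )
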