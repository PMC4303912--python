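"""Permeability estimators, transport-ratio classification and hypothesis tests.

Implements the analysis side of the transwell assays:

* the TER quality gate (inserts below 5 kOhm cm^2 are discarded before any
  permeability is computed);
* the mannitol paracellular permeability, P = dM_BL * V_donor /
  (M_AP * t * 3600 * A), from a start/end pair of counts;
* the apparent permeability coefficient Papp = (dQ/dt) / (A * C0) / 3600
  from the 0 -> 6 h receiver gain of a bidirectional assay (the two
  formulas are the same estimator in different units);
* the uptake/efflux transport ratios TR = Papp(A:B)/Papp(B:A) and its
  reciprocal, with TR >= 1.5 flagged as evidence of active transport;
* percent-of-initial time courses for BTA and CETA assays, the
  percent-of-control readout of the inhibitor series, and the pooled t-test
  / log-ANOVA used for group comparisons.

Receiver amounts are corrected by default for the aliquots previously
withdrawn from the receiver compartment (they carried drug out of the
system); an uncorrected mode is kept for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import CompoundRecord, dpm_to_amount

__all__ = [
    "AnalysisConfig",
    "MannitolAssayRecord",
    "PappResult",
    "TRResult",
    "ter_gate",
    "mannitol_permeability",
    "papp_6h",
    "transport_ratio",
    "percent_of_donor",
    "ceta_percent_initial",
    "inhibition_percent_of_control",
    "ttest_equal_var",
    "anova_log",
]


@dataclass
class AnalysisConfig:
    """Thresholds and options shared across the analysis pipeline."""

    ter_threshold: float = 5.0  # kOhm cm^2, inserts at/above are retained
    tr_threshold: float = 1.5  # TR at/above flags active transport
    papp_time: float = 6.0  # h, end of the Papp window
    alpha: float = 0.05
    log_transform_anova: bool = True
    aliquot_correction: bool = True
    apical_volume: float = 1.5  # mL, initial
    basal_volume: float = 2.0  # mL, initial

    def __post_init__(self) -> None:
        if self.ter_threshold <= 0 or self.tr_threshold <= 0 or self.papp_time <= 0:
            raise ValueError("thresholds must be positive")


def ter_gate(
    inserts: Iterable[tuple[str, float]], config: Optional[AnalysisConfig] = None
) -> list[str]:
    """Return ids of inserts whose TER meets the threshold (ties retained).

    Order-preserving and idempotent; an empty input yields an empty list.
    """
    config = config or AnalysisConfig()
    retained = []
    for insert_id, ter in inserts:
        if ter < 0:
            raise ValueError(f"negative TER for insert {insert_id!r}")
        if ter >= config.ter_threshold:
            retained.append(insert_id)
    return retained


@dataclass(frozen=True)
class MannitolAssayRecord:
    """Start/end counts of one mannitol flux measurement.

    ``delta_m_bl`` is the gain in basal-compartment radioactivity over the
    assay, ``m_ap`` the initial apical (donor) radioactivity; the volume is
    the donor volume, making the formula dimensionally identical to the
    Papp estimator with C0 = M_AP / V_donor.
    """

    delta_m_bl: float  # dpm
    m_ap: float  # dpm
    donor_volume: float = 1.5  # mL
    duration: float = 24.0  # h
    area: float = 0.9  # cm^2

    def __post_init__(self) -> None:
        if self.m_ap <= 0:
            raise ValueError("initial apical radioactivity must be positive")
        if self.duration <= 0 or self.area <= 0 or self.donor_volume <= 0:
            raise ValueError("duration, area and volume must be positive")


def mannitol_permeability(rec: MannitolAssayRecord) -> float:
    """Paracellular tracer permeability in cm/s."""
    return rec.delta_m_bl * rec.donor_volume / (
        rec.m_ap * rec.duration * 3600.0 * rec.area
    )


@dataclass(frozen=True)
class PappResult:
    """Directional apparent permeability of one insert."""

    insert_id: str
    direction: str  # "A:B" or "B:A"
    papp: float  # cm/s
    dq_dt: float  # pmol/h, receiver amount gain rate over the Papp window
    c0: float  # nmol/L, initial donor concentration
    area: float  # cm^2


def _concentrations(
    records: pd.DataFrame, compound: CompoundRecord
) -> pd.DataFrame:
    """Per-record molar concentration (pmol/mL) from counted dpm."""
    out = records.copy()
    amounts = out["dpm"].map(lambda d: dpm_to_amount(d, compound.specific_activity))
    out["conc"] = amounts / out["aliquot_volume_ml"]
    return out


def _receiver_amount(
    rows: pd.DataFrame,
    time: float,
    v0: float,
    aliquot: float,
    corrected: bool,
) -> float:
    """Total receiver-side amount (pmol) at ``time``, pre-aliquot.

    The compartment holds C(t) * V(t) where V(t) = V0 - aliquot * (number of
    earlier samplings); with correction on, amounts carried out by earlier
    aliquots are added back so Q(t) is the cumulative transported amount.
    """
    times = np.sort(rows["time_h"].unique())
    k = int(np.searchsorted(times, time))
    conc_t = float(rows.loc[rows["time_h"] == time, "conc"].iloc[0])
    q = conc_t * (v0 - aliquot * k)
    if corrected:
        for earlier in times[:k]:
            q += float(rows.loc[rows["time_h"] == earlier, "conc"].iloc[0]) * aliquot
    return q


def papp_6h(
    records: pd.DataFrame,
    compound: CompoundRecord,
    config: Optional[AnalysisConfig] = None,
    area: float = 0.9,
) -> PappResult:
    """Apparent permeability of one insert from its sampling records.

    ``records`` must contain, for a single insert, the donor sample at t=0
    and receiver samples at t=0 and t=``config.papp_time``. The direction is
    taken from the ``donor_side`` column. Negative dQ/dt is reported as-is.
    """
    config = config or AnalysisConfig()
    if records["insert_id"].nunique() != 1:
        raise ValueError("papp_6h expects records from exactly one insert")
    donor_side = records["donor_side"].iloc[0]
    if donor_side not in ("apical", "basal"):
        raise ValueError("records lack a BTA donor_side")
    receiver_side = "basal" if donor_side == "apical" else "apical"
    direction = "A:B" if donor_side == "apical" else "B:A"

    df = _concentrations(records, compound)
    donor = df[df["compartment"] == donor_side]
    receiver = df[df["compartment"] == receiver_side]
    if donor[donor["time_h"] == 0.0].empty:
        raise ValueError("missing donor sample at t=0")
    for t in (0.0, config.papp_time):
        if receiver[receiver["time_h"] == t].empty:
            raise ValueError(f"missing receiver sample at t={t:g} h")

    c0 = float(donor.loc[donor["time_h"] == 0.0, "conc"].iloc[0])
    if c0 <= 0:
        raise ValueError("initial donor concentration is zero")
    v0 = {"apical": config.apical_volume, "basal": config.basal_volume}[receiver_side]
    aliquot = float(records["aliquot_volume_ml"].iloc[0])
    q0 = _receiver_amount(receiver, 0.0, v0, aliquot, config.aliquot_correction)
    q6 = _receiver_amount(
        receiver, config.papp_time, v0, aliquot, config.aliquot_correction
    )
    dq_dt = (q6 - q0) / config.papp_time  # pmol/h
    papp = dq_dt / (area * c0) / 3600.0  # cm/s
    return PappResult(
        insert_id=str(records["insert_id"].iloc[0]),
        direction=direction,
        papp=papp,
        dq_dt=dq_dt,
        c0=c0,
        area=area,
    )


@dataclass(frozen=True)
class TRResult:
    """Uptake/efflux transport ratios and the active-transport flags."""

    uptake_tr: float
    efflux_tr: float
    active_uptake: bool
    active_efflux: bool
    threshold: float = 1.5


def transport_ratio(
    papp_ab: float, papp_ba: float, config: Optional[AnalysisConfig] = None
) -> TRResult:
    """Directional transport ratios from a Papp pair (TR >= 1.5 flags active)."""
    config = config or AnalysisConfig()
    if papp_ab <= 0 or papp_ba <= 0:
        raise ValueError("transport ratios require positive Papp values")
    uptake = papp_ab / papp_ba
    efflux = papp_ba / papp_ab
    return TRResult(
        uptake_tr=uptake,
        efflux_tr=efflux,
        active_uptake=uptake >= config.tr_threshold,
        active_efflux=efflux >= config.tr_threshold,
        threshold=config.tr_threshold,
    )


def percent_of_donor(
    records: pd.DataFrame, compound: CompoundRecord
) -> pd.DataFrame:
    """BTA time course: concentration as % of the t=0 donor concentration.

    Returns a tidy frame (compartment, time_h, percent) for one insert.
    """
    donor_side = records["donor_side"].iloc[0]
    if donor_side not in ("apical", "basal"):
        raise ValueError("records lack a BTA donor_side")
    df = _concentrations(records, compound)
    d0 = df[(df["compartment"] == donor_side) & (df["time_h"] == 0.0)]
    if d0.empty:
        raise ValueError("missing donor sample at t=0")
    c_donor0 = float(d0["conc"].iloc[0])
    if c_donor0 <= 0:
        raise ValueError("initial donor concentration is zero")
    out = df[["compartment", "time_h"]].copy()
    out["percent"] = 100.0 * df["conc"] / c_donor0
    return out.sort_values(["compartment", "time_h"]).reset_index(drop=True)


def ceta_percent_initial(
    records: pd.DataFrame, compound: CompoundRecord
) -> pd.DataFrame:
    """CETA time course: each compartment as % of its own t=0 concentration."""
    df = _concentrations(records, compound)
    frames = []
    for compartment, rows in df.groupby("compartment"):
        r0 = rows[rows["time_h"] == 0.0]
        if r0.empty:
            raise ValueError(f"missing t=0 sample in {compartment} compartment")
        c0 = float(r0["conc"].iloc[0])
        if c0 <= 0:
            raise ValueError(f"zero initial concentration in {compartment}")
        part = rows[["compartment", "time_h"]].copy()
        part["percent"] = 100.0 * rows["conc"] / c0
        frames.append(part)
    return (
        pd.concat(frames)
        .sort_values(["compartment", "time_h"])
        .reset_index(drop=True)
    )


def inhibition_percent_of_control(
    papp_treated: Sequence[float], papp_controls: Sequence[float]
) -> np.ndarray:
    """Treated Papp values as percent of the mean inhibitor-free control."""
    controls = np.asarray(papp_controls, dtype=float)
    if controls.size == 0:
        raise ValueError("at least one control insert is required")
    mean_control = controls.mean()
    if mean_control <= 0:
        raise ValueError("mean control permeability must be positive")
    return 100.0 * np.asarray(papp_treated, dtype=float) / mean_control


def ttest_equal_var(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sided pooled-variance (equal variances assumed) t-test.

    Returns (t, df, p). Two identical constant groups give t=0, p=1 by
    convention; constant groups with different means are degenerate.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    df = a.size + b.size - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero variance with unequal means: t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def anova_log(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA on natural-log-transformed values.

    Returns (F, df_between, df_within, p). All observations must be
    positive; identical groups give F=0, p=1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    logged = []
    for i, g in enumerate(groups):
        arr = np.asarray(g, dtype=float)
        if np.any(arr <= 0):
            raise ValueError(
                f"group {i} contains non-positive values; "
                "log-transformed ANOVA requires strictly positive data"
            )
        logged.append(np.log(arr))
    df1 = len(logged) - 1
    df2 = sum(len(g) for g in logged) - len(logged)
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*logged)
    if math.isnan(f):  # zero variance everywhere: no signal, F = 0 by convention
        return 0.0, df1, df2, 1.0
    return float(f), df1, df2, float(p)
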