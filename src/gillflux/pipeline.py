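"""End-to-end orchestration: simulate -> gate -> estimate -> classify -> fit.

The functions here are the programmatic counterparts of the CLI verbs:
:func:`run_simulate` writes a seeded SamplingRecord dataset,
:func:`run_analyze` turns a record table into per-insert permeabilities,
transport-ratio classifications, mannitol calibration and inhibition
percent-of-control tables, and :func:`run_report` renders the results as
plain-text summaries. :func:`run_reproduce` chains the full synthetic study
catalog through all of it and adds the plasma read-across comparison.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import catalog as _catalog
from .chemistry import CompoundRecord, load_compound_table, molar_to_mass_conc
from .doseresponse import (
    compare_in_vitro_plasma,
    fit_linear,
    fit_low_range,
    load_plasma_table,
)
from .metrics import (
    AnalysisConfig,
    MannitolAssayRecord,
    inhibition_percent_of_control,
    mannitol_permeability,
    papp_6h,
    ter_gate,
    transport_ratio,
)
from .simulator import NoiseModel

logger = logging.getLogger("gillflux")

__all__ = ["run_simulate", "run_analyze", "run_report", "run_reproduce"]


def run_simulate(
    scenarios: Optional[Sequence[_catalog.Scenario]] = None,
    seed: int = 0,
    noise: Optional[NoiseModel] = None,
    out: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Generate a SamplingRecord dataset (full study catalog by default)."""
    if scenarios is None:
        scenarios = _catalog.paper_catalog()
    records = _catalog.generate_dataset(scenarios, seed=seed, noise=noise)
    logger.info(
        "simulate: %d scenarios -> %d records (seed=%d)",
        len(scenarios),
        len(records),
        seed,
    )
    if out is not None:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        records.to_csv(out, index=False)
    return records


def _nominal_dose(c0_nm: float, compound: CompoundRecord) -> float:
    """Nominal dose in ug/L recovered from the t=0 donor concentration."""
    dose = molar_to_mass_conc(c0_nm, compound.molecular_weight)
    return float(f"{dose:.3g}")


def _papp_table(
    records: pd.DataFrame,
    compounds: dict[str, CompoundRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    rows = []
    bta = records[(records["mode"] == "BTA")]
    for (insert_id, scenario), grp in bta.groupby(["insert_id", "scenario"]):
        compound = compounds[grp["drug"].iloc[0]]
        res = papp_6h(grp, compound, config)
        rows.append(
            {
                "insert_id": insert_id,
                "scenario": scenario,
                "drug": compound.name,
                "condition": grp["condition"].iloc[0],
                "apical_ph": grp["apical_ph"].iloc[0],
                "inhibitor": grp["inhibitor"].iloc[0],
                "inhibitor_side": grp["inhibitor_side"].iloc[0],
                "direction": res.direction,
                "dose_ug_per_L": _nominal_dose(res.c0, compound),
                "papp_cm_s": res.papp,
                "dq_dt_pmol_h": res.dq_dt,
                "c0_nM": res.c0,
            }
        )
    return pd.DataFrame(rows)


def _tr_table(papp: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Mean-Papp transport ratios per matched uptake/efflux scenario pair.

    The two directions of one experiment share a scenario label up to an
    "uptake"/"efflux" tag; pairing on that key (plus drug, condition and
    apical pH) keeps concentration-series and control inserts, which have no
    matching opposite direction, out of the ratios.
    """
    rows = []
    clean = papp[papp["inhibitor"] == ""].copy()
    clean["pair_key"] = clean["scenario"].str.replace(
        r"(uptake|efflux)", "", regex=True
    )
    for (drug, condition, ph, _key), grp in clean.groupby(
        ["drug", "condition", "apical_ph", "pair_key"]
    ):
        ab = grp.loc[grp["direction"] == "A:B", "papp_cm_s"]
        ba = grp.loc[grp["direction"] == "B:A", "papp_cm_s"]
        if ab.empty or ba.empty:
            continue
        tr = transport_ratio(float(ab.mean()), float(ba.mean()), config)
        rows.append(
            {
                "drug": drug,
                "condition": condition,
                "apical_ph": ph,
                "dose_ug_per_L": float(grp["dose_ug_per_L"].mean()),
                "papp_ab_cm_s": float(ab.mean()),
                "papp_ba_cm_s": float(ba.mean()),
                "uptake_tr": tr.uptake_tr,
                "efflux_tr": tr.efflux_tr,
                "active_uptake": tr.active_uptake,
                "active_efflux": tr.active_efflux,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "condition",
            "apical_ph",
            "dose_ug_per_L",
            "papp_ab_cm_s",
            "papp_ba_cm_s",
            "uptake_tr",
            "efflux_tr",
            "active_uptake",
            "active_efflux",
        ],
    )


def _mannitol_table(
    records: pd.DataFrame,
    compounds: dict[str, CompoundRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    rows = []
    mann = records[records["mode"] == "mannitol"]
    for insert_id, grp in mann.groupby("insert_id"):
        aliquot = float(grp["aliquot_volume_ml"].iloc[0])
        times = np.sort(grp["time_h"].unique())
        t_end = float(times[-1])
        dpm_conc = (
            grp.set_index(["compartment", "time_h"])["dpm"] / aliquot
        )  # dpm per mL
        m_ap = float(dpm_conc.loc[("apical", 0.0)]) * config.apical_volume
        v_end = config.basal_volume - aliquot * (len(times) - 1)
        m_bl_end = float(dpm_conc.loc[("basal", t_end)]) * v_end
        removed = sum(
            float(dpm_conc.loc[("basal", t)]) * aliquot for t in times[:-1]
        )
        m_bl_0 = float(dpm_conc.loc[("basal", 0.0)]) * config.basal_volume
        rec = MannitolAssayRecord(
            delta_m_bl=m_bl_end + removed - m_bl_0,
            m_ap=m_ap,
            donor_volume=config.apical_volume,
            duration=t_end,
        )
        rows.append(
            {
                "insert_id": insert_id,
                "ter_kohm_cm2": float(grp["ter_kohm_cm2"].iloc[0]),
                "permeability_cm_s": mannitol_permeability(rec),
            }
        )
    return pd.DataFrame(
        rows, columns=["insert_id", "ter_kohm_cm2", "permeability_cm_s"]
    )


def _inhibition_table(
    records: pd.DataFrame,
    compounds: dict[str, CompoundRecord],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Uptake Papp under each inhibitor as % of the inhibitor-free control.

    The permeability window is widened to each sampling time in turn, so the
    table traces the inhibition time course.
    """
    bta = records[records["mode"] == "BTA"]
    treated = bta[bta["inhibitor"] != ""]
    if treated.empty:
        return pd.DataFrame(
            columns=["inhibitor", "inhibitor_side", "time_h", "insert_id", "pct_of_control"]
        )
    drug = treated["drug"].iloc[0]
    controls = bta[
        (bta["inhibitor"] == "")
        & (bta["drug"] == drug)
        & (bta["donor_side"] == "apical")
        & (bta["condition"] == treated["condition"].iloc[0])
        & (bta["scenario"].str.contains("control"))
    ]
    if controls.empty:
        raise ValueError("no inhibitor-free control inserts found")
    times = sorted(t for t in treated["time_h"].unique() if t > 0)
    rows = []
    for t in times:
        cfg_t = replace(config, papp_time=float(t))
        ctrl_papp = [
            papp_6h(grp, compounds[drug], cfg_t).papp
            for _, grp in controls.groupby("insert_id")
        ]
        for (inhibitor, side), igrp in treated.groupby(["inhibitor", "inhibitor_side"]):
            for insert_id, grp in igrp.groupby("insert_id"):
                papp_t = papp_6h(grp, compounds[drug], cfg_t).papp
                pct = inhibition_percent_of_control([papp_t], ctrl_papp)[0]
                rows.append(
                    {
                        "inhibitor": inhibitor,
                        "inhibitor_side": side,
                        "time_h": t,
                        "insert_id": insert_id,
                        "pct_of_control": pct,
                    }
                )
    return pd.DataFrame(rows)


def _concentration_fit(papp: pd.DataFrame) -> Optional[dict]:
    """Through-origin flux-vs-concentration fit over the exposure series."""
    series = papp[
        (papp["direction"] == "A:B")
        & (papp["inhibitor"] == "")
        & (papp["drug"] == "propranolol")
        & (papp["condition"] == "asymmetric")
    ]
    # when the dataset labels its exposure series, use exactly those inserts
    labelled = series["scenario"].str.contains("conc", case=False)
    if labelled.any():
        series = series[labelled]
    if series["dose_ug_per_L"].nunique() < 5:
        return None
    conc = series["dose_ug_per_L"].to_numpy(dtype=float)
    flux = series["dq_dt_pmol_h"].to_numpy(dtype=float)
    out = {"linear": fit_linear(conc, flux, through_origin=True)}
    try:
        out["low_range"] = fit_low_range(conc, flux)
    except ValueError:
        pass
    return out


def run_analyze(
    records: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    compounds: Optional[dict[str, CompoundRecord]] = None,
    outdir: Optional[str | Path] = None,
) -> dict[str, object]:
    """Full analysis of a SamplingRecord table.

    Applies the TER gate before any estimation, then computes the Papp,
    transport-ratio, mannitol and inhibition tables and (when a
    concentration series is present) the dose-response fits.
    """
    config = config or AnalysisConfig()
    compounds = compounds or load_compound_table()
    missing = [c for c in ("insert_id", "compartment", "time_h", "dpm") if c not in records.columns]
    if missing:
        raise ValueError(f"record table lacks required columns: {missing}")

    inserts = (
        records[["insert_id", "ter_kohm_cm2"]]
        .drop_duplicates("insert_id")
        .itertuples(index=False)
    )
    # mannitol calibration inserts span the full TER range by design and are
    # exempt from the assay gate
    mannitol_ids = set(records.loc[records["mode"] == "mannitol", "insert_id"])
    gated = set(
        ter_gate([(r.insert_id, r.ter_kohm_cm2) for r in inserts], config)
    )
    n_all = records["insert_id"].nunique()
    keep = records["insert_id"].isin(gated | mannitol_ids)
    records = records[keep]
    logger.info(
        "analyze: TER gate retained %d/%d inserts (threshold %.1f kOhm cm2)",
        records["insert_id"].nunique(),
        n_all,
        config.ter_threshold,
    )

    papp = _papp_table(records, compounds, config)
    result: dict[str, object] = {
        "papp": papp,
        "tr": _tr_table(papp, config) if not papp.empty else pd.DataFrame(),
        "mannitol": _mannitol_table(records, compounds, config),
        "inhibition": _inhibition_table(records, compounds, config),
        "concentration_fit": _concentration_fit(papp) if not papp.empty else None,
        "n_gated_out": n_all - records["insert_id"].nunique(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("papp", "tr", "mannitol", "inhibition"):
            df = result[key]
            if isinstance(df, pd.DataFrame):
                df.to_csv(outdir / f"{key}.csv", index=False)
    return result


def _fmt_fit(fit) -> str:
    return (
        f"{fit.model}: slope={fit.slope:.4g} intercept={fit.intercept:.4g} "
        f"r2={fit.r_squared:.3f} n={fit.n}"
    )


def run_report(analysis: dict[str, object]) -> str:
    """Render an analysis dict as a plain-text report (pure function)."""
    lines: list[str] = []
    tr = analysis.get("tr")
    lines.append("== Transport ratios (mean Papp, TR >= 1.5 flags active) ==")
    if isinstance(tr, pd.DataFrame) and not tr.empty:
        view = tr.copy()
        for col in ("papp_ab_cm_s", "papp_ba_cm_s"):
            view[col] = view[col].map(lambda v: f"{v:.2e}")
        for col in ("uptake_tr", "efflux_tr"):
            view[col] = view[col].map(lambda v: f"{v:.2f}")
        lines.append(view.to_string(index=False))
    else:
        lines.append("(no bidirectional Papp pairs)")
    mann = analysis.get("mannitol")
    if isinstance(mann, pd.DataFrame) and not mann.empty:
        lines.append("")
        lines.append("== Mannitol paracellular permeability vs TER ==")
        summary = (
            mann.groupby("ter_kohm_cm2")["permeability_cm_s"]
            .mean()
            .reset_index()
        )
        summary["permeability_cm_s"] = summary["permeability_cm_s"].map(
            lambda v: f"{v:.2e}"
        )
        lines.append(summary.to_string(index=False))
    inhib = analysis.get("inhibition")
    if isinstance(inhib, pd.DataFrame) and not inhib.empty:
        lines.append("")
        lines.append("== Inhibition of uptake (% of mean control) ==")
        summary = (
            inhib.groupby(["inhibitor", "inhibitor_side", "time_h"])["pct_of_control"]
            .mean()
            .reset_index()
        )
        summary["pct_of_control"] = summary["pct_of_control"].map(lambda v: f"{v:.1f}")
        lines.append(summary.to_string(index=False))
    cf = analysis.get("concentration_fit")
    if cf:
        lines.append("")
        lines.append("== Concentration-response (flux pmol/h vs ug/L) ==")
        lines.append("overall " + _fmt_fit(cf["linear"]))
        if "low_range" in cf:
            lines.append("low-range " + _fmt_fit(cf["low_range"]["poly2"]))
            lines.append("low-range " + _fmt_fit(cf["low_range"]["linear"]))
    plasma = analysis.get("plasma")
    if plasma:
        lines.append("")
        lines.append("== Plasma read-across (in vitro basal vs plasma) ==")
        lines.append("vs predicted " + _fmt_fit(plasma["predicted"]))
        lines.append("vs actual    " + _fmt_fit(plasma["actual"]))
    return "\n".join(lines) + "\n"


def run_reproduce(
    outdir: str | Path,
    seed: int = 0,
    noise: Optional[NoiseModel] = None,
    n_inserts: int = 3,
) -> dict[str, object]:
    """Simulate the full study catalog, analyze it and write all reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenarios = _catalog.paper_catalog(n_inserts=n_inserts)
    records = run_simulate(scenarios, seed=seed, noise=noise, out=outdir / "records.csv")
    analysis = run_analyze(records, outdir=outdir)
    analysis["plasma"] = compare_in_vitro_plasma(load_plasma_table())
    report = run_report(analysis)
    (outdir / "report.txt").write_text(report)
    logger.info("reproduce: wrote %s", outdir / "report.txt")
    return analysis
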