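"""Concentration-response fitting and the fish plasma read-across comparison.

Three pieces:

* ordinary least-squares fits (through the origin or with intercept, plus a
  quadratic option for the curved low-concentration range) of receiver
  uptake flux against exposure concentration;
* the one-parameter blood:water partitioning prediction for propranolol,
  [plasma ng/mL] = 0.87 * [water ug/L] (the Fitzsimmons partition
  coefficient applied in the mammalian-fish leverage model);
* the regression comparison of in-vitro basal concentrations against
  predicted and measured in-vivo plasma concentrations, whose slopes
  summarise how far the 6-h static insert sits below a steady-state fish.

A small surrogate generator regenerates the concentration-response dataset
from a known through-origin linear model with multiplicative lognormal
noise; it is used for parameter-recovery checks of the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "predict_plasma",
    "fit_linear",
    "fit_poly2",
    "fit_low_range",
    "load_plasma_table",
    "compare_in_vitro_plasma",
    "simulate_concentration_response",
    "PLASMA_WATER_COEFFICIENT",
]

#: Blood:water partition coefficient of propranolol (ng/mL plasma per ug/L water).
PLASMA_WATER_COEFFICIENT = 0.87


@dataclass(frozen=True)
class RegressionFit:
    """One OLS fit: model name, coefficients (ascending order), r^2, n."""

    model: str  # linear_origin | linear_intercept | poly2
    coefficients: tuple[float, ...]
    r_squared: float
    n: int

    @property
    def slope(self) -> float:
        """First-order coefficient."""
        if self.model == "linear_origin":
            return self.coefficients[0]
        return self.coefficients[1]

    @property
    def intercept(self) -> float:
        return 0.0 if self.model == "linear_origin" else self.coefficients[0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear_origin":
            return self.coefficients[0] * x
        return sum(c * x**k for k, c in enumerate(self.coefficients))


def predict_plasma(
    water_conc: float | np.ndarray, coefficient: float = PLASMA_WATER_COEFFICIENT
) -> float | np.ndarray:
    """Predicted plasma concentration (ng/mL) from water exposure (ug/L)."""
    arr = np.asarray(water_conc, dtype=float)
    if np.any(arr < 0):
        raise ValueError("water concentration must be non-negative")
    out = coefficient * arr
    return float(out) if np.isscalar(water_conc) or arr.ndim == 0 else out


def _validated_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    return xa, ya


def fit_linear(
    x: Sequence[float], y: Sequence[float], through_origin: bool = False
) -> RegressionFit:
    """OLS straight-line fit; r^2 is uncentered for the through-origin model."""
    xa, ya = _validated_xy(x, y)
    min_n = 2 if through_origin else 3
    if xa.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.ptp(xa) == 0.0:
        raise ValueError("degenerate predictor: x has zero variance")
    if not through_origin and np.ptp(ya) == 0.0:
        raise ValueError("degenerate response: y has zero variance (r^2 undefined)")
    design = xa[:, None] if through_origin else sm.add_constant(xa)
    res = sm.OLS(ya, design).fit()
    if through_origin:
        return RegressionFit(
            "linear_origin", (float(res.params[0]),), float(res.rsquared), xa.size
        )
    return RegressionFit(
        "linear_intercept",
        (float(res.params[0]), float(res.params[1])),
        float(res.rsquared),
        xa.size,
    )


def fit_poly2(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Degree-2 polynomial OLS fit (with intercept)."""
    xa, ya = _validated_xy(x, y)
    if xa.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if np.ptp(xa) == 0.0:
        raise ValueError("degenerate predictor: x has zero variance")
    if np.ptp(ya) == 0.0:
        raise ValueError("degenerate response: y has zero variance (r^2 undefined)")
    design = np.column_stack([np.ones_like(xa), xa, xa**2])
    res = sm.OLS(ya, design).fit()
    return RegressionFit(
        "poly2", tuple(float(c) for c in res.params), float(res.rsquared), xa.size
    )


def fit_low_range(
    conc: Sequence[float],
    flux: Sequence[float],
    low_max: float = 0.14,
) -> dict[str, RegressionFit]:
    """Quadratic vs linear comparison on the low-concentration subset.

    Returns ``{"poly2": ..., "linear": ...}`` fitted to the points with
    concentration <= ``low_max`` ug/L. Because the linear model is nested in
    the quadratic, poly2 r^2 >= linear r^2 always.
    """
    ca, fa = _validated_xy(conc, flux)
    mask = ca <= low_max
    if mask.sum() < 4:
        raise ValueError("fewer than 4 points in the low range")
    return {
        "poly2": fit_poly2(ca[mask], fa[mask]),
        "linear": fit_linear(ca[mask], fa[mask]),
    }


def load_plasma_table(path: Optional[str] = None) -> pd.DataFrame:
    """The propranolol plasma comparison table.

    Columns: nominal water concentration (ug/L), predicted (in silico)
    plasma, measured (in vivo) plasma and in-vitro basal concentrations
    (all ng/mL) with SEMs; missing in-vivo entries are NaN. Without a path
    the packaged table is used.
    """
    if path is None:
        source = resources.files("gillflux.data").joinpath("propranolol_plasma.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    expected = predict_plasma(df["nominal_water_ug_per_L"].to_numpy())
    if not np.allclose(df["in_silico_ng_per_mL"], expected, rtol=1e-9):
        raise ValueError(
            "in_silico column is not 0.87 x nominal water concentration"
        )
    return df


def compare_in_vitro_plasma(table: pd.DataFrame) -> dict[str, object]:
    """Regress in-vitro basal concentrations on predicted and actual plasma.

    Rows with missing in-vivo values are dropped pairwise from the "actual"
    comparison. Both fits include an intercept. The returned slopes restate
    the fraction of the predicted (and of the measured) plasma concentration
    that the 6-h static insert reaches.
    """
    required = {"in_silico_ng_per_mL", "in_vivo_ng_per_mL", "in_vitro_ng_per_mL"}
    if not required.issubset(table.columns):
        raise ValueError(f"plasma table lacks columns {sorted(required)}")
    pred = table.dropna(subset=["in_silico_ng_per_mL", "in_vitro_ng_per_mL"])
    act = table.dropna(subset=["in_vivo_ng_per_mL", "in_vitro_ng_per_mL"])
    if len(pred) < 3 or len(act) < 3:
        raise ValueError("need at least 3 overlapping rows per comparison")
    fit_pred = fit_linear(
        pred["in_silico_ng_per_mL"], pred["in_vitro_ng_per_mL"]
    )
    fit_act = fit_linear(act["in_vivo_ng_per_mL"], act["in_vitro_ng_per_mL"])
    return {
        "predicted": fit_pred,
        "actual": fit_act,
        "fraction_of_predicted": fit_pred.slope,
        "fraction_of_actual": fit_act.slope,
    }


def simulate_concentration_response(
    slope: float = 0.052,
    concentrations: Optional[Sequence[float]] = None,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Regenerate a concentration-response dataset from a linear model.

    Draws one flux per insert as ``slope * concentration`` times a
    mean-one lognormal factor with coefficient of variation ``noise_cv``.
    By default the 54 per-insert exposure levels of the concentration
    series are used. Returns a frame with ``concentration`` and ``flux``.
    """
    if concentrations is None:
        from .catalog import concentration_series_inserts

        concentrations = concentration_series_inserts()
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.size)
    return pd.DataFrame({"concentration": conc, "flux": slope * conc * noise})
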