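"""Michaelis-Menten fitting and product-distribution normalisation.

The wet-lab companion to the simulation metrics: steady-state rates v
measured at substrate concentrations S are fitted to

    v = V_max * S / (K_M + S)

by unweighted nonlinear least squares (weighting of the assay is not
modelled; a per-point sigma can be supplied).  With the enzyme
concentration E0 the turnover number is k_cat = V_max / E0.  GC peak areas
are reduced to product percentages by straight proportional normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MichaelisMenten",
    "MichaelisMentenResults",
    "KineticsFit",
    "ProductDistribution",
    "fit_michaelis_menten",
    "normalize_product_distribution",
]


def _mm(S: np.ndarray, km: float, vmax: float) -> np.ndarray:
    return vmax * S / (km + S)


@dataclass
class KineticsFit:
    """Point estimates and standard errors of a Michaelis-Menten fit.

    ``K_M`` is in the units of S (μM in typical use); ``V_max`` in the units
    of v; ``k_cat`` (s^-1) is populated when an enzyme concentration was
    given.  A failed optimisation is flagged through ``converged`` rather
    than raised.
    """

    K_M: float
    V_max: float
    K_M_se: float
    V_max_se: float
    k_cat: float | None
    k_cat_se: float | None
    converged: bool
    n_obs: int


class MichaelisMenten:
    """Michaelis-Menten rate model for one substrate-saturation experiment.

    Parameters
    ----------
    s : substrate concentrations (>= 3 distinct values required)
    v : observed rates, same length, all >= 0
    enzyme_conc : optional total enzyme concentration E0 (same concentration
        units as V_max/k_cat implies); enables k_cat = V_max / E0.
    sigma : optional per-point rate uncertainties for weighted fitting.
    """

    def __init__(
        self,
        s: Sequence[float],
        v: Sequence[float],
        enzyme_conc: float | None = None,
        sigma: Sequence[float] | None = None,
    ):
        self.s = np.asarray(s, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if self.s.shape != self.v.shape or self.s.ndim != 1:
            raise ValueError("S and v must be 1-d arrays of equal length")
        if np.unique(self.s).size < 3:
            raise ValueError(
                "degenerate design: need at least 3 distinct substrate concentrations"
            )
        if np.any(self.s <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if np.any(self.v < 0):
            raise ValueError("rates must be >= 0")
        if enzyme_conc is not None and enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be > 0")
        self.enzyme_conc = enzyme_conc
        self.sigma = None if sigma is None else np.asarray(sigma, dtype=float)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        s_col: str = "S",
        v_col: str = "v",
        enzyme_conc: float | None = None,
    ) -> "MichaelisMenten":
        return cls(df[s_col].to_numpy(), df[v_col].to_numpy(), enzyme_conc)

    def fit(self) -> "MichaelisMentenResults":
        p0 = (float(np.median(self.s)), float(self.v.max() or 1.0))
        try:
            popt, pcov = curve_fit(
                _mm,
                self.s,
                self.v,
                p0=p0,
                sigma=self.sigma,
                absolute_sigma=False,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
                # tight tolerances: rates can be O(1e-3) and the recovered
                # constants should be limited by data, not by the optimiser
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                x_scale=np.maximum(np.abs(p0), 1e-12),
            )
            converged = bool(np.all(np.isfinite(popt)))
        except RuntimeError:
            popt = np.array([np.nan, np.nan])
            pcov = np.full((2, 2), np.nan)
            converged = False
        se = np.sqrt(np.diag(pcov))
        kcat = kcat_se = None
        if self.enzyme_conc is not None and converged:
            kcat = popt[1] / self.enzyme_conc
            kcat_se = se[1] / self.enzyme_conc
        params = KineticsFit(
            K_M=float(popt[0]),
            V_max=float(popt[1]),
            K_M_se=float(se[0]),
            V_max_se=float(se[1]),
            k_cat=kcat,
            k_cat_se=kcat_se,
            converged=converged,
            n_obs=self.s.size,
        )
        return MichaelisMentenResults(self, params, pcov)


@dataclass
class MichaelisMentenResults:
    model: MichaelisMenten
    params: KineticsFit
    cov_params: np.ndarray

    @property
    def converged(self) -> bool:
        return self.params.converged

    def predict(self, s: Sequence[float] | None = None) -> np.ndarray:
        s = self.model.s if s is None else np.asarray(s, dtype=float)
        return _mm(s, self.params.K_M, self.params.V_max)

    def residuals(self) -> np.ndarray:
        return self.model.v - self.predict()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Michaelis-Menten fit",
            "====================",
            f"n observations     {p.n_obs}",
            f"converged          {p.converged}",
            f"K_M                {p.K_M:.6g} +/- {p.K_M_se:.3g}",
            f"V_max              {p.V_max:.6g} +/- {p.V_max_se:.3g}",
        ]
        if p.k_cat is not None:
            lines.append(f"k_cat              {p.k_cat:.6g} +/- {p.k_cat_se:.3g}")
        return "\n".join(lines)


def fit_michaelis_menten(
    S: Sequence[float],
    v: Sequence[float],
    E0: float | None = None,
    sigma: Sequence[float] | None = None,
) -> KineticsFit:
    """Convenience wrapper: build the model, fit, return the parameter set."""
    return MichaelisMenten(S, v, enzyme_conc=E0, sigma=sigma).fit().params


@dataclass
class ProductDistribution:
    """Compound -> percentage map summing to 100, input order preserved."""

    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.percentages and abs(sum(self.percentages.values()) - 100.0) > 0.1:
            raise ValueError("percentages must sum to 100")

    def __getitem__(self, compound: str) -> float:
        return self.percentages[compound]

    def as_series(self) -> pd.Series:
        return pd.Series(self.percentages, name="percentage")


def normalize_product_distribution(
    areas: Mapping[str, float],
) -> ProductDistribution:
    """Peak areas to percentages: 100 * area / total, order preserved."""
    if not areas:
        raise ValueError("no peak areas given")
    if any(a < 0 for a in areas.values()):
        raise ValueError("peak areas must be >= 0")
    total = float(sum(areas.values()))
    if total <= 0:
        raise ValueError("all peak areas are zero")
    return ProductDistribution(
        percentages={c: 100.0 * a / total for c, a in areas.items()}
    )
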