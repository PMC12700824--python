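"""Hydrodynamic forward models and SEC molecular-weight calibration.

Shape discrimination for diffusing oligomers rests on how the translational
diffusion coefficient scales with subunit number n:

* globule: equal-volume sphere, D ~ n^(-1/3) (Stokes–Einstein);
* prolate spheroid (Perrin): D of the equal-volume sphere divided by the
  Perrin friction factor f/f0 = p^(-1/3) sqrt(p^2-1) / ln(p + sqrt(p^2-1))
  for aspect ratio p >= 1;
* rigid rod (Tirado–García de la Torre cylinder):
  D = kT (ln p + nu(p)) / (3 pi eta L), nu(p) = 0.312 + 0.565/p - 0.100/p^2.

Head-to-tail stacking of protomers of length L0 and diameter d0 (defaults
6 nm x 5 nm) gives an n-mer of length n*L0 at constant diameter, so the
predicted D(n_small)/D(n_large) ratio for an elongated species strictly
exceeds the globular (n_large/n_small)^(1/3) — the inequality that lets FCS
diffusion ratios distinguish rod-like filaments from globular aggregates.

SEC calibration regresses elution volume on log10 of molecular weight over
globular standards (ordinary least squares); predicted elution volumes for
multimer series flag states beyond the void-volume resolution limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .constants import (
    BOLTZMANN,
    DEFAULT_TEMPERATURE,
    NM_TO_M,
    WATER_VISCOSITY_293K,
)
from .exceptions import ValidationError

__all__ = [
    "HydroShape",
    "SECCalibration",
    "perrin_factor",
    "diffusion_coefficient",
    "predicted_diffusion_ratio",
    "hydrodynamic_diameter",
    "subunits_for_diameter",
    "sec_calibrate",
    "sec_predict",
    "DEFAULT_SEC_STANDARDS",
]

#: Globular calibration standards: (name, MW kDa, elution volume ml).  Blue
#: dextran marks the void volume and is excluded from the regression by
#: default.
DEFAULT_SEC_STANDARDS = (
    ("blue dextran", 2000.0, 8.7),
    ("ferritin", 440.0, 9.75),
    ("immunoglobulin G", 160.0, 11.4),
    ("BSA", 66.0, 13.3),
    ("ovalbumin", 44.0, 14.6),
    ("carbonic anhydrase", 29.0, 16.2),
    ("ribonuclease A", 13.7, 17.9),
)


@dataclass(frozen=True)
class HydroShape:
    """Sphere / prolate-spheroid / rod model of an n-mer.

    Lengths in nm; ``eta`` in Pa·s (default water at 293 K — multiply by
    ~2–4 for cytoplasm or nucleoplasm).
    """

    model: str = "rod"
    n: int = 1
    L0: float = 6.0
    d0: float = 5.0
    T: float = DEFAULT_TEMPERATURE
    eta: float = WATER_VISCOSITY_293K

    def __post_init__(self):
        if self.model not in ("sphere", "prolate", "rod"):
            raise ValidationError("model must be sphere, prolate or rod")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.L0 <= 0 or self.d0 <= 0:
            raise ValidationError("L0 and d0 must be > 0")
        if self.T <= 0 or self.eta <= 0:
            raise ValidationError("T and eta must be > 0")
        if self.model in ("prolate", "rod") and self.aspect_ratio < 1.0:
            raise ValidationError("aspect ratio must be >= 1 for prolate/rod")

    @property
    def length(self) -> float:
        """n-mer length n*L0 (head-to-tail stacking), nm."""
        return self.n * self.L0

    @property
    def aspect_ratio(self) -> float:
        return self.length / self.d0

    @property
    def equivalent_diameter(self) -> float:
        """Diameter (nm) of the sphere with the n-mer's volume (prolate
        ellipsoid of semi-axes n*L0/2, d0/2, d0/2)."""
        return 2.0 * ((self.length / 2.0) * (self.d0 / 2.0) ** 2) ** (1.0 / 3.0)


def perrin_factor(p: float) -> float:
    """Perrin translational friction ratio f/f0 for a prolate spheroid.

    ``p`` is the axial ratio (long/short semi-axis, >= 1).  Equals 1 at
    p = 1 (sphere) and grows monotonically; the p -> 1 limit is handled
    analytically (series in (p-1)).  Oblate shapes (p < 1) are not supported.
    """
    if not np.isfinite(p) or p < 1.0:
        raise ValidationError("aspect ratio must be >= 1 (oblate not supported)")
    if p < 1.0 + 1e-7:
        # Taylor expansion around the sphere: f/f0 = 1 + 4/45 (p-1)^2 + ...
        return 1.0 + (4.0 / 45.0) * (p - 1.0) ** 2
    xi = math.sqrt(p * p - 1.0)
    return p ** (-1.0 / 3.0) * xi / math.log(p + xi)


def _tirado_nu(p: float) -> float:
    return 0.312 + 0.565 / p - 0.100 / p**2


def diffusion_coefficient(shape: HydroShape) -> float:
    """Translational diffusion coefficient of the shape, µm^2/s."""
    kT = BOLTZMANN * shape.T
    d_eq_m = shape.equivalent_diameter * NM_TO_M
    if shape.model == "sphere":
        D = kT / (3.0 * math.pi * shape.eta * d_eq_m)
    elif shape.model == "prolate":
        D = kT / (3.0 * math.pi * shape.eta * d_eq_m) / perrin_factor(shape.aspect_ratio)
    else:  # rod
        p = shape.aspect_ratio
        if p < 2.0:
            warnings.warn(
                "rod (cylinder) formula used outside its validity range p >= 2",
                stacklevel=2,
            )
        L_m = shape.length * NM_TO_M
        D = kT * (math.log(p) + _tirado_nu(p)) / (3.0 * math.pi * shape.eta * L_m)
    return D / 1e-12  # m^2/s -> µm^2/s


def predicted_diffusion_ratio(
    n_small: int,
    n_large: int,
    model: str = "rod",
    L0: float = 6.0,
    d0: float = 5.0,
    T: float = DEFAULT_TEMPERATURE,
    eta: float = WATER_VISCOSITY_293K,
) -> float:
    """Theoretical D(n_small)/D(n_large) for head-to-tail n-mers.

    ``model='globule'`` returns the analytic equal-volume-sphere value
    (n_large/n_small)^(1/3); ``'prolate'`` and ``'rod'`` evaluate the
    corresponding friction model with the given protomer dimensions.
    """
    if n_small >= n_large:
        raise ValidationError("require n_small < n_large")
    if model == "globule":
        return (n_large / n_small) ** (1.0 / 3.0)
    if model not in ("prolate", "rod"):
        raise ValidationError("model must be globule, prolate or rod")
    d_small = diffusion_coefficient(HydroShape(model, n_small, L0, d0, T, eta))
    d_large = diffusion_coefficient(HydroShape(model, n_large, L0, d0, T, eta))
    return d_small / d_large


def hydrodynamic_diameter(D: float, T: float = DEFAULT_TEMPERATURE,
                          eta: float = WATER_VISCOSITY_293K) -> float:
    """Stokes–Einstein hydrodynamic diameter (nm) from D (µm^2/s).

    Dh = kT / (3 pi eta D).  The mapping is an involution: applying it to a
    diameter-equivalent diffusion coefficient returns the diameter, so the
    same function serves both directions (pass D in µm^2/s, get nm; the
    inverse uses ``kT / (3 pi eta Dh)``).
    """
    if D <= 0 or T <= 0 or eta <= 0:
        raise ValidationError("D, T and eta must be > 0")
    d_m = BOLTZMANN * T / (3.0 * math.pi * eta * D * 1e-12)
    return d_m / NM_TO_M


def diffusion_from_diameter(Dh_nm: float, T: float = DEFAULT_TEMPERATURE,
                            eta: float = WATER_VISCOSITY_293K) -> float:
    """Inverse Stokes–Einstein: D (µm^2/s) of a sphere of diameter Dh (nm)."""
    if Dh_nm <= 0:
        raise ValidationError("diameter must be > 0")
    D_m2 = BOLTZMANN * T / (3.0 * math.pi * eta * Dh_nm * NM_TO_M)
    return D_m2 / 1e-12


def subunits_for_diameter(
    Dh_target_nm: float,
    model: str = "rod",
    L0: float = 6.0,
    d0: float = 5.0,
    T: float = DEFAULT_TEMPERATURE,
    eta: float = WATER_VISCOSITY_293K,
    n_max: float = 1000.0,
) -> float:
    """Continuous subunit count whose n-mer has the target hydrodynamic
    diameter (root-finding on the forward model).

    Interprets an apparent sphere-equivalent diameter (e.g. from DLS) in
    terms of a rod or prolate of stacked protomers.  The answer is strongly
    formula-dependent: a hydrodynamic diameter is an intensity-free
    sphere-equivalent and rods of modest aspect ratio map onto it
    non-intuitively, so treat the result as indicative.
    """

    def f(n):
        shape = HydroShape(model, 1, n * L0, d0, T, eta)  # continuous length
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return hydrodynamic_diameter(diffusion_coefficient(shape), T, eta) - Dh_target_nm

    lo = max(d0 / L0, 1e-3)
    if f(lo) > 0:
        raise ValidationError("target diameter smaller than a single protomer's")
    return brentq(f, lo, n_max)


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

@dataclass
class SECCalibration:
    """Linear EV = intercept + slope * log10(MW) calibration."""

    standards: pd.DataFrame  # columns name, mw_kda, ev_ml
    slope: float
    intercept: float
    r2: float
    void_volume: float | None = None

    def __post_init__(self):
        if self.slope >= 0:
            raise ValidationError("slope must be negative (EV decreases with MW)")

    def predict_ev(self, mw_kda):
        mw = np.asarray(mw_kda, dtype=float)
        return self.intercept + self.slope * np.log10(mw)

    def invert_mw(self, ev_ml):
        """Molecular weight (kDa) eluting at the given volume (round trip
        with :meth:`predict_ev` to numerical precision)."""
        ev = np.asarray(ev_ml, dtype=float)
        return 10.0 ** ((ev - self.intercept) / self.slope)


def sec_calibrate(standards=DEFAULT_SEC_STANDARDS, exclude_void: bool = True) -> SECCalibration:
    """Ordinary least squares of elution volume on log10(MW).

    ``standards`` is an iterable of (name, MW kDa, EV ml) or a DataFrame with
    columns name/mw_kda/ev_ml.  By default the largest-MW standard is treated
    as the void marker and excluded from the regression (its EV is kept as
    the column's resolution limit); pass ``exclude_void=False`` to include it.
    """
    if isinstance(standards, pd.DataFrame):
        df = standards.rename(columns=str.lower).copy()
    else:
        df = pd.DataFrame(list(standards), columns=["name", "mw_kda", "ev_ml"])
    if len(df) < 3:
        raise ValidationError("need >= 3 standards")
    if df["mw_kda"].duplicated().any():
        raise ValidationError("duplicate molecular weights among standards")
    df = df.sort_values("mw_kda", ascending=False).reset_index(drop=True)
    if not df["ev_ml"].is_monotonic_increasing:
        warnings.warn("standards are not monotone in EV vs MW", stacklevel=2)

    void_volume = None
    fit_df = df
    if exclude_void:
        void_volume = float(df.loc[0, "ev_ml"])
        fit_df = df.iloc[1:]
        if len(fit_df) < 2:
            raise ValidationError("need >= 2 non-void standards")

    X = sm.add_constant(np.log10(fit_df["mw_kda"].to_numpy()))
    model = sm.OLS(fit_df["ev_ml"].to_numpy(), X).fit()
    return SECCalibration(
        standards=df,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        void_volume=void_volume,
    )


def sec_predict(cal: SECCalibration, mw_monomer: float, n_max: int = 12) -> pd.DataFrame:
    """Predicted elution volumes for 1..n_max multimers of a monomer MW (kDa).

    Rows whose predicted EV falls below the void volume are flagged
    ``beyond column resolution``.
    """
    if mw_monomer <= 0:
        raise ValidationError("mw_monomer must be > 0")
    n = np.arange(1, n_max + 1)
    mw = n * mw_monomer
    ev = cal.predict_ev(mw)
    flag = np.full(n.shape, "", dtype=object)
    if cal.void_volume is not None:
        flag[ev < cal.void_volume] = "beyond column resolution"
    return pd.DataFrame({"n": n, "mw_kda": mw, "ev_ml": ev, "flag": flag})
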