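"""van't Hoff analysis and binding thermodynamics.

ln K_a regressed on 1/T gives the enthalpy (slope) and entropy (intercept)
of association; Gibbs energy follows from dG = -RT ln K_a. The gas constant
is fixed at R = 1.987 cal K^-1 mol^-1, the value conventional in the
protein-ligand fluorescence literature (energies in kcal/mol and cal/mol/K).

Driving-force classification follows the Ross-Subramanian sign rules:
dH > 0, dS > 0 hydrophobic; dH < 0, dS < 0 hydrogen bond / van der Waals;
dH ~ 0 (|dH| < 1 kcal/mol), dS > 0 electrostatic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .quenching import BindingFit
from .spectra import ValidationError

__all__ = [
    "R_CAL_PER_MOL_K",
    "ThermoResult",
    "VantHoffRegression",
    "vant_hoff_fit",
    "gibbs_from_Ka",
    "classify_forces",
    "bound_fraction",
]

#: Gas constant in cal K^-1 mol^-1 (kcal-based unit system).
R_CAL_PER_MOL_K = 1.987

#: |dH| below this (kcal/mol) counts as "dH ~ 0" in the force rules.
ELECTROSTATIC_DH_CUT_KCAL = 1.0


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """OLS van't Hoff fit: ln K_a = -dH/(R T) + dS/R.

    Attributes (after fit)
    ----------------------
    dH_kcal_per_mol_ : float      Enthalpy change, -slope * R / 1000.
    dS_cal_per_mol_K_ : float     Entropy change, intercept * R.
    dH_se_kcal_, dS_se_cal_ : float   OLS standard errors.
    r_squared_ : float
    """

    def fit(self, X, y):
        """Fit with X = temperature (K), y = K_a (M^-1)."""
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        Ka = np.asarray(y, dtype=float)
        if T.size != Ka.size:
            raise ValidationError("X and y length mismatch")
        if T.size < 2:
            raise ValidationError("van't Hoff fit needs >= 2 temperatures")
        if np.unique(T).size != T.size:
            raise ValidationError("duplicate temperatures")
        if np.any(T <= 0) or np.any(Ka <= 0):
            raise ValidationError("temperatures and K_a must be > 0")
        res = stats.linregress(1.0 / T, np.log(Ka))
        self.dH_kcal_per_mol_ = -float(res.slope) * R_CAL_PER_MOL_K / 1000.0
        self.dS_cal_per_mol_K_ = float(res.intercept) * R_CAL_PER_MOL_K
        se_slope = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        se_icpt = float(res.intercept_stderr) if np.isfinite(res.intercept_stderr) else 0.0
        self.dH_se_kcal_ = se_slope * R_CAL_PER_MOL_K / 1000.0
        self.dS_se_cal_ = se_icpt * R_CAL_PER_MOL_K
        lnKa = np.log(Ka)
        self.r_squared_ = float(res.rvalue**2) if np.ptp(lnKa) > 0 else 1.0
        return self

    def predict(self, X):
        """Predicted K_a (M^-1) at the given temperatures."""
        check_is_fitted(self, "dH_kcal_per_mol_")
        T = np.asarray(X, dtype=float)
        if T.ndim == 2 and T.shape[1] == 1:
            T = T[:, 0]
        dH_cal = self.dH_kcal_per_mol_ * 1000.0
        return np.exp(-dH_cal / (R_CAL_PER_MOL_K * T) + self.dS_cal_per_mol_K_ / R_CAL_PER_MOL_K)


@dataclass(frozen=True)
class PerTemperature:
    T_K: float
    dG_kcal_per_mol: float          # from -RT ln Ka (reported)
    TdS_kcal_per_mol: float
    dG_gibbs_helmholtz_kcal: float  # dH - T dS cross-check


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff enthalpy/entropy, per-temperature Gibbs energies, force class."""

    dH_kcal_per_mol: float
    dS_cal_per_mol_K: float
    per_temperature: tuple[PerTemperature, ...]
    r_squared: float
    force_class: str
    dH_se_kcal: float = float("nan")
    dS_se_cal: float = float("nan")


def gibbs_from_Ka(K_a_per_M: float, T_K: float) -> float:
    """Gibbs free energy of association, dG = -RT ln K_a, in kcal/mol."""
    if K_a_per_M <= 0 or T_K <= 0:
        raise ValidationError("K_a and T must be > 0")
    return -R_CAL_PER_MOL_K * 1e-3 * T_K * float(np.log(K_a_per_M))


def classify_forces(dH_kcal: float, dS_cal: float) -> str:
    """Ross-Subramanian sign rules for the dominant binding force."""
    if not (np.isfinite(dH_kcal) and np.isfinite(dS_cal)):
        raise ValidationError("non-finite thermodynamic parameters")
    if abs(dH_kcal) < ELECTROSTATIC_DH_CUT_KCAL and dS_cal > 0:
        return "electrostatic"
    if dH_kcal > 0 and dS_cal > 0:
        return "hydrophobic"
    if dH_kcal < 0 and dS_cal < 0:
        return "hbond_vdw"
    return "mixed"


def bound_fraction(K_a_per_M: float, binder_conc_M: float) -> float:
    """Fraction of free ligand sequestered by a binder at concentration C.

    f = K_a C / (1 + K_a C), in [0, 1). With whole-blood hemoglobin at
    2.3 mM this estimates the erythrocyte-bound drug fraction.
    """
    if K_a_per_M < 0 or binder_conc_M < 0:
        raise ValidationError("K_a and concentration must be >= 0")
    x = K_a_per_M * binder_conc_M
    return x / (1.0 + x)


def vant_hoff_fit(points) -> ThermoResult:
    """van't Hoff analysis of K_a(T).

    Parameters
    ----------
    points : list of (T_K, K_a) pairs, dicts with keys ``T_K``/``K_a_per_M``,
        or :class:`~quenchbind.quenching.BindingFit` objects.

    Returns
    -------
    ThermoResult with dH (kcal/mol), dS (cal/mol/K), per-temperature dG from
    -RT ln K_a (the reported path), TdS, the Gibbs-Helmholtz dG = dH - TdS
    cross-check, and the force classification.
    """
    T, Ka = [], []
    for p in points:
        if isinstance(p, BindingFit):
            T.append(p.temperature_K)
            Ka.append(p.K_a_per_M)
        elif isinstance(p, dict):
            T.append(float(p["T_K"]))
            Ka.append(float(p["K_a_per_M"]))
        else:
            t, k = p
            T.append(float(t))
            Ka.append(float(k))
    T = np.asarray(T)
    Ka = np.asarray(Ka)
    model = VantHoffRegression().fit(T, Ka)
    dH = model.dH_kcal_per_mol_
    dS = model.dS_cal_per_mol_K_
    per_T = tuple(
        PerTemperature(
            T_K=float(t),
            dG_kcal_per_mol=gibbs_from_Ka(float(k), float(t)),
            TdS_kcal_per_mol=float(t) * dS / 1000.0,
            dG_gibbs_helmholtz_kcal=dH - float(t) * dS / 1000.0,
        )
        for t, k in zip(T, Ka)
    )
    return ThermoResult(
        dH_kcal_per_mol=dH,
        dS_cal_per_mol_K=dS,
        per_temperature=per_T,
        r_squared=model.r_squared_,
        force_class=classify_forces(dH, dS),
        dH_se_kcal=model.dH_se_kcal_,
        dS_se_cal=model.dS_se_cal_,
    )
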