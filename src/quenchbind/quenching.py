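"""Stern-Volmer quenching analysis.

Inner-filter correction, the linear Stern-Volmer fit (F0/F = 1 + K_SV [Q]),
the modified double-log Stern-Volmer fit
(log10((F0-F)/F) = log10 K_a + n log10 [Q]), the bimolecular quenching rate
constant k_q = K_SV / tau0, and the static/dynamic mechanism call.

The two regressions are exposed as scikit-learn style estimators
(:class:`SternVolmerRegression`, :class:`ModifiedSternVolmerRegression`)
operating on plain arrays; :func:`fit_stern_volmer` and
:func:`fit_modified_sv` are the titration-level wrappers that assemble the
arrays from a :class:`~quenchbind.spectra.TitrationSeries`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import TitrationSeries, ValidationError

__all__ = [
    "DIFFUSION_LIMIT_PER_M_S",
    "SVFit",
    "BindingFit",
    "MechanismCall",
    "FitError",
    "AntiQuenchingWarning",
    "SternVolmerRegression",
    "ModifiedSternVolmerRegression",
    "inner_filter_correct",
    "fit_stern_volmer",
    "fit_modified_sv",
    "classify_mechanism",
]

#: Diffusion-controlled upper bound for collisional quenching (M^-1 s^-1).
DIFFUSION_LIMIT_PER_M_S = 1e10


class FitError(RuntimeError):
    """Too few usable points to fit."""


class AntiQuenchingWarning(UserWarning):
    """Fluorescence above the zero-quencher reference at [Q] > 0."""


def inner_filter_correct(F_obs, A_ex, A_em):
    """Correct observed fluorescence for primary/secondary inner-filter effects.

    F_corr = F_obs * 10^((A_ex + A_em) / 2)

    Accepts scalars or arrays. The correction never decreases intensity.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(F_obs <= 0):
        raise ValidationError("observed fluorescence must be > 0")
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be >= 0")
    out = F_obs * 10.0 ** ((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def _as_1d_x(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValidationError("X must be 1-D or a single-column 2-D array")
    return X


class SternVolmerRegression(RegressorMixin, BaseEstimator):
    """OLS fit of the Stern-Volmer relation F0/F = intercept + K_SV [Q].

    The intercept is left free (not forced through 1); a quality flag
    ``intercept_ok_`` records whether it lies within 0.1 of the ideal 1.

    Parameters
    ----------
    tau0_s : float
        Unquenched fluorophore lifetime (s), used for k_q = K_SV / tau0.

    Attributes (after fit)
    ----------------------
    K_sv_ : float            Stern-Volmer constant (M^-1), clipped at 0.
    intercept_ : float       Fitted intercept (ideal 1).
    k_q_ : float             Bimolecular quenching constant (M^-1 s^-1).
    K_sv_se_, intercept_se_ : float   OLS standard errors.
    r_squared_ : float
    n_points_ : int
    intercept_ok_ : bool     |intercept - 1| <= 0.1.
    """

    def __init__(self, tau0_s: float = 5.71e-9):
        self.tau0_s = tau0_s

    def fit(self, X, y):
        """Fit with X = quencher concentration (M), y = F0/F."""
        q = _as_1d_x(X)
        r = np.asarray(y, dtype=float)
        if q.size != r.size:
            raise ValidationError("X and y length mismatch")
        if q.size < 3:
            raise FitError("Stern-Volmer fit needs >= 3 points")
        if self.tau0_s <= 0:
            raise ValidationError("tau0_s must be > 0")
        if np.ptp(q) == 0:
            raise FitError("all quencher concentrations identical")
        res = stats.linregress(q, r)
        self.K_sv_ = max(float(res.slope), 0.0)
        self.intercept_ = float(res.intercept)
        self.K_sv_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2) if np.ptp(r) > 0 else 1.0
        self.k_q_ = self.K_sv_ / self.tau0_s
        self.n_points_ = int(q.size)
        self.intercept_ok_ = abs(self.intercept_ - 1.0) <= 0.1
        return self

    def predict(self, X):
        check_is_fitted(self, "K_sv_")
        return self.intercept_ + self.K_sv_ * _as_1d_x(X)


class ModifiedSternVolmerRegression(RegressorMixin, BaseEstimator):
    """OLS fit of log10((F0-F)/F) = log10 K_a + n log10 [Q].

    Attributes (after fit)
    ----------------------
    K_a_ : float         Association constant (M^-1), 10**intercept.
    n_sites_ : float     Binding-site number (slope).
    K_a_se_ : float      Delta-method SE: K_a * ln(10) * SE(intercept).
    n_sites_se_ : float
    r_squared_ : float
    n_points_ : int
    """

    def fit(self, X, y):
        """Fit with X = quencher concentration (M, > 0), y = (F0-F)/F (> 0)."""
        q = _as_1d_x(X)
        g = np.asarray(y, dtype=float)
        if q.size != g.size:
            raise ValidationError("X and y length mismatch")
        if np.any(q <= 0) or np.any(g <= 0):
            raise ValidationError("modified SV fit needs [Q] > 0 and (F0-F)/F > 0")
        if q.size < 3:
            raise FitError("modified Stern-Volmer fit needs >= 3 points")
        res = stats.linregress(np.log10(q), np.log10(g))
        self.n_sites_ = float(res.slope)
        self.K_a_ = float(10.0**res.intercept)
        self.n_sites_se_ = float(res.stderr)
        self.K_a_se_ = self.K_a_ * np.log(10.0) * float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2) if np.ptp(np.log10(g)) > 0 else 1.0
        self.n_points_ = int(q.size)
        return self

    def predict(self, X):
        """Predicted (F0-F)/F at the given concentrations."""
        check_is_fitted(self, "K_a_")
        return self.K_a_ * _as_1d_x(X) ** self.n_sites_


@dataclass(frozen=True)
class SVFit:
    """Fitted Stern-Volmer parameters at one temperature."""

    temperature_K: float
    K_SV_per_M: float
    intercept: float
    k_q_per_M_s: float
    r_squared: float
    n_points: int
    K_SV_se: float = float("nan")
    intercept_ok: bool = True

    def __post_init__(self):
        if self.K_SV_per_M < 0:
            raise ValidationError("K_SV must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class BindingFit:
    """Fitted association constant and stoichiometry at one temperature."""

    temperature_K: float
    K_a_per_M: float
    n_sites: float
    r_squared: float
    K_a_se: float = float("nan")
    n_sites_se: float = float("nan")

    def __post_init__(self):
        if self.K_a_per_M <= 0 or self.n_sites <= 0:
            raise ValidationError("K_a and n must be > 0")


@dataclass(frozen=True)
class MechanismCall:
    mechanism: str  # "static" | "dynamic" | "ambiguous"
    evidence: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.mechanism not in ("static", "dynamic", "ambiguous"):
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "static" and not self.evidence:
            raise ValidationError("a static call requires recorded evidence")


def _corrected_intensities(series: TitrationSeries, correct_ife: bool):
    F = series.intensity_obs
    if correct_ife:
        F = inner_filter_correct(F, series.A_ex, series.A_em)
    q = series.conc_M
    F0 = float(F[q == 0.0][0])
    return q, F, F0


def fit_stern_volmer(series: TitrationSeries, correct_ife: bool = True) -> SVFit:
    """Fit F0/F versus [Q] for one titration.

    Uses all points with [Q] > 0 plus the zero-concentration reference
    (which anchors the ratio at 1). Points brighter than F0 at [Q] > 0 are
    retained but flagged with :class:`AntiQuenchingWarning`.
    """
    q, F, F0 = _corrected_intensities(series, correct_ife)
    n_anti = int(np.sum((q > 0) & (F >= F0 * (1 + 1e-9))))
    if n_anti:
        warnings.warn(
            f"{n_anti} point(s) brighter than F0 at [Q] > 0 (anti-quenching); retained",
            AntiQuenchingWarning,
        )
    if q.size < 3:
        raise FitError("need >= 3 usable points")
    model = SternVolmerRegression(tau0_s=series.tau0_s).fit(q, F0 / F)
    if not model.intercept_ok_:
        warnings.warn(
            f"Stern-Volmer intercept {model.intercept_:.3f} deviates from 1 by > 0.1",
            UserWarning,
        )
    return SVFit(
        temperature_K=series.temperature_K,
        K_SV_per_M=model.K_sv_,
        intercept=model.intercept_,
        k_q_per_M_s=model.k_q_,
        r_squared=model.r_squared_,
        n_points=model.n_points_,
        K_SV_se=model.K_sv_se_,
        intercept_ok=model.intercept_ok_,
    )


def fit_modified_sv(series: TitrationSeries, correct_ife: bool = True) -> BindingFit:
    """Fit the double-log binding plot for one titration.

    Points with F >= F0 at [Q] > 0 have no defined log((F0-F)/F) and are
    excluded with a warning; at least 3 usable points must remain.
    """
    q, F, F0 = _corrected_intensities(series, correct_ife)
    pos = q > 0
    usable = pos & (F < F0)
    n_dropped = int(np.sum(pos) - np.sum(usable))
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} point(s) with F >= F0 from the double-log fit",
            AntiQuenchingWarning,
        )
    if np.sum(usable) < 3:
        raise FitError("fewer than 3 usable points for the modified Stern-Volmer fit")
    g = (F0 - F[usable]) / F[usable]
    model = ModifiedSternVolmerRegression().fit(q[usable], g)
    return BindingFit(
        temperature_K=series.temperature_K,
        K_a_per_M=model.K_a_,
        n_sites=model.n_sites_,
        r_squared=model.r_squared_,
        K_a_se=model.K_a_se_,
        n_sites_se=model.n_sites_se_,
    )


def classify_mechanism(
    fits: list[SVFit], diffusion_limit_per_M_s: float = DIFFUSION_LIMIT_PER_M_S
) -> MechanismCall:
    """Call the quenching mechanism from temperature-resolved SV fits.

    static  — every k_q exceeds the diffusion limit, or K_SV strictly
              decreases with temperature (>= 2 fits);
    dynamic — k_q at or below the limit and K_SV strictly increasing;
    ambiguous otherwise. Each triggered criterion is recorded as evidence.
    """
    if not fits:
        raise ValidationError("need at least one Stern-Volmer fit")
    fits = sorted(fits, key=lambda f: f.temperature_K)
    ksv = np.array([f.K_SV_per_M for f in fits])
    kq = np.array([f.k_q_per_M_s for f in fits])
    evidence: list[str] = []

    kq_above = bool(np.all(kq > diffusion_limit_per_M_s))
    if kq_above:
        evidence.append(
            f"all k_q ({kq.min():.3g}-{kq.max():.3g} M^-1 s^-1) exceed the "
            f"diffusion limit {diffusion_limit_per_M_s:.1g} M^-1 s^-1"
        )
    decreasing = len(fits) >= 2 and bool(np.all(np.diff(ksv) < 0))
    increasing = len(fits) >= 2 and bool(np.all(np.diff(ksv) > 0))
    if decreasing:
        evidence.append(
            "K_SV strictly decreases with temperature: "
            + ", ".join(f"{f.K_SV_per_M:.4g} M^-1 at {f.temperature_K:g} K" for f in fits)
        )
    if kq_above or decreasing:
        return MechanismCall("static", tuple(evidence))
    if not kq_above and increasing:
        evidence.append(
            "K_SV strictly increases with temperature while k_q stays at or "
            "below the diffusion limit"
        )
        return MechanismCall("dynamic", tuple(evidence))
    evidence.append("criteria inconclusive (no temperature trend or conflicting signs)")
    return MechanismCall("ambiguous", tuple(evidence))
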