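"""Förster resonance energy transfer between a protein donor and a bound ligand.

Overlap integral J = ∫ F(λ) ε(λ) λ⁴ dλ / ∫ F(λ) dλ with λ in cm, so J
carries M⁻¹ cm³; Förster radius R₀⁶ = 8.79e-25 · κ² · n⁻⁴ · φ · J (cm⁶,
with the prefactor presuming exactly this unit system); transfer efficiency
E = 1 − F/F₀ and donor–acceptor distance r = R₀ ((1−E)/E)^(1/6).

Defaults follow the usual tryptophan-donor assumptions: isotropic dipole
orientation κ² = 2/3, aqueous refractive index n = 1.33, donor quantum
yield φ = 0.118. They are parameters, not constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, ValidationError

__all__ = [
    "DEFAULT_KAPPA2",
    "DEFAULT_REFRACTIVE_INDEX",
    "DEFAULT_QUANTUM_YIELD",
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "donor_acceptor_distance",
    "fret_validity",
    "compute_fret",
]

DEFAULT_KAPPA2 = 2.0 / 3.0
DEFAULT_REFRACTIVE_INDEX = 1.33
DEFAULT_QUANTUM_YIELD = 0.118

#: Practical distance window (nm) over which FRET efficiencies are measurable.
FRET_WINDOW_NM = (2.0, 8.0)

NM_PER_CM = 1e7


@dataclass(frozen=True)
class FretResult:
    J_M_cm3: float
    R0_nm: float
    E: float
    r_nm: float
    valid_range: bool
    in_fret_window: bool
    kappa2: float = DEFAULT_KAPPA2
    refr_index: float = DEFAULT_REFRACTIVE_INDEX
    phi_donor: float = DEFAULT_QUANTUM_YIELD

    def __post_init__(self):
        if self.J_M_cm3 < 0:
            raise ValidationError("J must be >= 0")
        # efficiency-distance consistency: E = R0^6 / (R0^6 + r^6)
        e_check = self.R0_nm**6 / (self.R0_nm**6 + self.r_nm**6)
        if not np.isclose(e_check, self.E, rtol=1e-9, atol=0):
            raise ValidationError("E and r are inconsistent with R0")


def overlap_integral(donor_em: Spectrum, acceptor_eps: Spectrum) -> float:
    """Spectral overlap J between donor emission and acceptor absorptivity.

    Trapezoidal quadrature on the union-refined grid over the common
    wavelength interval; both spectra are linearly interpolated onto it.
    The donor normalisation makes J invariant to rescaling the emission
    intensities. Returns 0 with a warning if the supports are disjoint.

    ``acceptor_eps`` must be in molar units (kind ``molar_absorption``,
    M^-1 cm^-1); a normalised absorbance curve cannot yield J.
    """
    if acceptor_eps.kind != "molar_absorption":
        raise ValidationError(
            "acceptor spectrum must have kind='molar_absorption' (M^-1 cm^-1); "
            "convert absorbance via eps = A / (c * l) first"
        )
    if np.any(acceptor_eps.intensity < 0):
        raise ValidationError("molar absorptivities must be >= 0")
    lo = max(donor_em.support[0], acceptor_eps.support[0])
    hi = min(donor_em.support[1], acceptor_eps.support[1])
    if lo >= hi:
        warnings.warn("donor and acceptor spectra do not overlap; J = 0", UserWarning)
        return 0.0
    grid = np.union1d(donor_em.wavelength_nm, acceptor_eps.wavelength_nm)
    grid = grid[(grid >= lo) & (grid <= hi)]
    F = np.interp(grid, donor_em.wavelength_nm, donor_em.intensity)
    eps = np.interp(grid, acceptor_eps.wavelength_nm, acceptor_eps.intensity)
    lam_cm = grid / NM_PER_CM
    denom = np.trapezoid(F, lam_cm)
    if denom <= 0:
        warnings.warn("donor has no intensity over the overlap interval; J = 0", UserWarning)
        return 0.0
    return float(np.trapezoid(F * eps * lam_cm**4, lam_cm) / denom)


def forster_radius(
    J_M_cm3: float,
    kappa2: float = DEFAULT_KAPPA2,
    refr_index: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> float:
    """Förster radius (nm): R0 = (8.79e-25 κ² n⁻⁴ φ J)^(1/6), J in M⁻¹ cm³."""
    if J_M_cm3 <= 0 or kappa2 <= 0 or refr_index <= 0 or phi <= 0:
        raise ValidationError("all Förster-radius inputs must be > 0")
    r0_cm = (8.79e-25 * kappa2 * refr_index**-4 * phi * J_M_cm3) ** (1.0 / 6.0)
    return r0_cm * NM_PER_CM


def transfer_efficiency(F: float, F0: float) -> float:
    """FRET efficiency from donor intensities with and without acceptor."""
    if not (0 < F <= F0):
        raise ValidationError("require 0 < F <= F0")
    return 1.0 - F / F0


def donor_acceptor_distance(E: float, R0_nm: float) -> float:
    """Donor–acceptor separation r = R0 ((1-E)/E)^(1/6) (nm)."""
    if not (0.0 < E < 1.0):
        raise ValidationError("E must lie strictly in (0, 1)")
    if R0_nm <= 0:
        raise ValidationError("R0 must be > 0")
    return R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


def fret_validity(r_nm: float, R0_nm: float) -> tuple[bool, dict]:
    """Check 0.5 R0 <= r <= 1.5 R0 (closed interval) and the 2-8 nm window.

    Distances satisfying the half-to-1.5 R0 band are the regime where a
    single static donor-acceptor pair explains the quenching.
    """
    if r_nm <= 0 or R0_nm <= 0:
        raise ValidationError("distances must be > 0")
    ok = 0.5 * R0_nm <= r_nm <= 1.5 * R0_nm
    lo, hi = FRET_WINDOW_NM
    report = {
        "valid_range": ok,
        "r_nm": r_nm,
        "R0_nm": R0_nm,
        "r_over_R0": r_nm / R0_nm,
        "r_in_window": lo <= r_nm <= hi,
        "R0_in_window": lo <= R0_nm <= hi,
    }
    return ok, report


def compute_fret(
    donor_em: Spectrum,
    acceptor_eps: Spectrum,
    F: float,
    F0: float,
    kappa2: float = DEFAULT_KAPPA2,
    refr_index: float = DEFAULT_REFRACTIVE_INDEX,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> FretResult:
    """Full FRET chain: J -> R0 -> E -> r -> validity."""
    J = overlap_integral(donor_em, acceptor_eps)
    R0 = forster_radius(J, kappa2=kappa2, refr_index=refr_index, phi=phi)
    E = transfer_efficiency(F, F0)
    r = donor_acceptor_distance(E, R0)
    ok, report = fret_validity(r, R0)
    return FretResult(
        J_M_cm3=J,
        R0_nm=R0,
        E=E,
        r_nm=r,
        valid_range=ok,
        in_fret_window=report["r_in_window"] and report["R0_in_window"],
        kappa2=kappa2,
        refr_index=refr_index,
        phi_donor=phi,
    )
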