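"""Conformational probes: peak picking, EEM peak analysis, synchronous scans.

Spectral peaks (e.g. the heme Soret band near 410 nm, tryptophan emission
near 340 nm) are located by argmax on the sampled grid — no sub-sample
interpolation, since instrument steps of 1-10 nm make parabolic refinement
false precision. Excitation-emission matrices are searched for local maxima
after masking first- and second-order Rayleigh scatter ridges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .spectra import EEM, Spectrum, ValidationError

__all__ = [
    "PeakSummary",
    "find_peak",
    "compare_to_reference",
    "eem_peaks",
    "synchronous_summary",
]

#: Half-width (nm) of the Rayleigh scatter masks around λem = λex and λem = 2 λex.
DEFAULT_SCATTER_HALFWIDTH_NM = 20.0


@dataclass(frozen=True)
class PeakSummary:
    """A located peak, optionally compared against a reference condition.

    ``position_nm`` is a wavelength for 1-D spectra or an (excitation,
    emission) pair for EEM peaks. ``shift_nm`` is signed, on the emission
    axis; negative means a blue shift.
    """

    position_nm: float | tuple[float, float]
    intensity: float
    percent_of_reference: float | None = None
    shift_nm: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.intensity < 0:
            raise ValidationError("peak intensity must be >= 0")
        if self.percent_of_reference is not None and self.percent_of_reference < 0:
            raise ValidationError("percent_of_reference must be >= 0")

    @property
    def emission_position_nm(self) -> float:
        p = self.position_nm
        return float(p[1]) if isinstance(p, tuple) else float(p)

    def percent_rounded(self) -> float | None:
        """Report-time rounding to 1 decimal; internal value stays full precision."""
        if self.percent_of_reference is None:
            return None
        return round(self.percent_of_reference, 1)


def find_peak(spec: Spectrum, window_nm: tuple[float, float] | None = None) -> PeakSummary:
    """Position and intensity of the maximum sample within a window.

    Ties break toward the shorter wavelength. A monotone spectrum returns
    the boundary point.
    """
    if window_nm is None:
        window_nm = spec.support
    lo, hi = float(window_nm[0]), float(window_nm[1])
    mask = (spec.wavelength_nm >= lo) & (spec.wavelength_nm <= hi)
    if not np.any(mask):
        raise ValidationError(f"window [{lo}, {hi}] nm contains no samples")
    wl = spec.wavelength_nm[mask]
    it = spec.intensity[mask]
    i = int(np.argmax(it))  # argmax returns the first (shortest-wavelength) maximum
    return PeakSummary(position_nm=float(wl[i]), intensity=float(it[i]), label=spec.label)


def compare_to_reference(sample_peak: PeakSummary, reference_peak: PeakSummary) -> PeakSummary:
    """Express a peak as percent of a reference peak, with the emission shift."""
    if reference_peak.intensity <= 0:
        raise ValidationError("reference peak intensity must be > 0")
    percent = 100.0 * sample_peak.intensity / reference_peak.intensity
    shift = sample_peak.emission_position_nm - reference_peak.emission_position_nm
    return PeakSummary(
        position_nm=sample_peak.position_nm,
        intensity=sample_peak.intensity,
        percent_of_reference=percent,
        shift_nm=shift,
        label=sample_peak.label,
    )


def _scatter_mask(eem: EEM, halfwidth_nm: float) -> np.ndarray:
    """True where a cell sits on a Rayleigh scatter ridge (to be excluded)."""
    ex = eem.excitation_nm[:, None]
    em = eem.emission_nm[None, :]
    first = np.abs(em - ex) < halfwidth_nm
    second = np.abs(em - 2.0 * ex) < halfwidth_nm
    return first | second


def eem_peaks(
    eem: EEM,
    n_peaks: int = 2,
    scatter_halfwidth_nm: float = DEFAULT_SCATTER_HALFWIDTH_NM,
    min_separation_nm: float = 20.0,
    rel_threshold: float = 0.05,
) -> list[PeakSummary]:
    """Top-n local maxima of an EEM, Rayleigh scatter excluded.

    A cell is a local maximum if it attains the neighbourhood maximum of its
    3x3 surroundings and is strictly positive. First-order (λem ≈ λex) and
    second-order (λem ≈ 2 λex) scatter diagonals are masked before the
    search; candidates below ``rel_threshold`` of the brightest unmasked
    cell are rejected (this suppresses noise-floor bumps and spurious
    maxima hugging the mask boundary), and candidates closer than
    ``min_separation_nm`` (on either axis) to an already accepted stronger
    peak are merged into it. Returns peaks sorted by intensity descending;
    may return fewer than ``n_peaks``. An all-masked or flat matrix returns
    an empty list.
    """
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    masked = _scatter_mask(eem, scatter_halfwidth_nm)
    z = np.where(masked, -np.inf, eem.intensity)
    if not np.any(np.isfinite(z)):
        warnings.warn("every EEM cell lies on a scatter ridge; no peaks", UserWarning)
        return []
    floor = rel_threshold * float(np.max(z[np.isfinite(z)]))
    local_max = ndimage.maximum_filter(z, size=3, mode="nearest") == z
    candidates = np.argwhere(
        local_max & np.isfinite(z) & (eem.intensity > 0) & (eem.intensity >= floor) & ~masked
    )
    # strongest first; ties toward shorter wavelengths via stable lexical order
    order = np.lexsort(
        (candidates[:, 1], candidates[:, 0], -eem.intensity[candidates[:, 0], candidates[:, 1]])
    )
    peaks: list[PeakSummary] = []
    taken: list[tuple[float, float]] = []
    for idx in order:
        i, j = candidates[idx]
        ex, em = float(eem.excitation_nm[i]), float(eem.emission_nm[j])
        if any(
            abs(ex - tx) < min_separation_nm and abs(em - tm) < min_separation_nm
            for tx, tm in taken
        ):
            continue
        peaks.append(
            PeakSummary(
                position_nm=(ex, em),
                intensity=float(eem.intensity[i, j]),
                label=eem.label,
            )
        )
        taken.append((ex, em))
        if len(peaks) == n_peaks:
            break
    if not peaks:
        warnings.warn("no unmasked local maxima found in EEM", UserWarning)
    return peaks


def synchronous_summary(
    spectra: list[Spectrum],
    delta_nm: int,
    reference_index: int = 0,
    window_nm: tuple[float, float] | None = None,
) -> list[PeakSummary]:
    """Per-spectrum peak summaries of a synchronous-scan series.

    ``delta_nm`` is the fixed excitation-emission offset (15 nm probes
    tyrosine, 60 nm tryptophan microenvironments). Each spectrum's peak is
    expressed relative to the reference (typically the ligand-free, 1:0
    molar-ratio scan): percent intensity and signed emission shift.
    """
    if delta_nm not in (15, 60):
        raise ValidationError("delta_nm must be 15 (Tyr) or 60 (Trp)")
    if not spectra:
        raise ValidationError("no spectra given")
    if any(s.kind != "synchronous" for s in spectra):
        raise ValidationError("all spectra must have kind='synchronous'")
    if not (0 <= reference_index < len(spectra)):
        raise ValidationError(f"reference index {reference_index} out of range")
    ref = find_peak(spectra[reference_index], window_nm)
    return [compare_to_reference(find_peak(s, window_nm), ref) for s in spectra]
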