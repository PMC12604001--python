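"""Data model and plain-text I/O for spectra, EEMs, and titration tables.

All wavelengths are in nanometres at the interface. Intensities are in
arbitrary units except ``kind="molar_absorption"``, where they are molar
absorptivities in M^-1 cm^-1 (the FRET overlap integral needs absolute
units; emission spectra do not, because the normalisation cancels).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECTRUM_KINDS",
    "Spectrum",
    "EEM",
    "TitrationPoint",
    "TitrationSeries",
    "ParseError",
    "ValidationError",
    "read_spectrum",
    "write_spectrum",
    "read_eem",
    "write_eem",
    "read_titration",
    "write_titration",
    "resample",
]

SPECTRUM_KINDS = ("emission", "absorption", "molar_absorption", "synchronous", "cd")

#: Unquenched donor fluorescence lifetime (s) used to convert K_SV to k_q.
DEFAULT_TAU0_S = 5.71e-9


class ParseError(ValueError):
    """A text file could not be parsed into the expected table."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical curve: intensity versus wavelength.

    Parameters
    ----------
    wavelength_nm : array-like
        Strictly increasing wavelengths in nm, length >= 2.
    intensity : array-like
        Same length as ``wavelength_nm``. Arbitrary units, or M^-1 cm^-1
        when ``kind == "molar_absorption"`` (must then be non-negative).
    kind : str
        One of ``emission, absorption, molar_absorption, synchronous, cd``.
    label : str
        Free-text label carried through reports.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"
    label: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if self.kind not in SPECTRUM_KINDS:
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValidationError("wavelength and intensity must be 1-D and equal length")
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise ValidationError("non-finite values in spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.kind == "molar_absorption" and np.any(it < 0):
            raise ValidationError("molar absorptivities must be >= 0")

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])


@dataclass(frozen=True)
class EEM:
    """An excitation-emission matrix: intensity over a 2-D wavelength grid."""

    excitation_nm: np.ndarray
    emission_nm: np.ndarray
    intensity: np.ndarray  # shape (n_excitation, n_emission)
    label: str = ""

    def __post_init__(self):
        ex = np.asarray(self.excitation_nm, dtype=float)
        em = np.asarray(self.emission_nm, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation_nm", ex)
        object.__setattr__(self, "emission_nm", em)
        object.__setattr__(self, "intensity", z)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise ValidationError("EEM axes must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise ValidationError(
                f"EEM matrix shape {z.shape} does not match axes ({ex.size}, {em.size})"
            )
        if not np.all(np.isfinite(z)):
            raise ValidationError("non-finite EEM intensities")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration measurement: quencher concentration plus observed signal.

    ``A_ex`` and ``A_em`` are the absorbances of the titrated species at the
    excitation and emission wavelengths, used for inner-filter correction.
    """

    quencher_conc_M: float
    intensity_obs: float
    A_ex: float = 0.0
    A_em: float = 0.0

    def __post_init__(self):
        vals = (self.quencher_conc_M, self.intensity_obs, self.A_ex, self.A_em)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("non-finite titration point")
        if self.quencher_conc_M < 0:
            raise ValidationError("negative quencher concentration")
        if self.intensity_obs <= 0:
            raise ValidationError("observed intensity must be > 0")
        if self.A_ex < 0 or self.A_em < 0:
            raise ValidationError("negative absorbance")
        if self.A_ex >= 3 or self.A_em >= 3:
            raise ValidationError("absorbance >= 3 is outside the sane assay range")


@dataclass(frozen=True)
class TitrationSeries:
    """A per-temperature fluorescence titration.

    Invariants: at least 3 points, concentrations non-decreasing, and exactly
    one zero-concentration point (the F0 reference).
    """

    temperature_K: float
    points: tuple[TitrationPoint, ...]
    excitation_nm: float = 295.0
    protein_conc_M: float = 5e-6
    tau0_s: float = DEFAULT_TAU0_S
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        if self.temperature_K <= 0:
            raise ValidationError("temperature must be > 0 K")
        if self.protein_conc_M <= 0 or self.tau0_s <= 0:
            raise ValidationError("protein concentration and tau0 must be > 0")
        if len(self.points) < 3:
            raise ValidationError("a titration needs at least 3 points")
        conc = np.array([p.quencher_conc_M for p in self.points])
        if np.any(np.diff(conc) < 0):
            raise ValidationError("quencher concentrations must be non-decreasing")
        n_zero = int(np.sum(conc == 0.0))
        if n_zero != 1:
            raise ValidationError(
                f"exactly one zero-concentration (F0) point required, found {n_zero}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def conc_M(self) -> np.ndarray:
        return np.array([p.quencher_conc_M for p in self.points])

    @property
    def intensity_obs(self) -> np.ndarray:
        return np.array([p.intensity_obs for p in self.points])

    @property
    def A_ex(self) -> np.ndarray:
        return np.array([p.A_ex for p in self.points])

    @property
    def A_em(self) -> np.ndarray:
        return np.array([p.A_em for p in self.points])


_DELIMS = (",", "\t", None)  # None -> any whitespace


def _parse_row(line: str) -> list[str] | None:
    """Split a data line on comma, tab, or whitespace; None for blank."""
    s = line.strip()
    if not s or s.startswith("#"):
        return None
    for d in _DELIMS:
        parts = [p.strip() for p in s.split(d)] if d else s.split()
        parts = [p for p in parts if p]
        if len(parts) >= 2:
            return parts
    return [s]


def read_spectrum(path, kind: str = "emission", label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, intensity) delimited text file.

    Comma-, tab-, or whitespace-delimited; lines starting with ``#`` are
    ignored. Rows may appear in any order; the result is sorted by
    wavelength. Duplicate wavelengths are rejected.
    """
    path = Path(path)
    wl, it = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        parts = _parse_row(line)
        if parts is None:
            continue
        if len(parts) < 2:
            raise ParseError(f"{path.name}:{lineno}: expected two columns, got {line!r}")
        try:
            wl.append(float(parts[0]))
            it.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: non-numeric value in {line!r}") from exc
    if len(wl) < 2:
        raise ValidationError(f"{path.name}: a spectrum needs at least 2 points")
    wl = np.asarray(wl)
    it = np.asarray(it)
    order = np.argsort(wl, kind="stable")
    wl, it = wl[order], it[order]
    if np.any(np.diff(wl) == 0):
        dup = wl[:-1][np.diff(wl) == 0][0]
        raise ValidationError(f"{path.name}: duplicate wavelength {dup} nm")
    return Spectrum(wl, it, kind=kind, label=path.stem if label is None else label)


def write_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum as 2-column CSV with a ``# kind=`` header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={spec.kind} label={spec.label}\n")
        for w, i in zip(spec.wavelength_nm, spec.intensity):
            fh.write(f"{float(w)!r},{float(i)!r}\n")


def read_eem(path, label: str | None = None) -> EEM:
    """Read a matrix CSV: first row emission grid, first column excitation grid."""
    path = Path(path)
    raw = pd.read_csv(path, header=None, comment="#").to_numpy(dtype=float)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ParseError(f"{path.name}: EEM matrix needs a header row and column")
    em = raw[0, 1:]
    ex = raw[1:, 0]
    return EEM(ex, em, raw[1:, 1:], label=path.stem if label is None else label)


def write_eem(eem: EEM, path) -> None:
    path = Path(path)
    top = np.concatenate([[np.nan], eem.emission_nm])
    body = np.column_stack([eem.excitation_nm, eem.intensity])
    full = np.vstack([top, body])
    # corner cell is a placeholder; readers ignore it
    with path.open("w") as fh:
        for r, row in enumerate(full):
            cells = ["" if (r == 0 and c == 0) else repr(float(v)) for c, v in enumerate(row)]
            fh.write(",".join(cells) + "\n")


_TITRATION_COLS = ("conc_M", "intensity", "A_ex", "A_em")


def read_titration(path, metadata: dict | None = None) -> TitrationSeries:
    """Read a titration CSV with header ``conc_M,intensity,A_ex,A_em``.

    The absorbance columns are optional (default 0). ``metadata`` supplies
    ``temperature_K`` (required), and optionally ``excitation_nm``,
    ``protein_conc_M``, ``tau0_s``, ``label``.
    """
    path = Path(path)
    metadata = dict(metadata or {})
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("conc_M", "intensity") if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing required column(s) {missing}")
    for c in ("A_ex", "A_em"):
        if c not in df.columns:
            df[c] = 0.0
    df = df.sort_values("conc_M", kind="stable")
    points = [
        TitrationPoint(row.conc_M, row.intensity, row.A_ex, row.A_em)
        for row in df.itertuples()
    ]
    if "temperature_K" not in metadata:
        raise ValidationError(f"{path.name}: metadata must provide temperature_K")
    return TitrationSeries(
        temperature_K=float(metadata["temperature_K"]),
        points=tuple(points),
        excitation_nm=float(metadata.get("excitation_nm", 295.0)),
        protein_conc_M=float(metadata.get("protein_conc_M", 5e-6)),
        tau0_s=float(metadata.get("tau0_s", DEFAULT_TAU0_S)),
        label=str(metadata.get("label", path.stem)),
    )


def write_titration(series: TitrationSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# temperature_K={series.temperature_K!r} excitation_nm={series.excitation_nm!r}"
            f" protein_conc_M={series.protein_conc_M!r} tau0_s={series.tau0_s!r}\n"
        )
        fh.write("conc_M,intensity,A_ex,A_em\n")
        for p in series.points:
            fh.write(
                f"{float(p.quencher_conc_M)!r},{float(p.intensity_obs)!r},"
                f"{float(p.A_ex)!r},{float(p.A_em)!r}\n"
            )


def resample(spec: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    The grid must be strictly increasing and lie within the spectrum's
    support — no extrapolation, ever (silent extrapolation corrupts
    overlap integrals). Values at original grid nodes are preserved
    exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError("resample grid must be a 1-D sequence")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValidationError("resample grid must be strictly increasing")
    lo, hi = spec.support
    if grid[0] < lo or grid[-1] > hi:
        raise ValidationError(
            f"grid [{grid[0]}, {grid[-1]}] outside spectral support [{lo}, {hi}]"
        )
    vals = np.interp(grid, spec.wavelength_nm, spec.intensity)
    if grid.size == 1:
        # Spectrum requires >= 2 points; a single-node query returns a
        # degenerate 2-point spectrum is not meaningful, so return value via
        # a length check is avoided: callers wanting one value use np.interp.
        raise ValidationError("resample grid needs at least 2 points; use interp_at for one")
    return Spectrum(grid, vals, kind=spec.kind, label=spec.label)


def interp_at(spec: Spectrum, wavelength_nm: float) -> float:
    """Interpolate a single intensity value (no extrapolation)."""
    lo, hi = spec.support
    if not (lo <= wavelength_nm <= hi):
        raise ValidationError(f"{wavelength_nm} nm outside spectral support [{lo}, {hi}]")
    return float(np.interp(wavelength_nm, spec.wavelength_nm, spec.intensity))
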