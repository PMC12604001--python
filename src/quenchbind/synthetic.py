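"""Seeded synthetic-data generators for the full analysis chain.

The generators emulate a tryptophan-quenching titration assay: a 5 uM
hemoglobin donor excited at 295 nm with a ~340 nm emission band, titrated
with 0-50 uM of an absorbing ligand at 298/303/310 K. Quenching follows the
static ground-state-complex model the analysis fits, (F0-F)/F = Ka [Q]^n,
with Ka(T) set by a van't Hoff pair (dH, dS). Ligand absorbances grow
linearly with concentration so inner-filter correction inverts exactly, and
multiplicative Gaussian noise is applied last. A single integer seed drives
every stochastic draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .spectra import EEM, Spectrum, TitrationPoint, TitrationSeries, ValidationError
from .thermo import R_CAL_PER_MOL_K

__all__ = [
    "GeneratorConfig",
    "ka_at_temperature",
    "make_titration",
    "make_fret_pair",
    "make_eem",
    "make_emission_spectra",
]

_DEFAULT_GRID_M = tuple(np.linspace(0.0, 50e-6, 11))


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters for the synthetic assay.

    ``Ka_ref_per_M`` is used only when ``dH_kcal`` is None (fixed-affinity,
    temperature-independent generation); otherwise Ka(T) follows
    exp(-dH/(R T) + dS/R) with R = 1.987 cal/(mol K).
    """

    seed: int = 0
    Ka_ref_per_M: float | None = None
    n_sites: float = 1.0
    dH_kcal: float | None = 22.42
    dS_cal: float | None = 91.39
    temperatures_K: tuple[float, ...] = (298.0, 303.0, 310.0)
    quencher_grid_M: tuple[float, ...] = _DEFAULT_GRID_M
    protein_conc_M: float = 5e-6
    excitation_nm: float = 295.0
    tau0_s: float = 5.71e-9
    F0_au: float = 1000.0
    em_center_nm: float = 340.0
    em_sigma_nm: float = 15.0
    blue_shift_max_nm: float = 3.0
    eps_ex_per_M_cm: float = 4.0e3   # ligand absorptivity at the excitation line
    eps_em_per_M_cm: float = 1.0e3   # and at the emission maximum
    path_cm: float = 1.0
    acceptor_center_nm: float = 358.0
    acceptor_sigma_nm: float = 30.0
    acceptor_peak_eps_per_M_cm: float = 1.7e4
    eem_noise_floor_au: float = 0.2
    noise_rel_sd: float = 0.0

    def __post_init__(self):
        if self.noise_rel_sd < 0:
            raise ValidationError("noise_rel_sd must be >= 0")
        grid = np.asarray(self.quencher_grid_M, dtype=float)
        if 0.0 not in grid:
            raise ValidationError("quencher grid must contain 0 (the F0 reference)")
        if np.any(grid < 0):
            raise ValidationError("negative quencher concentrations")
        if self.dH_kcal is None and self.Ka_ref_per_M is None:
            raise ValidationError("need either (dH_kcal, dS_cal) or Ka_ref_per_M")
        if (self.dH_kcal is None) != (self.dS_cal is None):
            raise ValidationError("dH_kcal and dS_cal must be given together")
        if self.n_sites <= 0 or self.F0_au <= 0:
            raise ValidationError("n_sites and F0 must be > 0")
        object.__setattr__(self, "temperatures_K", tuple(float(t) for t in self.temperatures_K))
        object.__setattr__(self, "quencher_grid_M", tuple(float(q) for q in grid))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def ka_at_temperature(cfg: GeneratorConfig, T_K: float) -> float:
    """Ground-truth Ka(T): van't Hoff form, or the fixed reference value."""
    if cfg.dH_kcal is None:
        return float(cfg.Ka_ref_per_M)
    dH_cal = cfg.dH_kcal * 1000.0
    return float(np.exp(-dH_cal / (R_CAL_PER_MOL_K * T_K) + cfg.dS_cal / R_CAL_PER_MOL_K))


def make_titration(cfg: GeneratorConfig) -> list[TitrationSeries]:
    """One synthetic titration series per configured temperature.

    Forward model, inverted exactly by the analysis chain when noise is 0:
    true F = F0 / (1 + Ka [Q]^n); A_ex/A_em = eps * [Q] * path; the observed
    intensity is the true one attenuated by the inner-filter factor
    10^((A_ex+A_em)/2); multiplicative Gaussian noise last.
    """
    rng = cfg.rng()
    out = []
    for T in cfg.temperatures_K:
        Ka = ka_at_temperature(cfg, T)
        points = []
        for q in cfg.quencher_grid_M:
            F_true = cfg.F0_au / (1.0 + Ka * q**cfg.n_sites) if q > 0 else cfg.F0_au
            A_ex = cfg.eps_ex_per_M_cm * q * cfg.path_cm
            A_em = cfg.eps_em_per_M_cm * q * cfg.path_cm
            F_obs = F_true / 10.0 ** ((A_ex + A_em) / 2.0)
            if cfg.noise_rel_sd > 0:
                F_obs *= 1.0 + rng.normal(0.0, cfg.noise_rel_sd)
                F_obs = max(F_obs, 1e-12)
            points.append(TitrationPoint(q, F_obs, A_ex, A_em))
        out.append(
            TitrationSeries(
                temperature_K=T,
                points=tuple(points),
                excitation_nm=cfg.excitation_nm,
                protein_conc_M=cfg.protein_conc_M,
                tau0_s=cfg.tau0_s,
                label=f"synthetic_{T:g}K",
            )
        )
    return out


def _gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def make_fret_pair(cfg: GeneratorConfig) -> tuple[Spectrum, Spectrum]:
    """Gaussian donor emission and Gaussian acceptor molar absorptivity.

    Both on a 1 nm grid over 250-450 nm. Defaults place the acceptor band
    so the overlap integral lands near 1.9e-14 M^-1 cm^3 (Förster radius
    ~2.7 nm), the scale typical of a tryptophan donor and a dihydropyridine
    acceptor.
    """
    lam = np.arange(250.0, 450.0 + 0.5, 1.0)
    donor = Spectrum(
        lam, _gaussian(lam, cfg.em_center_nm, cfg.em_sigma_nm),
        kind="emission", label="synthetic_donor",
    )
    acceptor = Spectrum(
        lam,
        cfg.acceptor_peak_eps_per_M_cm * _gaussian(lam, cfg.acceptor_center_nm, cfg.acceptor_sigma_nm),
        kind="molar_absorption",
        label="synthetic_acceptor",
    )
    return donor, acceptor


#: Ground-truth EEM peak positions (excitation, emission) and amplitudes:
#: an aromatic side-chain band and a peptide-backbone band.
EEM_PEAK1 = (280.0, 334.0, 1046.0)
EEM_PEAK2 = (230.0, 326.0, 523.0)


def make_eem(
    cfg: GeneratorConfig,
    quench_factors: tuple[float, float] = (1.0, 1.0),
    shift_nm: tuple[float, float] = (0.0, 0.0),
    excitation_grid_nm: np.ndarray | None = None,
    emission_grid_nm: np.ndarray | None = None,
    sigma_nm: float = 12.0,
) -> EEM:
    """Two-peak synthetic excitation-emission matrix.

    Peaks at (280, 334) and (230, 326) nm with amplitudes 1046 and 523 a.u.,
    scaled by ``quench_factors`` (each in [0, 1]) and shifted along the
    emission axis by ``shift_nm`` (negative = blue). A small seeded uniform
    noise floor is added everywhere. Default grids: 1 nm, excitation
    200-400 nm, emission 200-500 nm.
    """
    if not all(0.0 <= f <= 1.0 for f in quench_factors):
        raise ValidationError("quench factors must lie in [0, 1]")
    ex = np.arange(200.0, 400.0 + 0.5, 1.0) if excitation_grid_nm is None else np.asarray(
        excitation_grid_nm, dtype=float
    )
    em = np.arange(200.0, 500.0 + 0.5, 1.0) if emission_grid_nm is None else np.asarray(
        emission_grid_nm, dtype=float
    )
    z = np.zeros((ex.size, em.size))
    for (ex0, em0, amp), f, dshift in zip(
        (EEM_PEAK1, EEM_PEAK2), quench_factors, shift_nm
    ):
        z += (
            f
            * amp
            * _gaussian(ex, ex0, sigma_nm)[:, None]
            * _gaussian(em, em0 + dshift, sigma_nm)[None, :]
        )
    if cfg.eem_noise_floor_au > 0:
        z += cfg.rng().uniform(0.0, cfg.eem_noise_floor_au, size=z.shape)
    return EEM(ex, em, z, label="synthetic_eem")


def make_emission_spectra(cfg: GeneratorConfig, temperature_K: float | None = None) -> list[Spectrum]:
    """Per-concentration emission spectra with a concentration-proportional blue shift.

    The band center moves linearly from ``em_center_nm`` at [Q] = 0 to
    ``em_center_nm - blue_shift_max_nm`` at the top of the quencher grid,
    and the amplitude follows the same static-quenching model as
    :func:`make_titration`. Returned as kind='synchronous' scans suitable
    for :func:`~quenchbind.conformation.synchronous_summary`.
    """
    T = cfg.temperatures_K[0] if temperature_K is None else temperature_K
    Ka = ka_at_temperature(cfg, T)
    lam = np.arange(280.0, 420.0 + 0.5, 1.0)
    qmax = max(cfg.quencher_grid_M)
    out = []
    for q in cfg.quencher_grid_M:
        amp = cfg.F0_au / (1.0 + Ka * q**cfg.n_sites) if q > 0 else cfg.F0_au
        center = cfg.em_center_nm - cfg.blue_shift_max_nm * (q / qmax if qmax > 0 else 0.0)
        out.append(
            Spectrum(
                lam,
                amp * _gaussian(lam, center, cfg.em_sigma_nm),
                kind="synchronous",
                label=f"synthetic_em_q{q:.2e}",
            )
        )
    return out


def config_manifest(cfg: GeneratorConfig) -> dict:
    """JSON-serialisable record of the seed and true parameters."""
    d = asdict(cfg)
    d["temperatures_K"] = list(cfg.temperatures_K)
    d["quencher_grid_M"] = list(cfg.quencher_grid_M)
    return d
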