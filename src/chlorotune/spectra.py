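"""Absorption spectrum synthesis: Gaussian broadening of exciton stick
spectra, static-disorder ensemble averaging, and reference-peak alignment.

The ensemble average emulates what an MD-sampled calculation provides:
snapshot-to-snapshot variation of the site energies, modelled as i.i.d.
diagonal Gaussian noise.  Alignment rigidly shifts the energy grid so a
chosen peak lands on a reference energy — the shift is recorded, never
silently applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import HC_EV_NM
from .excitonics import ExcitonSystem, diagonalize, oscillator_strengths
from .pigment_geometry import Pigment

#: default Gaussian FWHM, eV (typical chlorophyll Q_y band visual width)
DEFAULT_FWHM = 0.06

#: default energy grid: visible/NIR Q-band region
DEFAULT_GRID = (1.4, 2.2, 2000)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Spectrum:
    """Absorption curve on a strictly ascending energy grid (eV)."""

    energy_grid: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.energy_grid.ndim != 1 or (np.diff(self.energy_grid) <= 0).any():
            raise ValueError("energy grid must be strictly ascending")
        if self.energy_grid.shape != self.intensity.shape:
            raise ValueError("grid and intensity must have the same length")
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.energy_grid))

    def local_maxima(self) -> np.ndarray:
        """Grid energies of the interior local maxima."""
        y = self.intensity
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
        return self.energy_grid[1:-1][interior]

    def moments(self) -> tuple[float, float]:
        """Intensity-weighted mean and standard deviation of the curve."""
        w = self.intensity / self.intensity.sum()
        mean = float(w @ self.energy_grid)
        var = float(w @ (self.energy_grid - mean) ** 2)
        return mean, np.sqrt(var)


def default_grid() -> np.ndarray:
    lo, hi, n = DEFAULT_GRID
    return np.linspace(lo, hi, n)


def broaden(
    stick_energies: Sequence[float],
    strengths: Sequence[float],
    fwhm: float = DEFAULT_FWHM,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Sum of area-normalized Gaussians, one per stick, each scaled by its
    oscillator strength; the integrated area equals the summed strengths
    (to grid quadrature accuracy).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    e = np.asarray(stick_energies, dtype=float)
    f = np.asarray(strengths, dtype=float)
    if e.shape != f.shape:
        raise ValueError("stick energies and strengths differ in length")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if e.size and (
        grid[0] > e.min() - 3 * fwhm or grid[-1] < e.max() + 3 * fwhm
    ):
        raise ValueError(
            f"grid [{grid[0]:.3f}, {grid[-1]:.3f}] eV does not span the "
            f"sticks +/- 3*fwhm"
        )
    sigma = fwhm * _FWHM_TO_SIGMA
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    y = np.zeros_like(grid)
    for ek, fk in zip(e, f):
        y += fk * norm * np.exp(-0.5 * ((grid - ek) / sigma) ** 2)
    return Spectrum(grid, y, {"fwhm": fwhm, "alignment_shift": 0.0, "n_ensemble": 1})


def ensemble_spectrum(
    base: ExcitonSystem,
    disorder_sigma: float,
    n: int,
    seed: int,
    *,
    fwhm: float = DEFAULT_FWHM,
    grid: np.ndarray | None = None,
    pigments: Sequence[Pigment] | None = None,
) -> Spectrum:
    """Static-disorder-averaged spectrum: the mean of ``n`` broadened
    spectra whose site energies are perturbed by i.i.d. Gaussian noise of
    width ``disorder_sigma`` (eV).

    A fixed seed makes the result bit-reproducible; sigma = 0 reduces to
    the single-system spectrum.  Without a pigment list all sticks carry
    unit strength.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if disorder_sigma < 0:
        raise ValueError("disorder_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)

    def one(sys: ExcitonSystem) -> Spectrum:
        states = diagonalize(sys)
        if pigments is not None:
            f = oscillator_strengths(states, pigments)
        else:
            f = np.ones_like(states.energies)
        return broaden(states.energies, f, fwhm=fwhm, grid=grid)

    if disorder_sigma == 0.0:
        spec = one(base)
        spec.metadata["n_ensemble"] = n
        return spec

    total = np.zeros_like(grid)
    for _ in range(n):
        noise = rng.normal(0.0, disorder_sigma, size=base.n_sites)
        perturbed = ExcitonSystem(
            pigment_ids=list(base.pigment_ids),
            site_energies=base.site_energies + noise,
            couplings=base.couplings,
            model_label=base.model_label,
        )
        total += one(perturbed).intensity
    return Spectrum(
        grid,
        total / n,
        {"fwhm": fwhm, "alignment_shift": 0.0, "n_ensemble": n,
         "disorder_sigma": disorder_sigma, "seed": seed},
    )


def align_to_reference(spec: Spectrum, reference_peak: float) -> Spectrum:
    """Rigidly shift the energy grid so the local maximum nearest the
    reference energy coincides with it.

    A pure translation: pairwise peak separations are unchanged.  The
    applied shift is recorded in ``metadata['alignment_shift']``.  A
    nearest-distance tie is broken toward the higher-energy peak.
    """
    peaks = spec.local_maxima()
    if peaks.size == 0:
        raise ValueError("spectrum has no local maximum to align")
    dist = np.abs(peaks - reference_peak)
    best = dist.min()
    chosen = peaks[np.isclose(dist, best)].max()  # tie -> higher energy
    shift = float(reference_peak - chosen)
    meta = dict(spec.metadata)
    meta["alignment_shift"] = meta.get("alignment_shift", 0.0) + shift
    return Spectrum(spec.energy_grid + shift, spec.intensity.copy(), meta)


def ev_to_nm(e_ev: float) -> float:
    """Photon wavelength (nm) from energy (eV): lambda = hc / E."""
    if e_ev <= 0:
        raise ValueError("energy must be positive")
    return HC_EV_NM / e_ev


def nm_to_ev(lambda_nm: float) -> float:
    """Photon energy (eV) from wavelength (nm)."""
    if lambda_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / lambda_nm


def report_nm(e_ev: float) -> int:
    """Wavelength rounded to integer nm, the usual reporting style."""
    return int(round(ev_to_nm(e_ev)))


def report_ev(e_ev: float) -> float:
    """Energy rounded to 3 decimals (eV), the usual reporting style."""
    return round(e_ev, 3)
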