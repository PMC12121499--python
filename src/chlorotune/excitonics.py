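"""Frenkel exciton model in the site basis.

The exciton Hamiltonian carries the pigment Q_y site energies on its
diagonal and the excitonic couplings V_ij off-diagonal.  Its eigenstates
are the observable transitions; oscillator strengths follow from the
exciton transition dipoles, and the participation ratio quantifies how
many sites share each excitation (1 = localized, N = fully delocalized).

Energies are eV internally; couplings may enter in cm^-1 at the I/O
boundary.  Couplings can either be supplied as tables (e.g. published FED
values) or estimated from structure with the point-dipole approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    CM1_PER_EV,
    DIPOLE_COUPLING_PREFACTOR,
    OSC_STRENGTH_PREFACTOR,
    cm1_to_ev,
    ev_to_cm1,
)
from .pigment_geometry import Pigment

#: exciton states with oscillator strength below this are reported "dark"
DARK_THRESHOLD = 1e-4

#: default empirical dielectric screening for pigment-protein couplings
DEFAULT_SCREENING = 0.72

_SITE_ENERGY_WINDOW = (0.5, 4.0)  # eV sanity window for visible/NIR Q bands


@dataclass
class ExcitonSystem:
    """N pigments with Q_y site energies (eV) and a symmetric coupling
    matrix (eV, zero diagonal): the site-basis exciton Hamiltonian."""

    pigment_ids: list[str]
    site_energies: np.ndarray
    couplings: np.ndarray
    model_label: str = ""

    def __post_init__(self) -> None:
        self.site_energies = np.asarray(self.site_energies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        n = len(self.pigment_ids)
        if self.site_energies.shape != (n,):
            raise ValueError("site_energies length must match pigment_ids")
        if self.couplings.shape != (n, n):
            raise ValueError("couplings must be an NxN matrix")
        if not np.allclose(self.couplings, self.couplings.T, atol=1e-12):
            raise ValueError("couplings matrix must be symmetric")
        if np.abs(np.diag(self.couplings)).max(initial=0.0) > 1e-12:
            raise ValueError("couplings diagonal must be zero")
        lo, hi = _SITE_ENERGY_WINDOW
        if ((self.site_energies <= lo) | (self.site_energies >= hi)).any():
            raise ValueError(
                f"site energies outside the sanity window {_SITE_ENERGY_WINDOW} eV"
            )

    @property
    def n_sites(self) -> int:
        return len(self.pigment_ids)

    def hamiltonian(self) -> np.ndarray:
        return np.diag(self.site_energies) + self.couplings

    def site_index(self, pigment_id: str) -> int:
        try:
            return self.pigment_ids.index(pigment_id)
        except ValueError:
            raise KeyError(
                f"unknown site {pigment_id!r}; known: {self.pigment_ids}"
            ) from None


@dataclass
class ExcitonStates:
    """Eigen-decomposition of an ExcitonSystem.

    ``coefficients[k, i]`` is the amplitude of site i in exciton state k;
    rows are orthonormal.  Energies ascend; sum(energies) equals the sum of
    site energies (trace conservation).
    """

    pigment_ids: list[str]
    energies: np.ndarray
    coefficients: np.ndarray
    participation_ratios: np.ndarray
    oscillator_strengths: np.ndarray | None = None

    def is_dark(self) -> np.ndarray:
        if self.oscillator_strengths is None:
            raise ValueError("oscillator strengths not computed")
        return self.oscillator_strengths < DARK_THRESHOLD


def point_dipole_coupling(
    p1: Pigment, p2: Pigment, screening_f: float = DEFAULT_SCREENING
) -> float:
    """Excitonic coupling (cm^-1) in the point-dipole approximation.

    V = 5034.1 * f * kappa * mu1*mu2 / R^3, with transition dipoles in
    Debye, the center-center distance R in angstrom, and the orientation
    factor kappa = mu1.mu2 - 3 (mu1.R)(mu2.R).  The sign is physical and
    carried through; |kappa| <= 2.
    """
    r_vec = p2.center() - p1.center()
    r = float(np.linalg.norm(r_vec))
    if r <= 2.0:
        raise ValueError(
            f"center distance {r:.2f} A <= 2 A: point-dipole approximation "
            "breaks down"
        )
    r_hat = r_vec / r
    m1, m2 = p1.qy_unit_vector, p2.qy_unit_vector
    kappa = float(m1 @ m2 - 3.0 * (m1 @ r_hat) * (m2 @ r_hat))
    return (
        DIPOLE_COUPLING_PREFACTOR
        * screening_f
        * kappa
        * p1.dipole_magnitude
        * p2.dipole_magnitude
        / r**3
    )


def coupling_matrix_from_pigments(
    pigments: Sequence[Pigment], screening_f: float = DEFAULT_SCREENING
) -> np.ndarray:
    """Full point-dipole coupling matrix (eV) over a pigment list."""
    n = len(pigments)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = cm1_to_ev(
                point_dipole_coupling(pigments[i], pigments[j], screening_f)
            )
    return v


def _validate_units(df: pd.DataFrame, allowed: set[str], what: str) -> None:
    if "unit" not in df.columns:
        raise ValueError(f"{what} table is missing the 'unit' column")
    bad = set(df["unit"].astype(str)) - allowed
    if bad:
        raise ValueError(
            f"{what} table has unsupported units {sorted(bad)}; "
            f"allowed: {sorted(allowed)}"
        )


def build_system(
    site_energy_table: pd.DataFrame | str | Path,
    coupling_table: pd.DataFrame | str | Path | None = None,
    *,
    pigments: Sequence[Pigment] | None = None,
    screening_f: float = DEFAULT_SCREENING,
    model_label: str = "",
) -> ExcitonSystem:
    """Assemble an ExcitonSystem from delimited tables.

    The site-energy table needs columns (pigment_id, value, unit) with unit
    'eV'.  Couplings come either from a table with columns
    (pigment_i, pigment_j, value, unit) — unit 'cm-1' or 'eV' — or, when a
    pigment list is given instead, from the point-dipole estimator.
    Asymmetric coupling input (duplicate (i, j)/(j, i) rows disagreeing by
    more than 1e-6 eV) is an error, never silently averaged.
    """
    from .io import read_table

    energies = read_table(site_energy_table)
    required = {"pigment_id", "value", "unit"}
    if not required.issubset(energies.columns):
        raise ValueError(
            f"site-energy table needs columns {sorted(required)}, "
            f"got {list(energies.columns)}"
        )
    _validate_units(energies, {"eV"}, "site-energy")
    ids = [str(p) for p in energies["pigment_id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pigment_id in site-energy table")
    eps = energies["value"].astype(float).to_numpy()

    n = len(ids)
    v = np.zeros((n, n))
    if coupling_table is not None:
        couplings = read_table(coupling_table)
        req = {"pigment_i", "pigment_j", "value", "unit"}
        if not req.issubset(couplings.columns):
            raise ValueError(
                f"coupling table needs columns {sorted(req)}, "
                f"got {list(couplings.columns)}"
            )
        _validate_units(couplings, {"cm-1", "eV"}, "coupling")
        index = {pid: k for k, pid in enumerate(ids)}
        unknown = [
            pid
            for pid in set(couplings["pigment_i"]) | set(couplings["pigment_j"])
            if str(pid) not in index
        ]
        if unknown:
            raise ValueError(
                f"coupling table references unknown pigment ids: {sorted(map(str, unknown))}"
            )
        seen: dict[tuple[int, int], float] = {}
        for row in couplings.itertuples(index=False):
            i, j = index[str(row.pigment_i)], index[str(row.pigment_j)]
            if i == j:
                raise ValueError(f"self-coupling for {row.pigment_i!r}")
            val = float(row.value)
            if row.unit == "cm-1":
                val = cm1_to_ev(val)
            key = (min(i, j), max(i, j))
            if key in seen and abs(seen[key] - val) > 1e-6:
                raise ValueError(
                    f"asymmetric coupling input for pair "
                    f"({ids[key[0]]}, {ids[key[1]]}): "
                    f"{seen[key]:.6g} vs {val:.6g} eV"
                )
            seen[key] = val
        for (i, j), val in seen.items():
            v[i, j] = v[j, i] = val
    elif pigments is not None:
        if [p.pigment_id for p in pigments] != ids:
            raise ValueError(
                "pigment list does not match the site-energy table ids"
            )
        v = coupling_matrix_from_pigments(pigments, screening_f)

    return ExcitonSystem(
        pigment_ids=ids,
        site_energies=eps,
        couplings=v,
        model_label=model_label,
    )


def diagonalize(
    sys: ExcitonSystem, pigments: Sequence[Pigment] | None = None
) -> ExcitonStates:
    """Eigenstates of the exciton Hamiltonian, energies ascending.

    The sign of each eigenvector is fixed so that its largest-|coefficient|
    entry is positive (ties broken toward the lowest site index).  If a
    pigment list with transition dipoles is given, oscillator strengths are
    attached.
    """
    w, vecs = np.linalg.eigh(sys.hamiltonian())
    coeff = vecs.T  # rows = states
    for k in range(coeff.shape[0]):
        row = coeff[k]
        i_max = int(np.argmax(np.round(np.abs(row), 12)))  # ties -> lowest index
        if row[i_max] < 0:
            coeff[k] = -row
    pr = 1.0 / np.sum(coeff**4, axis=1)
    states = ExcitonStates(
        pigment_ids=list(sys.pigment_ids),
        energies=w,
        coefficients=coeff,
        participation_ratios=pr,
    )
    if pigments is not None:
        states.oscillator_strengths = oscillator_strengths(states, pigments)
    return states


def oscillator_strengths(
    states: ExcitonStates, pigments: Sequence[Pigment]
) -> np.ndarray:
    """Oscillator strengths f_k = 4.702e-7 * E_k[cm^-1] * |mu_k|^2[D^2].

    The exciton transition dipole is the coefficient-weighted vector sum of
    the site dipoles, mu_k = sum_i c_ki * mu_i * mu_hat_i; orthonormality of
    the coefficients guarantees the dipole-strength sum rule
    sum_k |mu_k|^2 = sum_i mu_i^2.
    """
    if [p.pigment_id for p in pigments] != states.pigment_ids:
        raise ValueError("pigment list does not match state site ordering")
    site_dipoles = np.array(
        [p.dipole_magnitude * p.qy_unit_vector for p in pigments]
    )  # (n_sites, 3)
    mu = states.coefficients @ site_dipoles  # (n_states, 3)
    mu2 = np.sum(mu**2, axis=1)
    return OSC_STRENGTH_PREFACTOR * ev_to_cm1(states.energies) * mu2


def site_energy_gap(sys: ExcitonSystem, site_a: str, site_b: str) -> float:
    """Signed site-energy difference epsilon_a - epsilon_b (eV)."""
    return float(
        sys.site_energies[sys.site_index(site_a)]
        - sys.site_energies[sys.site_index(site_b)]
    )
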