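"""Charge-separation energetics and kinetics.

Radical-pair (charge-transfer) state energies are bookkept from a
reference energy plus shifts in the donor oxidation potential; the cascade
from the excited reaction center to the final quinone-reduced/Mn-oxidized
state is propagated with a first-order master equation.  Forward rates may
come from Marcus nonadiabatic electron-transfer theory or from a
calibrated rate table; backward rates follow from detailed balance, so a
closed network relaxes to the Boltzmann distribution of its state
energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .constants import HBAR_EV_S, KB_EV_K, T_DEFAULT_K
from .pigment_geometry import ChemType


@dataclass(frozen=True)
class CTState:
    """One electronic state of the charge-separation cascade, with its
    energy above the ground state (eV)."""

    label: str
    energy: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise ValueError(f"{self.label}: state energy must be >= 0")


@dataclass(frozen=True)
class RedoxShift:
    """Shift of a site's oxidation potential relative to the white-light
    reference, in mV.

    Note on signs: an *increase* of the donor oxidation potential is
    reported here as a positive shift, and by the bookkeeping convention of
    :func:`ct_state_energy` it *stabilizes* (lowers) the charge-separated
    state.  The electrochemical sign convention is deliberately not
    resolved beyond this documented arithmetic.
    """

    site_label: str
    chem_type: ChemType
    delta_e_ox_mv: float

    def __post_init__(self) -> None:
        if abs(self.delta_e_ox_mv) >= 1000:
            raise ValueError("redox shift outside the +/-1 V sanity window")


def ct_state_energy(e_wl_reference: float, shift: RedoxShift) -> float:
    """Charge-separated state energy (eV) from the white-light reference
    energy and the donor-site oxidation-potential shift:
    E = E_ref - delta_e_ox / 1000."""
    if e_wl_reference <= 0:
        raise ValueError("reference energy must be positive")
    return e_wl_reference - shift.delta_e_ox_mv / 1000.0


def marcus_rate(
    delta_g: float,
    lambda_reorg: float,
    coupling_v: float,
    temperature: float = T_DEFAULT_K,
) -> float:
    """Nonadiabatic Marcus electron-transfer rate (s^-1).

    k = (2 pi / hbar) V^2 (4 pi lambda k_B T)^(-1/2)
        exp(-(dG + lambda)^2 / (4 lambda k_B T)),  energies in eV.
    """
    if lambda_reorg <= 0:
        raise ValueError("reorganization energy must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kbt = KB_EV_K * temperature
    prefactor = (2.0 * math.pi / HBAR_EV_S) * coupling_v**2
    density = 1.0 / math.sqrt(4.0 * math.pi * lambda_reorg * kbt)
    activation = math.exp(
        -((delta_g + lambda_reorg) ** 2) / (4.0 * lambda_reorg * kbt)
    )
    return prefactor * density * activation


def detailed_balance_backward(
    k_forward: float, delta_g: float, temperature: float = T_DEFAULT_K
) -> float:
    """Backward rate from detailed balance: k_back = k_fwd exp(dG / k_B T),
    with dG = E_product - E_reactant (negative for downhill steps)."""
    if k_forward < 0:
        raise ValueError("forward rate must be >= 0")
    return k_forward * math.exp(delta_g / (KB_EV_K * temperature))


@dataclass
class KineticNetwork:
    """Labelled CT states with a rate generator matrix (s^-1).

    ``generator[i, j]`` is the rate j -> i for i != j; each diagonal entry
    is minus its column sum, so total population is conserved.
    """

    states: list[CTState]
    generator: np.ndarray
    initial_populations: np.ndarray

    def __post_init__(self) -> None:
        self.generator = np.asarray(self.generator, dtype=float)
        self.initial_populations = np.asarray(
            self.initial_populations, dtype=float
        )
        n = len(self.states)
        if self.generator.shape != (n, n):
            raise ValueError("generator must be square over the state list")
        if not np.isfinite(self.generator).all():
            raise ValueError("generator contains non-finite rates")
        off = self.generator.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        scale = max(np.abs(self.generator).max(), 1.0)
        if np.abs(self.generator.sum(axis=0)).max() > 1e-9 * scale:
            raise ValueError("generator columns must sum to zero")
        if (self.initial_populations < 0).any() or abs(
            self.initial_populations.sum() - 1.0
        ) > 1e-9:
            raise ValueError("initial populations must be a simplex vector")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def state_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown state {label!r}; known: {self.labels}"
            ) from None


@dataclass
class KineticsResult:
    """Time-resolved populations on a log-spaced grid."""

    labels: list[str]
    time_grid: np.ndarray
    populations: np.ndarray  # (n_times, n_states)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if (np.diff(self.time_grid) <= 0).any():
            raise ValueError("time grid must be strictly ascending")
        if (self.populations < -1e-9).any():
            raise ValueError("negative populations")
        if np.abs(self.populations.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("population not conserved")

    def population(self, label: str) -> np.ndarray:
        return self.populations[:, self.labels.index(label)]


def chain_network(
    states: Sequence[CTState],
    forward_rates: Sequence[float],
    temperature: float = T_DEFAULT_K,
    reversible: bool = True,
) -> KineticNetwork:
    """Linear-chain network with the given forward rates and, optionally,
    detailed-balance backward rates derived from the state energies."""
    n = len(states)
    if len(forward_rates) != n - 1:
        raise ValueError("need exactly n-1 forward rates for an n-state chain")
    g = np.zeros((n, n))
    for i, k in enumerate(forward_rates):
        if k < 0 or not np.isfinite(k):
            raise ValueError(f"invalid forward rate {k!r} at step {i}")
        g[i + 1, i] += k
        if reversible:
            dg = states[i + 1].energy - states[i].energy
            g[i, i + 1] += detailed_balance_backward(k, dg, temperature)
    np.fill_diagonal(g, 0.0)
    g[np.diag_indices(n)] = -g.sum(axis=0)
    p0 = np.zeros(n)
    p0[0] = 1.0
    return KineticNetwork(list(states), g, p0)


# Calibrated forward rate table for the default charge-separation cascade
# (fixed package defaults reproducing the well-studied PSII kinetics; the
# final step is rate-limited by the slow Q_A -> Q_B electron transfer).
DEFAULT_FORWARD_RATES = (3.0e11, 3.47e9, 1.0e7, 2.31e3)

#: the 1.45 / 1.35 eV intermediate energies are interpolated defaults
#: between the 1.57 and 1.25 eV anchors.
FRL_STATE_TABLE = (
    ("S1", 1.72, "excited reaction center (far-red photon)"),
    ("ChlD1+ PheoD1-", 1.57, "primary radical pair"),
    ("PD1PD2+ QA-", 1.45, "hole on the special pair, electron on Q_A"),
    ("Yz_ox QA-", 1.35, "tyrosine Z oxidized"),
    ("Mn_ox QB-", 1.25, "Mn cluster oxidized, Q_B reduced (final)"),
)

WL_STATE_TABLE = (
    ("S1", 1.82, "excited reaction center (red photon)"),
    ("ChlD1+ PheoD1-", 1.715, "primary radical pair"),
    ("PD1PD2+ QA-", 1.45, "hole on the special pair, electron on Q_A"),
    ("Yz_ox QA-", 1.35, "tyrosine Z oxidized"),
    ("Mn_ox QB-", 1.25, "Mn cluster oxidized, Q_B reduced (final)"),
)

NETWORK_MODELS = {"FRL_chl_d": FRL_STATE_TABLE, "WL": WL_STATE_TABLE}


def build_default_network(
    model: str = "FRL_chl_d", temperature: float = T_DEFAULT_K
) -> KineticNetwork:
    """Default charge-separation cascade for the far-red (Chl d at the
    accessory-chlorophyll site) or white-light model.

    Five states from the excited reaction center down to the
    Mn-oxidized/Q_B-reduced final state, forward rates from the calibrated
    table, backward rates by detailed balance, all population initially on
    S1.
    """
    try:
        table = NETWORK_MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; known: {sorted(NETWORK_MODELS)}"
        ) from None
    states = [CTState(lbl, e, desc) for lbl, e, desc in table]
    return chain_network(states, DEFAULT_FORWARD_RATES, temperature)


def default_time_grid() -> np.ndarray:
    """Log-spaced grid spanning sub-ps photophysics to the ms regime."""
    return np.logspace(-13, -1, 400)


def propagate(
    net: KineticNetwork, t_grid: np.ndarray | None = None
) -> KineticsResult:
    """Populations P(t) = exp(G t) P(0) on the time grid.

    The generator is diagonalized once and the populations evaluated in the
    eigenbasis, which stays accurate for rates spanning many orders of
    magnitude where repeated squaring in a direct matrix exponential loses
    conservation.  A connected network has exactly one stationary mode, so
    the smallest-magnitude eigenvalue is clamped to exactly zero (its
    numerical perturbation is of order eps*||G|| and would otherwise leak
    population at long times); remaining real parts are capped at zero.
    Falls back to the scaling-and-squaring exponential if the eigenbasis is
    ill-conditioned.
    """
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, float)
    if (t_grid <= 0).any() or (np.diff(t_grid) <= 0).any():
        raise ValueError("time grid must be positive and strictly ascending")
    p0 = net.initial_populations
    g = net.generator
    pops = np.empty((t_grid.size, len(net.states)))
    w, vecs = np.linalg.eig(g)
    use_eig = np.linalg.cond(vecs) < 1e8
    if use_eig:
        w[np.argmin(np.abs(w))] = 0.0
        w = np.where(w.real > 0.0, 1j * w.imag, w)
        coeff = np.linalg.solve(vecs, p0.astype(complex))
        for i, t in enumerate(t_grid):
            pops[i] = ((vecs * np.exp(w * t)) @ coeff).real
    else:  # pragma: no cover - degenerate eigenbasis
        for i, t in enumerate(t_grid):
            pops[i] = expm(g * t) @ p0
    pops = np.clip(pops, 0.0, None)
    return KineticsResult(net.labels, t_grid, pops)


def halftime(
    result: KineticsResult, state_label: str, mode: str = "formation"
) -> float:
    """Halftime of a state's population curve (s).

    formation: first time the population reaches half its global maximum;
    decay: first time after the maximum that it falls back to half-maximum.
    Crossings are interpolated log-linearly in time between grid points.
    """
    if mode not in ("formation", "decay"):
        raise ValueError("mode must be 'formation' or 'decay'")
    p = result.population(state_label)
    p_max = p.max()
    if p_max <= 1e-9:
        raise ValueError(f"state {state_label!r} not populated")
    half = 0.5 * p_max
    i_max = int(np.argmax(p))
    t = result.time_grid

    def interp(i: int, rising: bool) -> float:
        # log-linear interpolation between grid points i-1 and i
        t0, t1 = t[i - 1], t[i]
        p0, p1 = p[i - 1], p[i]
        if p1 == p0:
            return float(t1)
        frac = (half - p0) / (p1 - p0)
        return float(10 ** (np.log10(t0) + frac * (np.log10(t1) - np.log10(t0))))

    if mode == "formation":
        above = np.flatnonzero(p[: i_max + 1] >= half)
        if above.size == 0:
            raise ValueError(f"state {state_label!r} never reaches half-max")
        i = int(above[0])
        return float(t[0]) if i == 0 else interp(i, rising=True)
    below = np.flatnonzero(p[i_max:] <= half)
    if below.size == 0:
        raise ValueError(
            f"state {state_label!r} does not decay to half-max on the grid"
        )
    i = i_max + int(below[0])
    return float(t[i]) if i == i_max else interp(i, rising=False)


def halftime_summary(
    result: KineticsResult, mode: str = "formation"
) -> dict[str, float | None]:
    """Halftimes for every state; None where the state is never populated
    or the requested crossing does not occur on the grid."""
    out: dict[str, float | None] = {}
    for lbl in result.labels:
        try:
            out[lbl] = halftime(result, lbl, mode)
        except ValueError:
            out[lbl] = None
    return out
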