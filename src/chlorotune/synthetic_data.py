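"""Synthetic generators for every input class the pipeline consumes, plus
the bundle of published reference parameter sets.

The generators stand in for the upstream quantum-chemistry and MD outputs:
idealized pigment clusters with coordinates and transition dipoles,
Gaussian-disordered site-energy sets, VEE quadruples with known embedded
components, and first-order kinetic chains with known rates.  Everything
is deterministic under a fixed seed (one RNG stream per call, no global
state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .charge_separation import CTState, KineticNetwork, RedoxShift, chain_network
from .excitonics import ExcitonSystem
from .pigment_geometry import ChemType, Pigment, SiteLabel
from .tuning_ledger import VEESet

#: idealized Mg-N bond length, angstrom
MG_N_DISTANCE = 2.05


@dataclass
class GeneratorConfig:
    """Parameters of the idealized pigment-cluster generator."""

    seed: int
    n_pigments: int = 2
    ring_radius: float = 3.4  # carbon-ring radius, angstrom
    inter_pigment_spacing: float = 8.0  # Mg-Mg, angstrom
    disorder_sigma: float = 0.0  # eV
    site_energy_means: np.ndarray | None = None  # eV

    def __post_init__(self) -> None:
        if self.inter_pigment_spacing <= 3.0:
            raise ValueError(
                "inter-pigment spacing must exceed 3 A (steric clash)"
            )
        if self.n_pigments < 1:
            raise ValueError("need at least one pigment")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _ideal_ring() -> tuple[list[str], list[str], np.ndarray]:
    """Planar idealized chlorin: Mg, four pyrrole N at the Mg-N distance,
    and 16 ring carbons on an outer circle.  Centered at the origin in the
    xy plane."""
    names = ["MG"]
    elements = ["MG"]
    coords = [np.zeros(3)]
    for name, angle in zip(
        ("NA", "NB", "NC", "ND"), np.deg2rad((45.0, 135.0, 225.0, 315.0))
    ):
        names.append(name)
        elements.append("N")
        coords.append(
            MG_N_DISTANCE * np.array([np.cos(angle), np.sin(angle), 0.0])
        )
    return names, elements, coords


def make_pigment_cluster(
    cfg: GeneratorConfig, pdb_path: str | Path | None = None
) -> tuple[list[Pigment], struc.AtomArray]:
    """Generate ``n_pigments`` idealized chlorin rings on a line at the
    configured Mg-Mg spacing, each with an independent random orientation.

    Returns the Pigment objects and the biotite atom array; when
    ``pdb_path`` is given the cluster is also written as a PDB file that
    round-trips through :func:`chlorotune.pigment_geometry.read_pigments`.
    """
    rng = np.random.default_rng(cfg.seed)
    base_names, base_elements, base_coords = _ideal_ring()
    # 16 ring carbons on the outer circle
    for i, angle in enumerate(np.deg2rad(np.arange(16) * 22.5 + 11.25)):
        base_names.append(f"C{i + 1}")
        base_elements.append("C")
        base_coords.append(
            cfg.ring_radius * np.array([np.cos(angle), np.sin(angle), 0.0])
        )
    base = np.array(base_coords)

    pigments: list[Pigment] = []
    all_atoms: list[struc.Atom] = []
    site_cycle = list(SiteLabel)[:6]
    for i in range(cfg.n_pigments):
        rot = _random_rotation(rng)
        center = np.array([i * cfg.inter_pigment_spacing, 0.0, 0.0])
        coords = base @ rot.T + center
        label = site_cycle[i % len(site_cycle)]
        i_nb, i_nd = base_names.index("NB"), base_names.index("ND")
        axis = coords[i_nd] - coords[i_nb]
        pigments.append(
            Pigment(
                pigment_id=f"{label.value}",
                chem_type=ChemType.chl_a,
                site_label=label,
                atom_names=list(base_names),
                elements=list(base_elements),
                coords=coords,
                mg_position=coords[0],
                qy_unit_vector=axis / np.linalg.norm(axis),
            )
        )
        for name, element, xyz in zip(base_names, base_elements, coords):
            all_atoms.append(
                struc.Atom(
                    xyz,
                    chain_id="A",
                    res_id=i + 1,
                    res_name="CLA",
                    atom_name=name,
                    element=element,
                    hetero=True,
                )
            )
    array = struc.array(all_atoms)
    if pdb_path is not None:
        pdb = PDBFile()
        pdb.set_structure(array)
        pdb.write(str(pdb_path))
    return pigments, array


def cluster_selection_map(n_pigments: int) -> dict[str, tuple[str, str, int]]:
    """Selection map matching :func:`make_pigment_cluster` output."""
    site_cycle = list(SiteLabel)[:6]
    return {
        site_cycle[i % len(site_cycle)].value: ("A", "CLA", i + 1)
        for i in range(n_pigments)
    }


def make_disordered_site_energies(
    cfg: GeneratorConfig,
) -> np.ndarray:
    """Site energies drawn around the configured means with i.i.d.
    Gaussian static disorder."""
    means = (
        np.full(cfg.n_pigments, 1.9)
        if cfg.site_energy_means is None
        else np.asarray(cfg.site_energy_means, dtype=float)
    )
    rng = np.random.default_rng(cfg.seed)
    return means + rng.normal(0.0, cfg.disorder_sigma, size=means.shape)


def make_vee_set(
    pigment_id: str,
    baseline: float,
    strain: float,
    electrostatic: float,
    coupling_polarization: float,
) -> VEESet:
    """VEE quadruple with the given components embedded exactly — the
    right inverse of :func:`chlorotune.tuning_ledger.decompose`."""
    gas_protein = baseline + strain
    monomer = gas_protein + electrostatic
    multimer = monomer + coupling_polarization
    return VEESet(
        pigment_id=pigment_id,
        vee_gas_at_gas_geom=baseline,
        vee_gas_at_protein_geom=gas_protein,
        vee_protein_monomer=monomer,
        vee_multimer=multimer,
    )


def make_network(
    n_states: int,
    rate_log10_range: tuple[float, float] = (3.0, 12.0),
    seed: int = 0,
) -> KineticNetwork:
    """Irreversible chain with forward rates log-uniform in the given
    decade range and strictly decreasing state energies."""
    if n_states < 2:
        raise ValueError("need at least two states")
    rng = np.random.default_rng(seed)
    lo, hi = rate_log10_range
    rates = 10.0 ** rng.uniform(lo, hi, size=n_states - 1)
    energies = np.linspace(1.72, 0.25, n_states)
    states = [
        CTState(f"S{i}", float(e), "synthetic chain state")
        for i, e in enumerate(energies)
    ]
    return chain_network(states, rates, reversible=False)


def _pair_system(
    label: str, pair_energy: float, chl_d1_energy: float, coupling_cm1: float
) -> ExcitonSystem:
    from .constants import cm1_to_ev

    v = np.zeros((3, 3))
    v[0, 1] = v[1, 0] = cm1_to_ev(coupling_cm1)
    return ExcitonSystem(
        pigment_ids=["P_D1", "P_D2", "Chl_D1"],
        # the published site-energy table reports one value for the coupled
        # special pair; it is assigned to both P_D1 and P_D2 diagonals
        site_energies=np.array([pair_energy, pair_energy, chl_d1_energy]),
        couplings=v,
        model_label=label,
    )


def reference_fixtures() -> dict:
    """Published reference parameter sets for the five reaction-center
    models, as ready-to-use objects.

    Site energies (eV) and special-pair couplings (cm^-1) from the
    published site-energy table; tuning-ledger components, redox shifts
    and charge-transfer state energies from the published analysis.  Each
    numeric group carries a citation string describing its provenance.
    """
    systems = {
        "chl_d_at_chl_d1": _pair_system("Chl d @ Chl_D1", 1.936, 1.904, 97.0),
        "chl_f_at_chl_d1": _pair_system("Chl f @ Chl_D1", 1.943, 1.897, 105.0),
        "chl_d_at_p_d2": _pair_system("Chl d @ P_D2", 1.867, 2.007, 180.0),
        "chl_f_at_p_d2": _pair_system("Chl f @ P_D2", 1.786, 2.006, 192.0),
        "wl": _pair_system("WL-PSII", 1.946, 1.993, 77.0),
    }
    # Baselines back-computed so the in-protein monomer VEE matches the
    # published site energy; the Chl f coupling/polarization component is
    # not published and is set to zero.
    vee_sets = {
        "chl_d_at_chl_d1": make_vee_set(
            "Chl_D1", baseline=1.910, strain=-0.006, electrostatic=-0.003,
            coupling_polarization=-0.032,
        ),
        "chl_f_at_chl_d1": make_vee_set(
            "Chl_D1", baseline=1.820, strain=0.021, electrostatic=0.056,
            coupling_polarization=0.0,
        ),
    }
    redox_shifts = {
        "chl_d": RedoxShift("Chl_D1", ChemType.chl_d, 145.0),
        "chl_f": RedoxShift("Chl_D1", ChemType.chl_f, 198.0),
    }
    return {
        "exciton_systems": systems,
        "vee_sets": vee_sets,
        "redox_shifts": redox_shifts,
        "ct_energies_ev": {"S1": 1.72, "ChlD1+ PheoD1-": 1.57, "Mn_ox QB-": 1.25},
        "wl_reference_ct_ev": 1.715,
        "citations": {
            "exciton_systems": (
                "published Q_y site energies of the special pair and "
                "accessory chlorophyll for all five reaction-center models "
                "(correlated ab initio level), with published special-pair "
                "couplings 97/105/180/192/77 cm^-1"
            ),
            "vee_sets": (
                "published strain/electrostatic/coupling-polarization "
                "components for the accessory-chlorophyll site; baselines "
                "back-computed, Chl f coupling component unpublished (0)"
            ),
            "redox_shifts": (
                "published oxidation-potential increases of the accessory "
                "chlorophyll site: +145 mV (Chl d), +198 mV (Chl f)"
            ),
            "ct_energies_ev": (
                "published charge-separation ladder anchors 1.72/1.57/1.25 eV"
            ),
            "wl_reference_ct_ev": (
                "back-computed white-light reference chosen so the published "
                "+145 mV shift yields the published 1.57 eV state; not a "
                "published value"
            ),
        },
    }
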