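"""Pigment geometry: reading chlorin pigments from PDB files and the
geometric primitives (Q_y dipole axes, inter-pigment distances) that the
excitonic-coupling and structural-analysis operations consume.

Chlorophyll-type pigments appear as HETATM residues (CLA, CHL, CL7, ...)
whose naming dialect varies between depositions; both the residue-name map
and the Q_y axis atom names are therefore configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist


class ChemType(str, Enum):
    """Chemical identity of a chlorin pigment.

    Chl a carries a vinyl group at C3; Chl d replaces it with a formyl
    group, and Chl f carries a formyl at C2 — the substitutions that shift
    the Q_y band to longer wavelengths.  Pheophytin a is the Mg-free
    analogue of Chl a.
    """

    chl_a = "chl_a"
    chl_d = "chl_d"
    chl_f = "chl_f"
    pheo_a = "pheo_a"


class SiteLabel(str, Enum):
    """Reaction-center pigment sites of photosystem II (D1/D2 subunits)."""

    P_D1 = "P_D1"
    P_D2 = "P_D2"
    Chl_D1 = "Chl_D1"
    Chl_D2 = "Chl_D2"
    Pheo_D1 = "Pheo_D1"
    Pheo_D2 = "Pheo_D2"
    other = "other"


#: residue name -> chemical type.  Chl d/f codes vary between depositions,
#: hence the dialect entries; fully overridable via ``residue_map``.
DEFAULT_RESIDUE_MAP: dict[str, ChemType] = {
    "CLA": ChemType.chl_a,
    "CHL": ChemType.chl_a,
    "CL7": ChemType.chl_d,
    "CHD": ChemType.chl_d,
    "CL8": ChemType.chl_f,
    "CHF": ChemType.chl_f,
    "PHO": ChemType.pheo_a,
    "PHE": ChemType.pheo_a,  # HETATM dialect, not the amino acid
}

#: default Q_y axis atom pair (PDB chlorophyll convention); the N21/N23
#: dialect is accepted by passing ``axis_atoms=("N21", "N23")``.
DEFAULT_AXIS_ATOMS: tuple[str, str] = ("NB", "ND")

#: effective in-protein Q_y transition dipole magnitude, Debye.
DEFAULT_DIPOLE_D = 4.0

# Conjugated macrocycle nomenclature: pyrrole nitrogens (NA-ND or N21-N24)
# and ring carbons (IUPAC C1-C20, or the older C1A..C4D / CHA..CHD ring and
# methine-bridge names).  Phytyl-tail atoms never match.
_MACROCYCLE_RE = re.compile(
    r"^(N[A-D]|N2[1-4]|C([1-9]|1[0-9]|20)|C[1-4][A-D]|CH[A-D])$"
)


def is_macrocycle_atom(name: str, element: str) -> bool:
    """True for conjugated-macrocycle heavy atoms (ring C and pyrrole N)."""
    return element.upper() in ("C", "N") and bool(_MACROCYCLE_RE.match(name))


@dataclass
class Pigment:
    """One chlorin pigment extracted from a structure.

    Coordinates are Cartesian angstroms as stored in the file (no
    re-centering).  ``qy_unit_vector`` points along the NB->ND nitrogen
    axis (or the configured dialect pair) and has unit norm.
    """

    pigment_id: str
    chem_type: ChemType
    site_label: SiteLabel
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    mg_position: np.ndarray | None
    qy_unit_vector: np.ndarray
    dipole_magnitude: float = DEFAULT_DIPOLE_D
    axis_atoms: tuple[str, str] = DEFAULT_AXIS_ATOMS

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.qy_unit_vector = np.asarray(self.qy_unit_vector, dtype=float)
        if abs(np.linalg.norm(self.qy_unit_vector) - 1.0) > 1e-9:
            raise ValueError(
                f"{self.pigment_id}: qy_unit_vector must have unit norm"
            )
        if self.dipole_magnitude <= 0:
            raise ValueError(f"{self.pigment_id}: dipole_magnitude must be > 0")
        if len(self.macrocycle_indices()) == 0:
            raise ValueError(f"{self.pigment_id}: no macrocycle atoms found")

    @property
    def atoms(self) -> list[tuple[str, str, np.ndarray]]:
        """Atoms as (name, element, position) triples, in file order."""
        return list(zip(self.atom_names, self.elements, self.coords))

    def atom_position(self, name: str) -> np.ndarray:
        try:
            i = self.atom_names.index(name)
        except ValueError:
            raise KeyError(
                f"{self.pigment_id}: atom {name!r} not present"
            ) from None
        return self.coords[i]

    def macrocycle_indices(self) -> np.ndarray:
        mask = [
            is_macrocycle_atom(n, e)
            for n, e in zip(self.atom_names, self.elements)
        ]
        return np.flatnonzero(mask)

    def macrocycle_coords(self) -> np.ndarray:
        return self.coords[self.macrocycle_indices()]

    def center(self) -> np.ndarray:
        """Mg position, or the macrocycle centroid for Mg-free pigments."""
        if self.mg_position is not None:
            return np.asarray(self.mg_position, dtype=float)
        return self.macrocycle_coords().mean(axis=0)


def qy_axis(
    p: Pigment, axis_atoms: tuple[str, str] | None = None
) -> np.ndarray:
    """Unit vector along the Q_y transition axis, from the first to the
    second axis-defining pyrrole nitrogen (NB -> ND by default).

    The sign is deterministic: always from the first named atom toward the
    second.  Invariant under rigid translation; equivariant under rotation.
    """
    a, b = axis_atoms or p.axis_atoms
    v = p.atom_position(b) - p.atom_position(a)
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise ValueError(
            f"{p.pigment_id}: zero-length Q_y axis ({a} and {b} coincide)"
        )
    return v / norm


def edge_to_edge_distance(p1: Pigment, p2: Pigment) -> float:
    """Minimum heavy-atom distance between the two conjugated macrocycles
    (angstrom).  'Edge-to-edge' refers to the conjugated ring systems, so
    phytyl-tail atoms are excluded.  Symmetric in its arguments.
    """
    c1, c2 = p1.macrocycle_coords(), p2.macrocycle_coords()
    if c1.size == 0 or c2.size == 0:
        raise ValueError("empty macrocycle atom set")
    return float(cdist(c1, c2).min())


def mg_mg_distance(
    p1: Pigment, p2: Pigment, return_metadata: bool = False
) -> float | tuple[float, dict]:
    """Center-center distance (angstrom) between two pigments.

    Uses the Mg positions; a pigment without Mg (pheophytin) falls back to
    its macrocycle centroid, flagged in the metadata when requested.
    """
    d = float(np.linalg.norm(p1.center() - p2.center()))
    if return_metadata:
        meta = {
            "centroid_fallback": {
                p.pigment_id: p.mg_position is None for p in (p1, p2)
            }
        }
        return d, meta
    return d


def _infer_chem_type(
    res_name: str, residue_map: Mapping[str, ChemType]
) -> ChemType:
    try:
        return residue_map[res_name.upper()]
    except KeyError:
        raise ValueError(
            f"residue name {res_name!r} not in the residue-name map; "
            f"known names: {sorted(residue_map)}"
        ) from None


def read_pigments(
    structure_path: str | Path,
    selection_map: Mapping[SiteLabel | str, tuple[str, str, int]],
    *,
    residue_map: Mapping[str, ChemType] | None = None,
    axis_atoms: tuple[str, str] = DEFAULT_AXIS_ATOMS,
    dipole_magnitudes: Mapping[ChemType, float] | None = None,
) -> list[Pigment]:
    """Read the pigments named in ``selection_map`` from a PDB file.

    Parameters
    ----------
    structure_path
        PDB file containing the pigments as HETATM residues.
    selection_map
        site label -> (chain_id, residue_name, residue_number).  One
        pigment is returned per entry, with atoms in file order.
    residue_map
        residue name -> chemical type; defaults to the common chlorophyll
        dialect table.
    axis_atoms
        Q_y axis atom-name pair (default NB/ND).
    dipole_magnitudes
        per-chem-type Q_y dipole magnitude in Debye (default 4.0 D for all).
    """
    residue_map = residue_map or DEFAULT_RESIDUE_MAP
    pdb = PDBFile.read(str(structure_path))
    atoms = pdb.get_structure(model=1)

    pigments: list[Pigment] = []
    for raw_label, (chain, res_name, res_id) in selection_map.items():
        label = SiteLabel(raw_label)
        mask = (
            (atoms.chain_id == chain)
            & (atoms.res_name == res_name)
            & (atoms.res_id == int(res_id))
        )
        if not mask.any():
            raise ValueError(
                f"selection entry {label.value}: residue "
                f"({chain}, {res_name}, {res_id}) not found in "
                f"{structure_path}"
            )
        sub = atoms[mask]
        names = list(sub.atom_name)
        elements = list(sub.element)
        coords = np.asarray(sub.coord, dtype=float)

        chem_type = _infer_chem_type(res_name, residue_map)
        for ax in axis_atoms:
            if ax not in names:
                raise ValueError(
                    f"selection entry {label.value}: axis pyrrole nitrogen "
                    f"{ax!r} missing"
                )

        mg = None
        if "MG" in names:
            mg = coords[names.index("MG")]

        mag = DEFAULT_DIPOLE_D
        if dipole_magnitudes and chem_type in dipole_magnitudes:
            mag = dipole_magnitudes[chem_type]

        i_a, i_b = names.index(axis_atoms[0]), names.index(axis_atoms[1])
        v = coords[i_b] - coords[i_a]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(
                f"selection entry {label.value}: degenerate Q_y axis"
            )

        pigments.append(
            Pigment(
                pigment_id=label.value,
                chem_type=chem_type,
                site_label=label,
                atom_names=names,
                elements=elements,
                coords=coords,
                mg_position=mg,
                qy_unit_vector=v / norm,
                dipole_magnitude=mag,
                axis_atoms=axis_atoms,
            )
        )
    return pigments
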