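"""Readers and writers for the delimited-table, CSV, JSON and YAML
formats that cross the package boundary.

All tables are comma-delimited text with a header row and an explicit
``unit`` column where units apply — no unit guessing, ever.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .charge_separation import CTState, KineticNetwork, KineticsResult, chain_network, marcus_rate
from .spectra import Spectrum, ev_to_nm, nm_to_ev
from .tuning_ledger import ShiftLedger, VEESet


def read_table(source: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Accept a DataFrame or a delimited-text path."""
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source)


def write_site_energy_table(
    path: str | Path, pigment_ids: Sequence[str], energies_ev: Sequence[float]
) -> None:
    pd.DataFrame(
        {"pigment_id": pigment_ids, "value": energies_ev, "unit": "eV"}
    ).to_csv(path, index=False)


def write_coupling_table(
    path: str | Path,
    pairs: Iterable[tuple[str, str, float]],
    unit: str = "cm-1",
) -> None:
    rows = [{"pigment_i": i, "pigment_j": j, "value": v, "unit": unit}
            for i, j, v in pairs]
    pd.DataFrame(rows).to_csv(path, index=False)


_VEE_COLUMNS = (
    "vee_gas_at_gas_geom",
    "vee_gas_at_protein_geom",
    "vee_protein_monomer",
    "vee_multimer",
)


def read_vee_table(source: pd.DataFrame | str | Path) -> list[VEESet]:
    """VEE table: one row per pigment, the four VEE columns, unit column
    declaring eV."""
    df = read_table(source)
    required = {"pigment_id", *_VEE_COLUMNS, "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VEE table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("VEE table is empty")
    bad = set(df["unit"].astype(str)) - {"eV"}
    if bad:
        raise ValueError(f"VEE table units must be eV, got {sorted(bad)}")
    return [
        VEESet(
            pigment_id=str(row.pigment_id),
            **{c: float(getattr(row, c)) for c in _VEE_COLUMNS},
        )
        for row in df.itertuples(index=False)
    ]


def write_vee_table(path: str | Path, sets: Sequence[VEESet]) -> None:
    rows = [
        {"pigment_id": v.pigment_id,
         **{c: getattr(v, c) for c in _VEE_COLUMNS},
         "unit": "eV"}
        for v in sets
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ledger_table(path: str | Path, ledgers: Sequence[ShiftLedger]) -> None:
    pd.DataFrame([lg.as_dict() | {"unit": "eV"} for lg in ledgers]).to_csv(
        path, index=False
    )


def write_spectrum(
    spec: Spectrum, path: str | Path, x_unit: str = "energy_eV"
) -> None:
    """Two-column CSV (energy_eV or wavelength_nm, intensity) with the
    metadata written to a JSON sidecar next to it."""
    path = Path(path)
    if x_unit == "energy_eV":
        x = spec.energy_grid
    elif x_unit == "wavelength_nm":
        x = np.array([ev_to_nm(e) for e in spec.energy_grid])
    else:
        raise ValueError("x_unit must be 'energy_eV' or 'wavelength_nm'")
    pd.DataFrame({x_unit: x, "intensity": spec.intensity}).to_csv(
        path, index=False
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(spec.metadata, indent=2, sort_keys=True))


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "energy_eV" in df.columns:
        grid = df["energy_eV"].to_numpy()
        intensity = df["intensity"].to_numpy()
    elif "wavelength_nm" in df.columns:
        grid = np.array([nm_to_ev(x) for x in df["wavelength_nm"]])
        intensity = df["intensity"].to_numpy()
    else:
        raise ValueError("spectrum CSV needs an energy_eV or wavelength_nm column")
    order = np.argsort(grid)
    return Spectrum(grid[order], intensity[order], meta)


def read_network_spec(path: str | Path) -> KineticNetwork:
    """Kinetic-network YAML: ``states`` as a list of {label, energy_eV}
    (ladder order), ``edges`` as a list of {from, to, k_forward_s-1} or
    {from, to, marcus: {lambda_eV, V_eV}}, optional ``temperature_K``.

    Edges must follow the chain order of the state list; backward rates
    are added by detailed balance unless ``reversible: false``.
    """
    spec = yaml.safe_load(Path(path).read_text())
    if not isinstance(spec, dict) or "states" not in spec or "edges" not in spec:
        raise ValueError("network spec needs 'states' and 'edges' sections")
    states = [
        CTState(str(s["label"]), float(s["energy_eV"]), str(s.get("description", "")))
        for s in spec["states"]
    ]
    labels = [s.label for s in states]
    temperature = float(spec.get("temperature_K", 298.15))
    rates: list[float] = []
    edges = spec["edges"]
    if len(edges) != len(states) - 1:
        raise ValueError("edges must form a chain: need n_states - 1 edges")
    for i, edge in enumerate(edges):
        if str(edge["from"]) != labels[i] or str(edge["to"]) != labels[i + 1]:
            raise ValueError(
                f"edge {i} must connect {labels[i]!r} -> {labels[i + 1]!r}"
            )
        if "k_forward_s-1" in edge:
            k = float(edge["k_forward_s-1"])
        elif "marcus" in edge:
            m = edge["marcus"]
            dg = states[i + 1].energy - states[i].energy
            k = marcus_rate(dg, float(m["lambda_eV"]), float(m["V_eV"]), temperature)
        else:
            raise ValueError(f"edge {i} needs 'k_forward_s-1' or 'marcus'")
        if k < 0:
            raise ValueError(f"edge {i}: negative rate")
        rates.append(k)
    return chain_network(
        states, rates, temperature, reversible=bool(spec.get("reversible", True))
    )


def write_kinetics(
    result: KineticsResult,
    csv_path: str | Path,
    json_path: str | Path | None = None,
    halftimes: Mapping[str, float | None] | None = None,
    extra: Mapping | None = None,
) -> None:
    df = pd.DataFrame(result.populations, columns=result.labels)
    df.insert(0, "time_s", result.time_grid)
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {"halftimes_s": dict(halftimes or {})}
        if extra:
            payload.update(extra)
        Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
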