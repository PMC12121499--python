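"""Three-component decomposition of protein-induced spectral tuning.

Four vertical excitation energies (VEEs) of the same pigment — gas phase at
its gas-phase geometry, gas phase at its in-protein geometry, in-protein
monomer, and in-protein multimer — bracket three physically distinct
tuning mechanisms:

* strain               = VEE(gas @ protein geom) - VEE(gas @ gas geom)
* electrostatic        = VEE(protein monomer)    - VEE(gas @ protein geom)
* coupling/polarization = VEE(multimer)          - VEE(protein monomer)

The three components telescope exactly to the total shift
VEE(multimer) - VEE(gas @ gas geom).  Sign convention: negative = redshift
(lower energy).  The VEE values themselves are inputs — typically from
quantum-chemical calculations — and nothing here recomputes them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

_VEE_WINDOW = (0.5, 4.0)  # eV

#: components with |value| below this are classified "neutral"
NEUTRAL_THRESHOLD = 0.001

COMPONENTS = ("strain", "electrostatic", "coupling_polarization")


@dataclass(frozen=True)
class VEESet:
    """The four VEE evaluations (eV) for one pigment."""

    pigment_id: str
    vee_gas_at_gas_geom: float
    vee_gas_at_protein_geom: float
    vee_protein_monomer: float
    vee_multimer: float

    def __post_init__(self) -> None:
        lo, hi = _VEE_WINDOW
        for name in (
            "vee_gas_at_gas_geom",
            "vee_gas_at_protein_geom",
            "vee_protein_monomer",
            "vee_multimer",
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(
                    f"{self.pigment_id}: {name} = {v} eV outside {_VEE_WINDOW}"
                )


@dataclass(frozen=True)
class ShiftLedger:
    """Decomposed tuning shifts (eV); total is the exact component sum."""

    pigment_id: str
    strain: float
    electrostatic: float
    coupling_polarization: float
    total: float

    def __post_init__(self) -> None:
        if abs(
            self.total
            - (self.strain + self.electrostatic + self.coupling_polarization)
        ) > 1e-12:
            raise ValueError("ledger total must equal the component sum")

    def as_dict(self) -> dict:
        return asdict(self)


def decompose(v: VEESet) -> ShiftLedger:
    """Exact bookkeeping of the three tuning components from a VEESet."""
    strain = v.vee_gas_at_protein_geom - v.vee_gas_at_gas_geom
    electrostatic = v.vee_protein_monomer - v.vee_gas_at_protein_geom
    coupling_pol = v.vee_multimer - v.vee_protein_monomer
    return ShiftLedger(
        pigment_id=v.pigment_id,
        strain=strain,
        electrostatic=electrostatic,
        coupling_polarization=coupling_pol,
        total=strain + electrostatic + coupling_pol,
    )


def classify_shift(delta: float, threshold: float = NEUTRAL_THRESHOLD) -> str:
    """'redshifting' (negative), 'blueshifting' (positive) or 'neutral'."""
    if abs(delta) < threshold:
        return "neutral"
    return "redshifting" if delta < 0 else "blueshifting"


def classify_ledger(ledger: ShiftLedger) -> dict[str, str]:
    """Per-component red/blue/neutral classification of one ledger."""
    out = {c: classify_shift(getattr(ledger, c)) for c in COMPONENTS}
    out["total"] = classify_shift(ledger.total)
    return out


def compare_ledgers(a: ShiftLedger, b: ShiftLedger) -> dict:
    """Component-wise differences a - b with sign classification."""
    diffs = {c: getattr(a, c) - getattr(b, c) for c in COMPONENTS}
    diffs["total"] = a.total - b.total
    return {
        "pigment_a": a.pigment_id,
        "pigment_b": b.pigment_id,
        "differences": diffs,
        "classification": {k: classify_shift(d) for k, d in diffs.items()},
    }
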