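"""Readers and writers for the external representations the pipeline touches:
multi-frame XYZ geometries (with an optional per-atom point-charge column),
CSV tables of vertical transitions, spectrum CSV files, and point-charge
field files for electrostatic-embedding inputs.

XYZ dialect: Å units, free whitespace, the comment line is carried as the
frame label, and an optional 5th column is parsed as a point charge in e.
CSV files require a header, '.' decimal separator, UTF-8.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import HC_EV_NM

__all__ = [
    "ATOMIC_MASSES",
    "Molecule",
    "TransitionRecord",
    "SpectrumTable",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_transitions",
    "write_transitions",
    "write_spectrum",
    "read_spectrum",
    "write_pointcharge_field",
    "load_u6oh_table1",
]

#: isotope-averaged standard atomic weights (amu), keyed by element symbol
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798, "Rb": 85.4678, "Sr": 87.62,
    "I": 126.90447, "Xe": 131.293,
    # convenience symbols for synthetic toys
    "X": 1.0,
}


@dataclass
class Molecule:
    """A single molecular geometry.

    Coordinates are Cartesian Å, shape (N, 3).  ``charges`` are optional
    per-atom point charges in e.  ``label`` carries the XYZ comment line.
    """

    symbols: list[str]
    masses: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.symbols)
        if self.masses.shape != (n,):
            raise ValueError(
                f"masses length {self.masses.shape} does not match {n} symbols"
            )
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} atoms"
            )
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charges must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "Molecule":
        return Molecule(
            symbols=list(self.symbols),
            masses=self.masses.copy(),
            coords=self.coords.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            label=self.label,
        )


@dataclass(frozen=True)
class TransitionRecord:
    """One vertical electronic transition of one sampled geometry.

    ``geom_id`` indexes the sampled geometry R_k, ``state`` is the excited
    state l ≥ 1 (e.g. the D2…D10 doublets map to l = 1…9), ``E_va_eV`` the
    vertical excitation energy and ``f`` the oscillator strength.
    """

    geom_id: int
    state: int
    E_va_eV: float
    f: float
    mu_au: float | None = None

    def __post_init__(self) -> None:
        if self.E_va_eV <= 0:
            raise ValueError(
                f"E_va must be positive, got {self.E_va_eV} eV "
                f"(geom {self.geom_id}, state {self.state})"
            )
        if self.f < 0:
            raise ValueError(
                f"oscillator strength must be >= 0, got {self.f} "
                f"(geom {self.geom_id}, state {self.state})"
            )
        if self.state < 1:
            raise ValueError(f"state index must be >= 1, got {self.state}")


@dataclass
class SpectrumTable:
    """An absorption spectrum on a photon-energy grid.

    ``sigma``/``dsigma`` are the cross section and its sampling error in cm²;
    ``eps``/``deps`` the molar extinction coefficient and its error in
    M⁻¹cm⁻¹ (zero until converted).  ``per_state`` optionally maps an excited
    state index to its σ component.  ``sigma_k`` (not serialized) holds the
    per-geometry signals used for the error analysis.
    """

    E_grid: np.ndarray
    sigma: np.ndarray
    dsigma: np.ndarray
    eps: np.ndarray | None = None
    deps: np.ndarray | None = None
    per_state: dict[int, np.ndarray] | None = None
    meta: dict = field(default_factory=dict)
    sigma_k: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.E_grid = np.asarray(self.E_grid, dtype=float)
        if self.E_grid.ndim != 1 or np.any(np.diff(self.E_grid) <= 0):
            raise ValueError("E_grid must be 1-D and strictly increasing")
        for name in ("sigma", "dsigma", "eps", "deps"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.E_grid.shape:
                raise ValueError(f"{name} must match the grid length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative everywhere")
            setattr(self, name, arr)

    @property
    def lambda_grid(self) -> np.ndarray:
        """Wavelengths (nm) matching E_grid, λ = hc/E."""
        return HC_EV_NM / self.E_grid


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _mass_for(symbol: str, line_no: int) -> float:
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise ValueError(
            f"unknown element symbol {symbol!r} at line {line_no}"
        ) from None


def read_xyz_frames(path: str | Path) -> list[Molecule]:
    """Read a multi-frame XYZ file.

    An optional 5th column on atom records is parsed as a point charge (e);
    masses are filled from the built-in standard-atomic-weight table.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    frames: list[Molecule] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ValueError(
                f"{path}: malformed atom-count line {i + 1}: {lines[i]!r}"
            ) from None
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ValueError(
                f"{path}: frame starting at line {i + 1} declares {n} atoms "
                f"but the file ends early"
            )
        label = lines[i + 1].strip() if i + 1 < len(lines) else ""
        symbols: list[str] = []
        masses: list[float] = []
        coords: list[list[float]] = []
        charges: list[float] = []
        has_charges = False
        for j in range(n):
            ln = i + 2 + j
            if ln >= len(lines):
                raise ValueError(
                    f"{path}: frame at line {i + 1} declares {n} atoms but "
                    f"only {j} records follow"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: malformed atom record at line {ln + 1}: "
                    f"{lines[ln]!r} (frame declares {n} atoms)"
                )
            sym = parts[0]
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric coordinate at line {ln + 1}"
                ) from None
            symbols.append(sym)
            masses.append(_mass_for(sym, ln + 1))
            coords.append(xyz)
            if len(parts) >= 5:
                charges.append(float(parts[4]))
                has_charges = True
            else:
                charges.append(0.0)
        frames.append(
            Molecule(
                symbols=symbols,
                masses=np.array(masses),
                coords=np.array(coords),
                charges=np.array(charges) if has_charges else None,
                label=label,
            )
        )
        i += 2 + n
    return frames


def write_xyz_frames(frames: Sequence[Molecule], path: str | Path) -> None:
    """Write molecules as a multi-frame XYZ file (charges as a 5th column)."""
    out = []
    for mol in frames:
        out.append(str(mol.n_atoms))
        out.append(mol.label)
        for i, sym in enumerate(mol.symbols):
            x, y, z = mol.coords[i]
            row = f"{sym:<3s} {x:18.10f} {y:18.10f} {z:18.10f}"
            if mol.charges is not None:
                row += f" {mol.charges[i]:14.8f}"
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# transition tables
# ---------------------------------------------------------------------------

def read_transitions(path: str | Path) -> list[TransitionRecord]:
    """Read a transitions CSV with columns geom_id, state, E_eV, f[, mu_au].

    Rows are validated (E > 0, f ≥ 0, unique (geom_id, state)) and returned
    in file order.
    """
    df = pd.read_csv(path)
    required = {"geom_id", "state", "E_eV", "f"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[TransitionRecord] = []
    seen: set[tuple[int, int]] = set()
    for idx, row in df.iterrows():
        key = (int(row["geom_id"]), int(row["state"]))
        if key in seen:
            raise ValueError(
                f"{path}: duplicate (geom_id, state) = {key} at row {idx}"
            )
        seen.add(key)
        try:
            rec = TransitionRecord(
                geom_id=key[0],
                state=key[1],
                E_va_eV=float(row["E_eV"]),
                f=float(row["f"]),
                mu_au=float(row["mu_au"]) if "mu_au" in df.columns else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid row {idx}: {exc}") from None
        records.append(rec)
    return records


def write_transitions(records: Sequence[TransitionRecord], path: str | Path) -> None:
    rows = [
        {"geom_id": r.geom_id, "state": r.state, "E_eV": r.E_va_eV, "f": r.f}
        for r in records
    ]
    pd.DataFrame(rows, columns=["geom_id", "state", "E_eV", "f"]).to_csv(
        path, index=False
    )


def load_u6oh_table1() -> list[TransitionRecord]:
    """The packaged worked example: CASPT2 vertical transitions of the
    uracil C6-OH adduct radical (states D2…D10 as l = 1…9, one geometry)."""
    ref = importlib.resources.files("nuclens").joinpath("data/u6oh_table1.csv")
    with importlib.resources.as_file(ref) as p:
        return read_transitions(p)


# ---------------------------------------------------------------------------
# spectrum CSV
# ---------------------------------------------------------------------------

def write_spectrum(table: SpectrumTable, path: str | Path) -> None:
    """Write a spectrum as CSV: E_eV, lambda_nm, sigma_cm2, dsigma_cm2,
    eps_M1cm1, deps_M1cm1, plus one sigma_state_<l>_cm2 column per retained
    per-state component.  Values round-trip at 10+ significant digits.
    """
    n = len(table.E_grid)
    zeros = np.zeros(n)
    cols: dict[str, np.ndarray] = {
        "E_eV": table.E_grid,
        "lambda_nm": table.lambda_grid,
        "sigma_cm2": table.sigma,
        "dsigma_cm2": table.dsigma,
        "eps_M1cm1": table.eps if table.eps is not None else zeros,
        "deps_M1cm1": table.deps if table.deps is not None else zeros,
    }
    if table.per_state:
        for state in sorted(table.per_state):
            cols[f"sigma_state_{state}_cm2"] = table.per_state[state]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectrum(path: str | Path) -> SpectrumTable:
    df = pd.read_csv(path)
    per_state = {}
    for col in df.columns:
        if col.startswith("sigma_state_"):
            state = int(col.removeprefix("sigma_state_").removesuffix("_cm2"))
            per_state[state] = df[col].to_numpy()
    return SpectrumTable(
        E_grid=df["E_eV"].to_numpy(),
        sigma=df["sigma_cm2"].to_numpy(),
        dsigma=df["dsigma_cm2"].to_numpy(),
        eps=df["eps_M1cm1"].to_numpy(),
        deps=df["deps_M1cm1"].to_numpy(),
        per_state=per_state or None,
    )


# ---------------------------------------------------------------------------
# point-charge fields (electrostatic embedding)
# ---------------------------------------------------------------------------

def write_pointcharge_field(snapshot, xyz_path: str | Path,
                            charges_path: str | Path) -> None:
    """Write a snapshot as electrostatic-embedding inputs: a chromophore-only
    XYZ file, and a whitespace-delimited ``x y z q`` file (Å, e) holding the
    solvent point charges.
    """
    mol = snapshot.atoms
    if mol.charges is None:
        raise ValueError("snapshot atoms carry no charges (atom index 0)")
    chrom_idx = np.asarray(snapshot.chromophore_idx, dtype=int)
    solvent_idx = np.setdiff1d(np.arange(mol.n_atoms), chrom_idx)
    chrom = Molecule(
        symbols=[mol.symbols[i] for i in chrom_idx],
        masses=mol.masses[chrom_idx],
        coords=mol.coords[chrom_idx],
        label=f"chromophore of {snapshot.source_id}",
    )
    write_xyz_frames([chrom], xyz_path)
    rows = []
    for i in solvent_idx:
        x, y, z = mol.coords[i]
        rows.append(f"{x:18.10f} {y:18.10f} {z:18.10f} {mol.charges[i]:14.8f}")
    Path(charges_path).write_text("\n".join(rows) + "\n", encoding="utf-8")
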