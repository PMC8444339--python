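"""Harmonic normal-mode analysis for Wigner sampling.

Mass-weights a Cartesian Hessian (Hartree/Bohr², masses in amu), projects
out rigid translations and rotations (Eckart frame at the input geometry),
and diagonalizes in the internal subspace.  Frequencies are reported as
wavenumbers in cm⁻¹; imaginary modes are encoded as negative wavenumbers.
Also reads pre-computed frequency data from Molden files or a simple JSON
schema (see docs/frequency_schema.md).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .constants import BOHR_A, CM1_PER_SQRT_HARTREE_AMU_BOHR2
from .io_formats import ATOMIC_MASSES, Molecule

__all__ = [
    "Hessian",
    "NormalModes",
    "normal_mode_analysis",
    "read_frequency_data",
    "write_molden",
    "write_frequency_json",
]

#: smallest principal moment of inertia (amu·Å²) below which a molecule is
#: treated as linear (5 zero modes instead of 6)
LINEARITY_TOL_AMU_A2 = 1e-8


@dataclass
class Hessian:
    """Cartesian second-derivative matrix in Hartree/Bohr², 3N×3N."""

    molecule: Molecule
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n3 = 3 * self.molecule.n_atoms
        if self.matrix.shape != (n3, n3):
            raise ValueError(
                f"Hessian shape {self.matrix.shape} does not match 3N = {n3}"
            )
        asym = np.max(np.abs(self.matrix - self.matrix.T))
        if asym > 1e-8:
            raise ValueError(f"Hessian not symmetric (max asymmetry {asym:.2e})")


@dataclass
class NormalModes:
    """Validated harmonic modes: wavenumbers (cm⁻¹, negative = imaginary)
    and mass-weighted displacement vectors, one column per retained mode."""

    molecule: Molecule
    freqs_cm1: np.ndarray
    modes: np.ndarray  # (3N, n_modes), orthonormal columns, mass-weighted
    n_projected: int

    def __post_init__(self) -> None:
        self.freqs_cm1 = np.asarray(self.freqs_cm1, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        n3 = 3 * self.molecule.n_atoms
        if self.modes.shape != (n3, len(self.freqs_cm1)):
            raise ValueError("mode matrix must be 3N x n_modes")
        if self.n_projected not in (5, 6):
            raise ValueError("n_projected must be 5 (linear) or 6")
        gram = self.modes.T @ self.modes
        dev = np.max(np.abs(gram - np.eye(len(self.freqs_cm1))))
        if dev > 1e-6:
            raise ValueError(f"modes not orthonormal (Gram deviation {dev:.2e})")

    @property
    def n_modes(self) -> int:
        return len(self.freqs_cm1)


def _trans_rot_vectors(mol: Molecule) -> tuple[np.ndarray, bool]:
    """Orthonormalized mass-weighted translation/rotation vectors and a
    linearity flag.  Linearity: smallest principal moment < tolerance."""
    m = mol.masses
    sqm = np.sqrt(m)
    com = (m[:, None] * mol.coords).sum(axis=0) / m.sum()
    r = mol.coords - com

    inertia = np.zeros((3, 3))
    for i in range(mol.n_atoms):
        x = r[i]
        inertia += m[i] * (np.dot(x, x) * np.eye(3) - np.outer(x, x))
    moments = np.linalg.eigvalsh(inertia)
    linear = mol.n_atoms >= 2 and moments[0] < LINEARITY_TOL_AMU_A2

    n = mol.n_atoms
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = sqm
        vecs.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rot = sqm[:, None] * np.cross(r, e)
        vecs.append(rot.ravel())
    tr = np.array(vecs).T  # (3N, 6)
    # orthonormalize, dropping null rotations (linear molecule / single atom)
    q, s, _ = np.linalg.svd(tr, full_matrices=False)
    keep = s > 1e-10 * s[0]
    return q[:, keep], linear


def normal_mode_analysis(h: Hessian) -> NormalModes:
    """Mass-weight, Eckart-project, and diagonalize a Hessian.

    Eigenvalues λ of the projected mass-weighted Hessian (Hartree/(amu·Bohr²))
    map to wavenumbers sign(λ)·sqrt(|λ|)·5140.49 cm⁻¹.
    """
    mol = h.molecule
    if mol.n_atoms < 2:
        raise ValueError("normal-mode analysis needs at least 2 atoms")
    sqm = np.repeat(np.sqrt(mol.masses), 3)
    hmw = h.matrix / np.outer(sqm, sqm)

    tr, linear = _trans_rot_vectors(mol)
    n_projected = 5 if linear else 6
    # orthonormal basis of the internal (vibrational) subspace
    internal = scipy.linalg.null_space(tr.T)
    hint = internal.T @ hmw @ internal
    evals, evecs = np.linalg.eigh(hint)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * CM1_PER_SQRT_HARTREE_AMU_BOHR2
    modes = internal @ evecs
    return NormalModes(
        molecule=mol, freqs_cm1=freqs, modes=modes, n_projected=n_projected
    )


# ---------------------------------------------------------------------------
# frequency-data I/O (Molden + JSON)
# ---------------------------------------------------------------------------

def _mass_weight_and_check(mol: Molecule, cart_modes: np.ndarray,
                           tol: float = 1e-3) -> np.ndarray:
    """Convert Cartesian mode vectors (columns) to normalized mass-weighted
    ones and re-orthonormalize; reject if the Gram deviation exceeds tol."""
    sqm = np.repeat(np.sqrt(mol.masses), 3)
    mw = cart_modes * sqm[:, None]
    norms = np.linalg.norm(mw, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm mode vector")
    mw = mw / norms
    gram = mw.T @ mw
    dev = np.max(np.abs(gram - np.eye(mw.shape[1])))
    if dev > tol:
        raise ValueError(
            f"mode vectors are not orthonormalizable: Gram deviation {dev:.3e} "
            f"exceeds {tol}"
        )
    # symmetric (Löwdin) orthonormalization — closest orthonormal set
    u, _, vt = np.linalg.svd(mw, full_matrices=False)
    return u @ vt


def _infer_n_projected(mol: Molecule, n_modes: int) -> int:
    n3 = 3 * mol.n_atoms
    n_proj = n3 - n_modes
    if n_proj not in (5, 6):
        raise ValueError(
            f"{n_modes} modes for {mol.n_atoms} atoms implies "
            f"{n_proj} projected modes; expected 5 or 6"
        )
    _, linear = _trans_rot_vectors(mol)
    expected = 5 if linear else 6
    if n_proj != expected:
        warnings.warn(
            f"file provides {n_modes} modes (n_projected = {n_proj}) but the "
            f"geometry suggests {expected}; accepting the file's count",
            stacklevel=3,
        )
    return n_proj


def read_frequency_data(path: str | Path) -> NormalModes:
    """Read normal-mode data from a Molden file ([FREQ]/[FR-COORD]/
    [FR-NORM-COORD] blocks) or the documented JSON schema.  Cartesian mode
    vectors are mass-weighted and Löwdin re-orthonormalized."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if text.lstrip().startswith("{"):
        return _read_frequency_json(text)
    if "[FREQ]" in text:
        return _read_molden(text)
    raise ValueError(f"{path}: neither a JSON frequency file nor Molden format")


def _read_frequency_json(text: str) -> NormalModes:
    data = json.loads(text)
    symbols = list(data["symbols"])
    if "masses_amu" in data:
        masses = np.asarray(data["masses_amu"], dtype=float)
    else:
        masses = np.array([ATOMIC_MASSES[s] for s in symbols])
    mol = Molecule(
        symbols=symbols,
        masses=masses,
        coords=np.asarray(data["coords_A"], dtype=float),
        label=data.get("label", ""),
    )
    freqs = np.asarray(data["freqs_cm1"], dtype=float)
    cart = np.asarray(data["modes_cartesian"], dtype=float)  # (n_modes, 3N)
    if cart.shape != (len(freqs), 3 * mol.n_atoms):
        raise ValueError("modes_cartesian must be (n_modes, 3N)")
    modes = _mass_weight_and_check(mol, cart.T)
    n_proj = _infer_n_projected(mol, len(freqs))
    return NormalModes(molecule=mol, freqs_cm1=freqs, modes=modes,
                       n_projected=n_proj)


def _read_molden(text: str) -> NormalModes:
    lines = text.splitlines()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("["):
            current = stripped.split("]")[0].strip("[").upper()
            sections[current] = []
        elif current is not None:
            sections[current].append(ln)

    if "FREQ" not in sections or "FR-COORD" not in sections:
        raise ValueError("Molden file lacks [FREQ]/[FR-COORD] blocks")
    freqs = np.array([float(ln.split()[0]) for ln in sections["FREQ"]
                      if ln.strip()])
    symbols, coords = [], []
    for ln in sections["FR-COORD"]:
        if not ln.strip():
            continue
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    coords_A = np.array(coords) * BOHR_A  # Molden FR-COORD is in Bohr
    masses = np.array([ATOMIC_MASSES[s] for s in symbols])
    mol = Molecule(symbols=symbols, masses=masses, coords=coords_A)

    vib_lines = sections.get("FR-NORM-COORD", [])
    n3 = 3 * mol.n_atoms
    cart_modes: list[list[float]] = []
    cur: list[float] | None = None
    for ln in vib_lines:
        stripped = ln.strip().lower()
        if not stripped:
            continue
        if stripped.startswith("vibration"):
            if cur is not None:
                cart_modes.append(cur)
            cur = []
        elif cur is not None:
            cur.extend(float(p) for p in ln.split())
    if cur is not None:
        cart_modes.append(cur)
    cart = np.array(cart_modes, dtype=float)
    if cart.shape != (len(freqs), n3):
        raise ValueError(
            f"Molden normal coordinates have shape {cart.shape}, expected "
            f"({len(freqs)}, {n3})"
        )
    modes = _mass_weight_and_check(mol, cart.T)
    n_proj = _infer_n_projected(mol, len(freqs))
    return NormalModes(molecule=mol, freqs_cm1=freqs, modes=modes,
                       n_projected=n_proj)


def write_molden(nm: NormalModes, path: str | Path) -> None:
    """Write normal modes as a Molden frequency file (coordinates in Bohr,
    Cartesian displacement vectors)."""
    mol = nm.molecule
    out = ["[Molden Format]", "[FREQ]"]
    out += [f" {f:14.6f}" for f in nm.freqs_cm1]
    out.append("[FR-COORD]")
    for i, sym in enumerate(mol.symbols):
        x, y, z = mol.coords[i] / BOHR_A
        out.append(f" {sym:<3s} {x:16.10f} {y:16.10f} {z:16.10f}")
    out.append("[FR-NORM-COORD]")
    sqm = np.repeat(np.sqrt(mol.masses), 3)
    for k in range(nm.n_modes):
        out.append(f" vibration {k + 1}")
        cart = (nm.modes[:, k] / sqm).reshape(-1, 3)
        for row in cart:
            out.append(f"   {row[0]:16.10f} {row[1]:16.10f} {row[2]:16.10f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def write_frequency_json(nm: NormalModes, path: str | Path) -> None:
    """Write the JSON frequency schema (the Molden-free interchange format)."""
    mol = nm.molecule
    sqm = np.repeat(np.sqrt(mol.masses), 3)
    cart = (nm.modes / sqm[:, None]).T  # (n_modes, 3N) Cartesian
    data = {
        "symbols": mol.symbols,
        "masses_amu": mol.masses.tolist(),
        "coords_A": mol.coords.tolist(),
        "freqs_cm1": nm.freqs_cm1.tolist(),
        "modes_cartesian": cart.tolist(),
        "label": mol.label,
    }
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")
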