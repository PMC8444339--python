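"""Synthetic fixtures: analytic harmonic toy molecules, transition-table
ensembles with stated Gaussian spreads, and toy water boxes.

The toy Hessians are assembled exactly at equilibrium as H = Σ_t k_t B_tᵀB_t
from the Wilson B rows of the internal coordinates (bond, angle, dihedral),
so symmetry and translational invariance hold to machine precision.  The
"analytic" frequencies come from the Wilson GF-matrix route (eigenvalues of
F^{1/2} G F^{1/2} with G = B M⁻¹ Bᵀ), an independent path from the
Eckart-projected Cartesian diagonalization it serves to cross-check; the
diatomic additionally has the literal closed form ω = sqrt(k/μ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_A, CM1_PER_SQRT_HARTREE_AMU_BOHR2
from .io_formats import Molecule, TransitionRecord
from .normal_modes import Hessian
from .solvate import SolvatedSnapshot, _pair_displacements

__all__ = ["ToySpec", "make_toy_hessian", "make_transition_ensemble",
           "make_toy_waterbox"]

TOY_KINDS = ("diatomic", "bent-triatomic", "enone-chain")

#: rigid 3-point water geometry and charges (common 3-point model)
WATER_OH_A = 0.9572
WATER_HOH_DEG = 104.52
WATER_CHARGES = (-0.834, 0.417, 0.417)  # O, H, H


@dataclass
class ToySpec:
    """Parameters of an analytic toy molecule.

    Force constants are Hartree/Bohr² for bonds and Hartree/rad² for angles
    and the torsion; masses are amu.  Defaults give wavenumbers in the
    few-hundred to few-thousand cm⁻¹ range typical of organic chromophores.
    """

    kind: str = "diatomic"
    k_bond: float = 0.3
    k_angle: float = 0.15
    k_dihedral: float = 0.02
    masses: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TOY_KINDS:
            raise ValueError(f"unsupported toy kind {self.kind!r}; "
                             f"choose from {TOY_KINDS}")
        for name in ("k_bond", "k_angle", "k_dihedral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.masses is not None and any(m <= 0 for m in self.masses):
            raise ValueError("masses must be positive")


# ---------------------------------------------------------------------------
# Wilson B rows (exact analytic gradients of internal coordinates)
# ---------------------------------------------------------------------------

def _b_bond(x: np.ndarray, i: int, j: int) -> np.ndarray:
    b = np.zeros_like(x)
    u = x[j] - x[i]
    u /= np.linalg.norm(u)
    b[i] = -u
    b[j] = u
    return b.ravel()


def _b_angle(x: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """Gradient of the bend angle (rad) at j."""
    b = np.zeros_like(x)
    rij = x[i] - x[j]
    rkj = x[k] - x[j]
    nij = np.linalg.norm(rij)
    nkj = np.linalg.norm(rkj)
    u = rij / nij
    v = rkj / nkj
    cos_t = float(np.clip(u @ v, -1.0, 1.0))
    sin_t = np.sqrt(1.0 - cos_t**2)
    b[i] = (cos_t * u - v) / (nij * sin_t)
    b[k] = (cos_t * v - u) / (nkj * sin_t)
    b[j] = -b[i] - b[k]
    return b.ravel()


def _b_dihedral(x: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Gradient of the signed torsion i-j-k-l (rad)."""
    b = np.zeros_like(x)
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    di = nb2 / (n1 @ n1) * n1
    dl = -nb2 / (n2 @ n2) * n2
    f12 = (b1 @ b2) / (nb2**2)
    f32 = (b3 @ b2) / (nb2**2)
    b[i] = di
    b[l] = dl
    b[j] = -(1.0 + f12) * di + f32 * dl
    b[k] = -(1.0 + f32) * dl + f12 * di
    return b.ravel()


def _toy_topology(spec: ToySpec):
    """Equilibrium geometry (Å), symbols, masses, and (B-row builder, k)
    internal-coordinate list for the requested toy."""
    if spec.kind == "diatomic":
        symbols = ["C", "C"]
        masses = spec.masses or (12.011, 12.011)
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.25]])
        internals = [(("bond", 0, 1), spec.k_bond)]
    elif spec.kind == "bent-triatomic":
        symbols = ["O", "H", "H"]
        masses = spec.masses or (15.999, 1.008, 1.008)
        r, half = 0.9572, np.radians(WATER_HOH_DEG / 2.0)
        coords = np.array([
            [0.0, 0.0, 0.0],
            [r * np.sin(half), 0.0, r * np.cos(half)],
            [-r * np.sin(half), 0.0, r * np.cos(half)],
        ])
        internals = [
            (("bond", 0, 1), spec.k_bond),
            (("bond", 0, 2), spec.k_bond),
            (("angle", 1, 0, 2), spec.k_angle),
        ]
    else:  # enone-chain: planar O=C–C=C with a torsional spring
        symbols = ["O", "C", "C", "C"]
        masses = spec.masses or (15.999, 12.011, 12.011, 12.011)
        # planar zigzag, 120° angles, trans (dihedral 180°)
        def place(prev, cur, r, up):
            ang = np.radians(30.0 if up else -30.0)
            d = np.array([np.cos(ang), np.sin(ang), 0.0])
            return cur + r * d
        a0 = np.zeros(3)
        a1 = a0 + 1.22 * np.array([np.cos(np.radians(-30)),
                                   np.sin(np.radians(-30)), 0.0])
        a2 = place(a0, a1, 1.47, True)
        a3 = place(a1, a2, 1.34, False)
        coords = np.array([a0, a1, a2, a3])
        internals = [
            (("bond", 0, 1), spec.k_bond),
            (("bond", 1, 2), spec.k_bond),
            (("bond", 2, 3), spec.k_bond),
            (("angle", 0, 1, 2), spec.k_angle),
            (("angle", 1, 2, 3), spec.k_angle),
            (("dihedral", 0, 1, 2, 3), spec.k_dihedral),
        ]
    return symbols, np.asarray(masses, float), coords, internals


def _b_matrix(coords_bohr: np.ndarray, internals) -> np.ndarray:
    rows = []
    for (kind, *idx), _k in internals:
        if kind == "bond":
            rows.append(_b_bond(coords_bohr, *idx))
        elif kind == "angle":
            rows.append(_b_angle(coords_bohr, *idx))
        else:
            rows.append(_b_dihedral(coords_bohr, *idx))
    return np.array(rows)


def make_toy_hessian(spec: ToySpec) -> tuple[Molecule, Hessian, np.ndarray]:
    """Assemble a toy molecule, its exact harmonic Cartesian Hessian, and the
    analytic (GF-route) wavenumbers of its vibrational modes, sorted
    ascending in cm⁻¹."""
    symbols, masses, coords_A, internals = _toy_topology(spec)
    mol = Molecule(symbols=symbols, masses=masses, coords=coords_A)

    coords_bohr = coords_A / BOHR_A
    b = _b_matrix(coords_bohr, internals)
    ks = np.array([k for _, k in internals])
    h = (b * ks[:, None]).T @ b  # Σ k bᵀb, Hartree/Bohr²
    hess = Hessian(molecule=mol, matrix=h)

    if spec.kind == "diatomic":
        mu = masses[0] * masses[1] / (masses[0] + masses[1])
        freqs = np.array([np.sqrt(spec.k_bond / mu)
                          * CM1_PER_SQRT_HARTREE_AMU_BOHR2])
    else:
        # Wilson GF: nonzero spectrum of F^{1/2} G F^{1/2}, G = B M⁻¹ Bᵀ
        minv = np.repeat(1.0 / masses, 3)
        g = b @ (minv[:, None] * b.T)
        fsq = np.sqrt(ks)
        sym = fsq[:, None] * g * fsq[None, :]
        lam = np.linalg.eigvalsh(sym)
        lam = lam[lam > 1e-12 * lam.max()]
        freqs = np.sort(np.sqrt(lam) * CM1_PER_SQRT_HARTREE_AMU_BOHR2)
    return mol, hess, freqs


def make_transition_ensemble(n_geoms: int,
                             states: list[tuple[float, float, float, float]],
                             seed: int) -> list[TransitionRecord]:
    """Gaussian transition ensemble: per geometry k and state l,
    E ~ N(mean_E, sd_E²) and f ~ N(mean_f, sd_f²) clipped at 0.

    ``states`` entries are (mean_E_eV, sd_E_eV, mean_f, sd_f); each mean
    energy must exceed 3·sd_E so sampled energies stay positive.
    """
    if n_geoms <= 0:
        raise ValueError("n_geoms must be positive")
    for l, (me, se, mf, sf) in enumerate(states, start=1):
        if se < 0 or sf < 0:
            raise ValueError(f"state {l}: standard deviations must be >= 0")
        if me <= 3.0 * se:
            raise ValueError(
                f"state {l}: mean_E = {me} must exceed 3*sd_E = {3 * se} "
                f"to keep energies positive"
            )
        if mf < 0:
            raise ValueError(f"state {l}: mean_f must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_geoms):
        for l, (me, se, mf, sf) in enumerate(states, start=1):
            e = float(rng.normal(me, se)) if se > 0 else me
            f = float(rng.normal(mf, sf)) if sf > 0 else mf
            records.append(TransitionRecord(
                geom_id=k, state=l, E_va_eV=max(e, 1e-6), f=max(f, 0.0)
            ))
    return records


def _water_template() -> np.ndarray:
    half = np.radians(WATER_HOH_DEG / 2.0)
    return np.array([
        [0.0, 0.0, 0.0],
        [WATER_OH_A * np.sin(half), 0.0, WATER_OH_A * np.cos(half)],
        [-WATER_OH_A * np.sin(half), 0.0, WATER_OH_A * np.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_toy_waterbox(n_waters: int, box_A: float, chromophore: Molecule,
                      seed: int, min_sep_A: float = 2.0,
                      max_attempts: int = 10_000) -> SolvatedSnapshot:
    """Pack rigid 3-point waters around a centered chromophore.

    Waters get random positions and orientations, rejected until every
    inter-molecular atom pair is at least ``min_sep_A`` apart (minimum
    image).  Charges: O −0.834 e, H +0.417 e; chromophore charges default
    to 0 if absent.
    """
    box = np.full(3, float(box_A))
    chrom = chromophore.copy()
    com = chrom.coords.mean(axis=0)
    chrom_coords = chrom.coords - com + box / 2.0

    rng = np.random.default_rng(seed)
    placed = [chrom_coords]
    template = _water_template()
    for w in range(n_waters):
        for attempt in range(max_attempts):
            rot = _random_rotation(rng)
            pos = rng.uniform(0.0, box_A, size=3)
            water = template @ rot.T + pos
            occupied = np.vstack(placed)
            if _pair_displacements(water, occupied, box).min() >= min_sep_A:
                placed.append(water)
                break
        else:
            raise RuntimeError(
                f"could not place water {w + 1}/{n_waters} after "
                f"{max_attempts} attempts; try a larger box"
            )

    symbols = list(chrom.symbols) + ["O", "H", "H"] * n_waters
    masses = np.concatenate(
        [chrom.masses, np.tile([15.999, 1.008, 1.008], n_waters)]
    )
    coords = np.vstack(placed)
    chrom_charges = (chrom.charges if chrom.charges is not None
                     else np.zeros(chrom.n_atoms))
    charges = np.concatenate(
        [chrom_charges, np.tile(WATER_CHARGES, n_waters)]
    )
    atoms = Molecule(symbols=symbols, masses=masses, coords=coords,
                     charges=charges, label=f"toy waterbox seed={seed}")
    return SolvatedSnapshot(
        atoms=atoms,
        chromophore_idx=np.arange(chrom.n_atoms),
        box=box,
        source_id=f"toy-waterbox-{seed}",
    )
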