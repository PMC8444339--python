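"""Wigner sampling of the harmonic vibrational ground state.

Geometries are drawn from the coordinate marginal of the Wigner distribution
of each retained normal mode: Q_i ~ N(0, ħ/(2ω_i)) at T = 0, with the
thermal factor coth(ħω_i/2k_BT) at T > 0.  Cartesian geometries are
reconstructed as R_eq + M^(−1/2)·L·Q.  Momenta are not sampled — absorption
line shapes need geometries only.  Near-zero modes below a wavenumber cutoff
are skipped (and recorded): their Gaussian widths diverge as 1/√ω.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import wigner_q_variance_amu_A2
from .io_formats import Molecule
from .normal_modes import NormalModes

__all__ = ["WignerEnsemble", "sample_wigner", "ensemble_geometry_stats"]


@dataclass
class WignerEnsemble:
    """A seeded ensemble of geometries sharing the reference atom ordering.

    ``coords`` has shape (n_samples, N, 3) in Å; ``geometries`` materializes
    them as Molecule objects on demand.
    """

    reference: Molecule
    coords: np.ndarray
    seed: int
    n_samples: int
    temperature_K: float = 0.0
    skipped_modes: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        expected = (self.n_samples, self.reference.n_atoms, 3)
        if self.coords.shape != expected:
            raise ValueError(
                f"coords shape {self.coords.shape}, expected {expected}"
            )

    @property
    def geometries(self) -> list[Molecule]:
        ref = self.reference
        return [
            Molecule(symbols=list(ref.symbols), masses=ref.masses.copy(),
                     coords=self.coords[k], label=f"wigner-{k}")
            for k in range(self.n_samples)
        ]

    def __len__(self) -> int:
        return self.n_samples


def sample_wigner(nm: NormalModes, n_samples: int, seed: int,
                  temperature_K: float = 0.0,
                  freq_cutoff_cm1: float = 10.0,
                  imaginary_policy: str = "error") -> WignerEnsemble:
    """Draw ``n_samples`` geometries from the harmonic Wigner distribution.

    One generator seeded with ``seed`` fills the normal coordinates in
    mode-major order (all samples of mode 0, then mode 1, …), which makes
    ensembles bit-reproducible.  ``imaginary_policy`` may be "error" or
    "skip-imaginary" for imaginary modes above the cutoff.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if imaginary_policy not in ("error", "skip-imaginary"):
        raise ValueError(f"unknown imaginary_policy {imaginary_policy!r}")

    skipped: list[tuple[float, str]] = []
    active: list[int] = []
    for i, f in enumerate(nm.freqs_cm1):
        if abs(f) < freq_cutoff_cm1:
            skipped.append((float(f), "below cutoff"))
        elif f < 0:
            if imaginary_policy == "error":
                raise ValueError(
                    f"imaginary frequency {f:.2f} cm^-1 above the cutoff; "
                    f"use imaginary_policy='skip-imaginary' to skip it"
                )
            warnings.warn(
                f"skipping imaginary mode at {f:.2f} cm^-1", stacklevel=2
            )
            skipped.append((float(f), "imaginary"))
        else:
            active.append(i)

    mol = nm.molecule
    rng = np.random.default_rng(seed)
    q = np.empty((len(active), n_samples))
    for row, i in enumerate(active):  # mode-major draw order
        var = wigner_q_variance_amu_A2(nm.freqs_cm1[i], temperature_K)
        q[row] = rng.normal(0.0, np.sqrt(var), size=n_samples)

    # Δx_mw = L Q ; Δx = M^(−1/2) Δx_mw
    lmat = nm.modes[:, active]  # (3N, n_active)
    disp_mw = lmat @ q  # (3N, n_samples)
    inv_sqm = 1.0 / np.repeat(np.sqrt(mol.masses), 3)
    disp = (disp_mw * inv_sqm[:, None]).T.reshape(n_samples, mol.n_atoms, 3)
    coords = mol.coords[None, :, :] + disp
    return WignerEnsemble(
        reference=mol, coords=coords, seed=seed, n_samples=n_samples,
        temperature_K=temperature_K, skipped_modes=skipped,
    )


# ---------------------------------------------------------------------------
# internal-coordinate diagnostics
# ---------------------------------------------------------------------------

def bond_length(coords: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(coords[..., j, :] - coords[..., i, :], axis=-1)


def bend_angle(coords: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """Angle at j between atoms i and k, degrees."""
    u = coords[..., i, :] - coords[..., j, :]
    v = coords[..., k, :] - coords[..., j, :]
    cosang = (u * v).sum(-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Signed torsion i-j-k-l in (−180°, 180°]."""
    b1 = coords[..., j, :] - coords[..., i, :]
    b2 = coords[..., k, :] - coords[..., j, :]
    b3 = coords[..., l, :] - coords[..., k, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m1 * n2).sum(-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def ensemble_geometry_stats(ens: WignerEnsemble,
                            internal_coords: list[tuple],
                            bin_width: float = 1.0) -> dict:
    """Distribution summaries of bonds/angles/dihedrals over an ensemble.

    ``internal_coords`` entries are ("bond", i, j), ("angle", i, j, k) or
    ("dihedral", i, j, k, l).  Dihedrals are reported in (−180°, 180°] with
    circular mean and circular standard deviation; bonds in Å, angles in
    degrees.  Each summary holds mean, std, and a histogram of the stated
    bin width.
    """
    n_atoms = ens.reference.n_atoms
    out: dict = {}
    for spec in internal_coords:
        kind, *idx = spec
        if len(set(idx)) != len(idx):
            raise ValueError(f"{spec}: atom indices must be distinct")
        if any(not 0 <= i < n_atoms for i in idx):
            raise ValueError(f"{spec}: atom index out of range (N={n_atoms})")
        if kind == "bond" and len(idx) == 2:
            vals = bond_length(ens.coords, *idx)
            circular = False
        elif kind == "angle" and len(idx) == 3:
            vals = bend_angle(ens.coords, *idx)
            circular = False
        elif kind == "dihedral" and len(idx) == 4:
            vals = dihedral_angle(ens.coords, *idx)
            circular = True
        else:
            raise ValueError(f"unsupported internal coordinate spec {spec}")

        if circular:
            rad = np.radians(vals)
            z = np.exp(1j * rad).mean()
            mean = float(np.degrees(np.angle(z)))
            if mean <= -180.0:
                mean += 360.0
            r = min(abs(z), 1.0)
            std = float(np.degrees(np.sqrt(max(-2.0 * np.log(r), 0.0)))) \
                if r > 0 else float("inf")
            hist_range = (-180.0, 180.0)
        else:
            mean = float(vals.mean())
            std = float(vals.std(ddof=0))
            hist_range = (float(vals.min()), float(vals.max()) + bin_width)
        nbins = max(1, int(np.ceil((hist_range[1] - hist_range[0]) / bin_width)))
        counts, edges = np.histogram(vals, bins=nbins, range=hist_range)
        out[spec] = {
            "mean": mean,
            "std": std,
            "counts": counts,
            "bin_edges": edges,
            "circular": circular,
        }
    return out
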