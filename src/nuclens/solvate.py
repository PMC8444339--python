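"""The condensed-phase insertion protocol: distribute Wigner geometries over
MD snapshots, substitute each chromophore in place after a least-squares
alignment onto its instantaneous pose, and provide the structural
diagnostics (clash report, radial distribution function) used to validate
that the solvent shell is preserved.

Solvent atoms are never touched: coordinates, ordering, and point charges
pass through bit-identically.  The short frozen-chromophore relaxation MD
that a production workflow runs afterwards needs an MD engine and is out of
scope here; the clash report flags where that relaxation would act.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import Molecule
from .lstrans_align import apply_transform, best_fit

__all__ = [
    "SolvatedSnapshot",
    "assign_wigner_to_snapshots",
    "insert_chromophore",
    "clash_report",
    "radial_distribution",
]


@dataclass
class SolvatedSnapshot:
    """All atoms of one MD frame plus the chromophore's atom indices.

    ``box`` holds orthorhombic box lengths (Å) for minimum-image distances,
    or None for a non-periodic cluster.  ``substitution_rmsd`` records the
    residual of the last chromophore insertion, if any.
    """

    atoms: Molecule
    chromophore_idx: np.ndarray
    box: np.ndarray | None = None
    source_id: str = ""
    substitution_rmsd: float | None = None

    def __post_init__(self) -> None:
        self.chromophore_idx = np.asarray(self.chromophore_idx, dtype=int)
        n = self.atoms.n_atoms
        if len(np.unique(self.chromophore_idx)) != len(self.chromophore_idx):
            raise ValueError("chromophore indices must be distinct")
        if np.any((self.chromophore_idx < 0) | (self.chromophore_idx >= n)):
            raise ValueError("chromophore index out of range")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def solvent_idx(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.atoms.n_atoms), self.chromophore_idx)


def assign_wigner_to_snapshots(n_wigner: int, snapshot_ids: Sequence,
                               seed: int) -> dict[int, object]:
    """Randomly assign each Wigner geometry to exactly one snapshot.

    With s snapshots every snapshot receives ⌊n/s⌋ or ⌈n/s⌉ geometries
    (remainder spread round-robin, with a warning); 100 geometries over 10
    or 25 snapshots give the 100-in-10 and 100-in-25 ratios exactly.  The
    assignment is a seeded uniform random permutation dealt in order.
    """
    if len(snapshot_ids) == 0:
        raise ValueError("snapshot list must not be empty")
    if n_wigner <= 0:
        raise ValueError("n_wigner must be positive")
    s = len(snapshot_ids)
    if n_wigner % s != 0:
        warnings.warn(
            f"{n_wigner} geometries do not divide evenly over {s} snapshots; "
            f"spreading the remainder round-robin",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_wigner)
    return {int(w): snapshot_ids[pos % s] for pos, w in enumerate(perm)}


def insert_chromophore(snapshot: SolvatedSnapshot, wigner_geom: Molecule,
                       weights: np.ndarray | None = None) -> SolvatedSnapshot:
    """Substitute the snapshot's chromophore with a Wigner geometry.

    The Wigner geometry is least-squares aligned onto the chromophore's
    instantaneous pose (``lstrans_align.best_fit``) and swapped in; every
    solvent atom stays bit-identical.  The residual RMSD of the substitution
    is recorded on the returned snapshot.
    """
    idx = snapshot.chromophore_idx
    if wigner_geom.n_atoms != len(idx):
        raise ValueError(
            f"chromophore has {len(idx)} atoms but the Wigner geometry has "
            f"{wigner_geom.n_atoms}"
        )
    target = snapshot.atoms.coords[idx]
    fit = best_fit(wigner_geom.coords, target, weights)
    new_chrom = apply_transform(fit, wigner_geom.coords)

    new_coords = snapshot.atoms.coords.copy()
    new_coords[idx] = new_chrom
    new_atoms = Molecule(
        symbols=list(snapshot.atoms.symbols),
        masses=snapshot.atoms.masses.copy(),
        coords=new_coords,
        charges=None if snapshot.atoms.charges is None
        else snapshot.atoms.charges.copy(),
        label=snapshot.atoms.label,
    )
    return replace(snapshot, atoms=new_atoms, substitution_rmsd=fit.rmsd_after)


def _pair_displacements(a: np.ndarray, b: np.ndarray,
                        box: np.ndarray | None) -> np.ndarray:
    """All pair distance magnitudes between coordinate sets a (n,3) and
    b (m,3), minimum-image if a box is given; shape (n, m)."""
    d = a[:, None, :] - b[None, :, :]
    if box is not None:
        d -= box * np.round(d / box)
    return np.sqrt((d ** 2).sum(-1))


def clash_report(snapshot: SolvatedSnapshot,
                 min_dist_A: float = 1.5) -> list[tuple[int, int, float]]:
    """Chromophore–solvent pairs closer than ``min_dist_A`` (minimum-image if
    periodic), as (chromophore atom, solvent atom, distance), sorted by
    distance."""
    cidx = snapshot.chromophore_idx
    sidx = snapshot.solvent_idx
    if len(sidx) == 0:
        return []
    dist = _pair_displacements(
        snapshot.atoms.coords[cidx], snapshot.atoms.coords[sidx], snapshot.box
    )
    ci, si = np.nonzero(dist < min_dist_A)
    hits = [(int(cidx[i]), int(sidx[j]), float(dist[i, j]))
            for i, j in zip(ci, si)]
    return sorted(hits, key=lambda t: t[2])


def radial_distribution(snapshots: Sequence[SolvatedSnapshot],
                        group_a: Sequence[int], group_b: Sequence[int],
                        r_max: float, bin_width: float) -> dict:
    """Radial distribution function g(r) between two atom groups over an
    ensemble of frames.

    Pair-distance counts are normalized by the ideal-gas shell expectation at
    the ensemble's mean number density of group_b, so g(r) → 1 at large r
    for homogeneous systems.  Shared atoms between the groups are excluded
    as self-pairs.  Requires a box (for the reference density) on every
    frame.  Returns {"r": bin centers, "g": g(r), "counts": raw counts,
    "bin_edges": edges}.
    """
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("atom selectors must not be empty")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    density_sum = 0.0
    n_pairs_per_frame = None
    for snap in snapshots:
        if snap.box is None:
            raise ValueError(
                "g(r) normalization needs a box volume on every snapshot"
            )
        coords = snap.atoms.coords
        dist = _pair_displacements(coords[ga], coords[gb], snap.box)
        # exclude self pairs where the groups overlap
        mask = ga[:, None] != gb[None, :]
        d = dist[mask]
        counts += np.histogram(d, bins=edges)[0]
        vol = float(np.prod(snap.box))
        density_sum += len(gb) / vol
        n_pairs_per_frame = mask.sum(axis=1).mean()  # avg partners per a-atom

    n_frames = len(snapshots)
    rho_b = density_sum / n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # expected partners in each shell for one a-atom in one frame
    expected = rho_b * shell_vol * (n_pairs_per_frame / len(gb))
    norm = n_frames * len(ga) * expected
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, counts / norm, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return {"r": centers, "g": g, "counts": counts, "bin_edges": edges}
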