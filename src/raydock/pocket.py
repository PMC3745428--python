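"""Grid-based surface-pocket mapping.

A cubic lattice is laid over the neighbourhood of a target residue and each
point is labelled protein (inside any atom) or solvent.  Solvent points
flanked by protein along a scan line — the protein–solvent–protein criterion
of the LIGSITE family of pocket detectors — become "pocket" points; pocket
points touching the protein form the pocket *shell*, and a thin ring of
surface points just outside the pocket becomes the *forbidden* set.  The
shell and forbidden points, together with a ray origin buried along the
pocket→protein center-of-mass axis, fully describe the pocket topography
used for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures import InputError, ProteinStructure

__all__ = [
    "LABEL_S",
    "LABEL_P",
    "LABEL_PSP",
    "LABEL_SHELL",
    "LABEL_FORBIDDEN",
    "SCAN_DIRECTIONS",
    "GridMap",
    "PocketDefinition",
    "NoPocketError",
    "build_grid",
    "classify_grid",
    "mark_pocket",
    "extract_shell_and_forbidden",
    "compute_ray_origin",
]

LABEL_S = 0  # solvent
LABEL_P = 1  # protein
LABEL_PSP = 2  # pocket (protein-solvent-protein)
LABEL_SHELL = 3  # pocket point in contact with protein
LABEL_FORBIDDEN = 4  # surface point just outside the pocket perimeter

#: 3 axes + 4 body diagonals; each line is scanned in both senses.
SCAN_DIRECTIONS: Tuple[Tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


class NoPocketError(ValueError):
    """The grid pipeline found no pocket points at the target site."""


@dataclass
class GridMap:
    lower: np.ndarray  # corner of the lattice, Å
    spacing: float  # Å
    labels: np.ndarray  # int8 lattice of LABEL_* codes

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def point(self, idx: Sequence[int]) -> np.ndarray:
        return self.lower + self.spacing * np.asarray(idx, dtype=float)

    def points_where(self, label: int) -> np.ndarray:
        """Cartesian coordinates of all grid points carrying *label*, shape (n, 3)."""
        idx = np.argwhere(self.labels == label)
        return self.lower + self.spacing * idx.astype(float)

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def write_labels_csv(self, path, skip_solvent: bool = True) -> None:
        """Debug snapshot: one `x,y,z,label` row per grid point."""
        names = {LABEL_S: "S", LABEL_P: "P", LABEL_PSP: "pocket",
                 LABEL_SHELL: "shell", LABEL_FORBIDDEN: "forbidden"}
        with open(path, "w") as fh:
            fh.write("x,y,z,label\n")
            for idx in np.ndindex(*self.labels.shape):
                lab = int(self.labels[idx])
                if skip_solvent and lab == LABEL_S:
                    continue
                x, y, z = self.point(idx)
                fh.write(f"{x:.3f},{y:.3f},{z:.3f},{names[lab]}\n")


@dataclass
class PocketDefinition:
    """Shell + forbidden points and the ray origin (set by :func:`compute_ray_origin`)."""

    shell_points: np.ndarray  # (n, 3) Å
    forbidden_points: np.ndarray  # (m, 3) Å
    origin: np.ndarray | None = None
    offset: float = 30.0

    @property
    def pocket_com(self) -> np.ndarray:
        return self.shell_points.mean(axis=0)


def build_grid(
    protein: ProteinStructure,
    target: Tuple[str, int],
    spacing: float = 0.5,
    extent: float = 15.0,
) -> GridMap:
    """Cubic grid of side ``2*extent`` centered on the target residue centroid.

    dims per axis = floor(2*extent / spacing) + 1.
    """
    if spacing <= 0:
        raise InputError(f"spacing must be positive, got {spacing}")
    if extent <= spacing:
        raise InputError(f"extent ({extent}) must exceed spacing ({spacing})")
    res_atoms = protein.residue_atoms(*target)
    center = np.mean([a.position for a in res_atoms], axis=0)
    n = int(np.floor(2.0 * extent / spacing)) + 1
    lower = center - extent
    labels = np.full((n, n, n), LABEL_S, dtype=np.int8)
    return GridMap(lower=lower, spacing=spacing, labels=labels)


def classify_grid(grid: GridMap, protein: ProteinStructure) -> GridMap:
    """Label grid points P if within (≤, inclusive) any atom's radius, else S."""
    labels = np.full(grid.dims, LABEL_S, dtype=np.int8)
    n = np.array(grid.dims)
    sp = grid.spacing
    for pos, r in zip(protein.positions, protein.radii):
        # index window covering the atom's sphere
        lo = np.maximum(np.ceil((pos - r - grid.lower) / sp).astype(int), 0)
        hi = np.minimum(np.floor((pos + r - grid.lower) / sp).astype(int), n - 1)
        if np.any(lo > hi):
            continue
        ax = [grid.lower[k] + sp * np.arange(lo[k], hi[k] + 1) - pos[k] for k in range(3)]
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        block = labels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        block[d2 <= r * r + 1e-12] = LABEL_P
    grid.labels = labels
    return grid


def _shift(mask: np.ndarray, step: Tuple[int, int, int]) -> np.ndarray:
    """out[i] = mask[i + step], zero-filled at the boundary."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(step):
        if s > 0:
            src[ax] = slice(s, None)
            dst[ax] = slice(None, -s)
        elif s < 0:
            src[ax] = slice(None, s)
            dst[ax] = slice(-s, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def mark_pocket(grid: GridMap, max_span: int = 12) -> GridMap:
    """Mark solvent points lying between two protein points as pocket (PSP).

    A solvent point is promoted iff along at least one of the seven scan
    directions a protein point occurs within ``max_span`` grid steps on
    *each* side.  (Taking the nearest flanking P point on each side, the
    intervening points are necessarily non-protein, so no extra gap test is
    needed.)
    """
    P = grid.labels == LABEL_P
    S = grid.labels == LABEL_S
    psp = np.zeros_like(P)
    for d in SCAN_DIRECTIONS:
        fwd = np.zeros_like(P)
        bwd = np.zeros_like(P)
        cur_f, cur_b = P, P
        neg = tuple(-c for c in d)
        for _ in range(max_span):
            cur_f = _shift(cur_f, d)
            cur_b = _shift(cur_b, neg)
            fwd |= cur_f
            bwd |= cur_b
        psp |= fwd & bwd
    grid.labels[psp & S] = LABEL_PSP
    return grid


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
_FULL_STRUCT = ndimage.generate_binary_structure(3, 3)  # 26-connectivity


def extract_shell_and_forbidden(
    grid: GridMap,
    ring_width: int = 2,
    keep_largest_component: bool = True,
) -> PocketDefinition:
    """Shell = pocket points face-adjacent to protein; forbidden = surface ring.

    The shell is optionally reduced to its largest connected component
    (26-neighbor connectivity — a discretized curved surface is one sheet
    under vertex adjacency but shatters under face adjacency) so stray
    disjoint pockets do not pollute the ray map.  Forbidden points are
    solvent points touching the protein (face adjacency) within
    ``ring_width * spacing`` (Euclidean) of at least one shell point.
    """
    P = grid.labels == LABEL_P
    psp = grid.labels == LABEL_PSP
    if not psp.any():
        raise NoPocketError("no pocket points found")
    touches_P = ndimage.binary_dilation(P, structure=_FACE_STRUCT) & ~P
    shell = psp & touches_P
    if not shell.any():
        raise NoPocketError("no pocket points in contact with the protein")
    if keep_largest_component:
        comp, ncomp = ndimage.label(shell, structure=_FULL_STRUCT)
        if ncomp > 1:
            sizes = ndimage.sum_labels(shell, comp, index=np.arange(1, ncomp + 1))
            shell = comp == (1 + int(np.argmax(sizes)))
    grid.labels[shell] = LABEL_SHELL

    shell_xyz = grid.lower + grid.spacing * np.argwhere(shell).astype(float)
    surface_S = (grid.labels == LABEL_S) & touches_P
    cand = np.argwhere(surface_S)
    forb_xyz = np.empty((0, 3))
    if len(cand):
        cand_xyz = grid.lower + grid.spacing * cand.astype(float)
        tree = cKDTree(shell_xyz)
        dist, _ = tree.query(cand_xyz, k=1)
        near = dist <= ring_width * grid.spacing + 1e-9
        forb_xyz = cand_xyz[near]
        for idx in cand[near]:
            grid.labels[tuple(idx)] = LABEL_FORBIDDEN
    return PocketDefinition(shell_points=shell_xyz, forbidden_points=forb_xyz)


def compute_ray_origin(
    pocket: PocketDefinition,
    protein: ProteinStructure,
    offset: float = 30.0,
) -> PocketDefinition:
    """Place the ray origin *offset* Å from the pocket COM toward the protein COM."""
    if len(pocket.shell_points) == 0:
        raise NoPocketError("pocket has no shell points")
    pcom = pocket.pocket_com
    direction = protein.center_of_mass - pcom
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("pocket and protein centers of mass coincide; geometry degenerate")
    pocket.origin = pcom + offset * direction / norm
    pocket.offset = offset
    return pocket
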