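"""Rigid-body least-squares superposition (Kabsch) and RMSD reporting.

The optimal proper rotation is obtained from the SVD of the coordinate
cross-covariance with a determinant correction, so reflections are never
returned. Sequence-independent alignment searches are out of scope: the
caller supplies matched coordinate lists (or residue-range selections of
alpha-carbons), which is how the reference superpositions of this analysis
are specified — e.g. aligning the two predicted Gtsf zinc fingers
(residues 8-34 and 35-64) onto the zinc fingers of mouse Gtsf1, chain A of
PDB 6X46 (residues 14-41 and 48-75), available as a named preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .sequences import Span


@dataclass
class SuperpositionResult:
    """Proper rotation + translation minimising RMSD, and the RMSD itself."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Both arguments are (n, 3) arrays with matched row order, n >= 3 and a
    non-degenerate (non-collinear) configuration.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(
            f"coordinate shapes must match as (n, 3); got {mobile.shape} vs {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 matched atoms, got {n}")
    if not (np.isfinite(mobile).all() and np.isfinite(target).all()):
        raise GeometryError("non-finite coordinates")

    mob_c = mobile - mobile.mean(axis=0)
    tar_c = target - target.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2 or np.linalg.matrix_rank(tar_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) coordinate configuration")

    h = mob_c.T @ tar_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = target.mean(axis=0) - rot @ mobile.mean(axis=0)
    moved = mobile @ rot.T + translation
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd, n_atoms=n)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between two matched coordinate arrays (no fitting)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise GeometryError("coordinate shapes must match")
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


def select_ca_coords(chain_atoms, spans: list[Span]) -> np.ndarray:
    """Alpha-carbon coordinates of the residues in ``spans``, in span order.

    ``chain_atoms`` is a biotite AtomArray of a single chain.
    """
    coords = []
    for span in spans:
        mask = (
            (chain_atoms.atom_name == "CA")
            & (chain_atoms.res_id >= span.start)
            & (chain_atoms.res_id <= span.end)
        )
        coords.append(chain_atoms.coord[mask])
    return np.concatenate(coords, axis=0)


#: Residue-range pairings for the zinc-finger reference superposition:
#: predicted Gtsf zinc fingers (mobile) onto chain A of PDB 6X46 (target).
ZNF_PRESET = {
    "mobile": [Span(8, 34), Span(35, 64)],
    "target": [Span(14, 41), Span(48, 75)],
}
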