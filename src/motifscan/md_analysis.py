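"""Contact maps, hydrogen bonds and motif anchoring from MD trajectories.

A trajectory is a fixed two-chain topology plus per-frame coordinates
(multi-model PDB or in-memory arrays). Two residues are in contact in a
frame when any atom pair is within 4.5 Å (inclusive); by default only
heavy atoms are counted, for consistency with the model-contact rule
(``include_h=True`` restores all-atom distances). Per-replicate maps of
contact frequencies over frames are averaged elementwise across replicate
runs started from the same structure.

The hydrogen-bond criterion is donor-acceptor heavy-atom distance
<= 3.5 Å with a donor-hydrogen-acceptor angle >= 150 degrees, falling back
to distance-only when no hydrogen is named; both knobs are exposed and the
defaults are a standard geometric reconstruction rather than a quantity
fixed by the analysis itself.

Anchoring of a motif residue in a pocket is classified per replicate: the
replicate is anchored when the fraction of frames in which the motif
side-chain heavy atoms come within the cutoff of any pocket heavy atom
reaches the frame-fraction threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, FormatError, NotFoundError, ValidationError
from .model_contacts import ContactSet, _min_residue_distance_matrix, _LIGHT_ELEMENTS

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _heavy_mask(atoms: struc.AtomArray) -> np.ndarray:
    elements = np.char.upper(atoms.element.astype("U4"))
    return ~np.isin(elements, list(_LIGHT_ELEMENTS))


@dataclass
class Trajectory:
    """Two-chain topology with per-frame coordinates.

    ``atoms`` is the topology (annotations only; its own coordinates are
    frame 0), ``coords`` has shape (n_frames, n_atoms, 3) in Å.
    ``frame_spacing_ns`` is metadata only.
    """

    atoms: struc.AtomArray
    coords: np.ndarray
    bait_chain: str = "A"
    prey_chain: str = "B"
    frame_spacing_ns: float | None = None
    _res: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.atoms.array_length():
            raise FormatError(
                f"coordinate array {self.coords.shape} does not match the "
                f"{self.atoms.array_length()}-atom topology"
            )
        if self.coords.shape[0] < 1:
            raise FormatError("trajectory must contain at least one frame")
        for chain in (self.bait_chain, self.prey_chain):
            mask = self.atoms.chain_id == chain
            if not mask.any():
                raise FormatError(f"chain {chain!r} not present in topology")
            sub = self.atoms[mask]
            starts = struc.get_residue_starts(sub)
            positions = np.zeros(sub.array_length(), dtype=int)
            res_ids = []
            for pos, start in enumerate(starts, start=1):
                end = starts[pos] if pos < len(starts) else sub.array_length()
                positions[start:end] = pos
                res_ids.append(int(sub.res_id[start]))
            self._res[chain] = (mask, positions, np.asarray(res_ids))

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def chain_residues(self, chain: str) -> np.ndarray:
        """Author residue ids of a chain, in topology order."""
        return self._res[chain][2]


@dataclass
class ContactMap:
    """Per-residue-pair contact frequency over frames and replicates."""

    bait_axis: np.ndarray
    prey_axis: np.ndarray
    freq: np.ndarray
    n_frames: int
    n_replicates: int = 1

    def frequency(self, bait_res: int, prey_res: int) -> float:
        i = int(np.nonzero(self.bait_axis == bait_res)[0][0])
        j = int(np.nonzero(self.prey_axis == prey_res)[0][0])
        return float(self.freq[i, j])


@dataclass
class HBondSeries:
    """Per-frame geometry of one donor(-hydrogen)-acceptor triple."""

    donor: tuple
    acceptor: tuple
    hydrogen: tuple | None
    distances: np.ndarray
    angles: np.ndarray | None
    engaged: np.ndarray

    @property
    def persistence(self) -> float:
        return float(self.engaged.mean())


@dataclass
class AnchoringResult:
    """Per-replicate in-pocket frame fractions and anchored calls."""

    fractions: list[float]
    anchored: list[bool]
    threshold: float

    @property
    def n_replicates(self) -> int:
        return len(self.fractions)

    @property
    def n_anchored(self) -> int:
        return sum(self.anchored)


def load_trajectory(
    path: str | Path,
    bait_chain: str = "A",
    prey_chain: str = "B",
    frame_spacing_ns: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory with a fixed topology."""
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    keep = np.isin(stack.chain_id, [bait_chain, prey_chain])
    stack = stack[..., keep]
    template = stack[0]
    return Trajectory(
        atoms=template,
        coords=stack.coord,
        bait_chain=bait_chain,
        prey_chain=prey_chain,
        frame_spacing_ns=frame_spacing_ns,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB."""
    stack = struc.from_template(traj.atoms, traj.coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _chain_atom_selection(traj: Trajectory, chain: str, include_h: bool):
    mask, positions, res_ids = traj._res[chain]
    idx = np.nonzero(mask)[0]
    sub = traj.atoms[mask]
    keep = np.ones(len(idx), bool) if include_h else _heavy_mask(sub)
    return idx[keep], positions[keep], len(res_ids)


def frame_contacts(
    traj: Trajectory, frame: int, cutoff: float = 4.5, include_h: bool = False
) -> ContactSet:
    """Inter-chain residue contacts of one frame (inclusive <= cutoff)."""
    if not 0 <= frame < traj.n_frames:
        raise ValidationError(f"frame {frame} outside 0..{traj.n_frames - 1}")
    ia, pa, na = _chain_atom_selection(traj, traj.bait_chain, include_h)
    ib, pb, nb = _chain_atom_selection(traj, traj.prey_chain, include_h)
    dmat = _min_residue_distance_matrix(
        traj.coords[frame, ia], pa, na, traj.coords[frame, ib], pb, nb
    )
    bait_res = traj.chain_residues(traj.bait_chain)
    prey_res = traj.chain_residues(traj.prey_chain)
    hit = dmat <= cutoff
    pairs = frozenset(
        (int(bait_res[i]), int(prey_res[j])) for i, j in zip(*np.nonzero(hit))
    )
    min_dist = {
        (int(bait_res[i]), int(prey_res[j])): float(dmat[i, j])
        for i, j in zip(*np.nonzero(hit))
    }
    return ContactSet(pairs=pairs, frame="global", min_dist=min_dist)


def trajectory_contact_map(
    traj: Trajectory, cutoff: float = 4.5, include_h: bool = False
) -> ContactMap:
    """Fraction of frames in which each inter-chain pair is in contact."""
    ia, pa, na = _chain_atom_selection(traj, traj.bait_chain, include_h)
    ib, pb, nb = _chain_atom_selection(traj, traj.prey_chain, include_h)
    counts = np.zeros((na, nb), dtype=int)
    for f in range(traj.n_frames):
        dmat = _min_residue_distance_matrix(
            traj.coords[f, ia], pa, na, traj.coords[f, ib], pb, nb
        )
        counts += dmat <= cutoff
    return ContactMap(
        bait_axis=traj.chain_residues(traj.bait_chain).copy(),
        prey_axis=traj.chain_residues(traj.prey_chain).copy(),
        freq=counts / traj.n_frames,
        n_frames=traj.n_frames,
        n_replicates=1,
    )


def average_maps(maps: Sequence[ContactMap]) -> ContactMap:
    """Elementwise mean of replicate maps sharing identical axes."""
    if not maps:
        raise ValidationError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if (
            not np.array_equal(m.bait_axis, first.bait_axis)
            or not np.array_equal(m.prey_axis, first.prey_axis)
        ):
            raise ValidationError("contact-map axes differ between replicates")
    return ContactMap(
        bait_axis=first.bait_axis.copy(),
        prey_axis=first.prey_axis.copy(),
        freq=np.mean([m.freq for m in maps], axis=0),
        n_frames=sum(m.n_frames for m in maps),
        n_replicates=sum(m.n_replicates for m in maps),
    )


def marginal_profiles(cmap: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """(bait profile, prey profile): per-residue sums of pair frequencies.

    These are sums of probabilities (the relative interaction profile of a
    residue with the whole partner chain), so values may exceed 1.
    """
    return cmap.freq.sum(axis=1), cmap.freq.sum(axis=0)


def _atom_index(traj: Trajectory, spec: tuple) -> int:
    chain, res_id, name = spec
    mask = (
        (traj.atoms.chain_id == chain)
        & (traj.atoms.res_id == int(res_id))
        & (traj.atoms.atom_name == name)
    )
    idx = np.nonzero(mask)[0]
    if len(idx) != 1:
        raise NotFoundError(f"atom {spec} matched {len(idx)} atoms in topology")
    return int(idx[0])


def hbond_series(
    traj: Trajectory,
    donor: tuple,
    acceptor: tuple,
    hydrogen: tuple | None = None,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
) -> HBondSeries:
    """Per-frame donor-acceptor distance (and D-H-A angle) time series.

    Atoms are addressed as ``(chain_id, res_id, atom_name)``. Engagement
    requires distance <= ``dist_cutoff`` and, when a hydrogen is given,
    D-H-A angle >= ``angle_cutoff`` degrees.
    """
    d = traj.coords[:, _atom_index(traj, donor)]
    a = traj.coords[:, _atom_index(traj, acceptor)]
    distances = np.linalg.norm(d - a, axis=1)
    engaged = distances <= dist_cutoff
    angles = None
    if hydrogen is not None:
        h = traj.coords[:, _atom_index(traj, hydrogen)]
        v1, v2 = d - h, a - h
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        engaged = engaged & (angles >= angle_cutoff)
    return HBondSeries(
        donor=donor, acceptor=acceptor, hydrogen=hydrogen,
        distances=distances, angles=angles, engaged=engaged,
    )


def in_pocket_fraction(
    traj: Trajectory,
    motif_residue: int,
    pocket_residues: Iterable[int],
    cutoff: float = 4.5,
) -> float:
    """Fraction of frames with the motif side chain within ``cutoff`` of
    any pocket heavy atom.

    The motif residue is addressed on the prey chain by author residue id;
    pocket residues live on the bait chain. Side chain means heavy atoms
    outside the peptide backbone; a residue without any (glycine) cannot be
    classified and raises :class:`ConfigError`.
    """
    prey_mask = (traj.atoms.chain_id == traj.prey_chain) & (
        traj.atoms.res_id == int(motif_residue)
    )
    if not prey_mask.any():
        raise NotFoundError(f"prey residue {motif_residue} not in topology")
    side = prey_mask & ~np.isin(traj.atoms.atom_name, list(_BACKBONE)) & _heavy_mask(traj.atoms)
    if not side.any():
        raise ConfigError(
            f"motif residue {motif_residue} has no side-chain heavy atoms"
        )
    pocket = (traj.atoms.chain_id == traj.bait_chain) & np.isin(
        traj.atoms.res_id, np.asarray(list(pocket_residues), dtype=int)
    ) & _heavy_mask(traj.atoms)
    if not pocket.any():
        raise NotFoundError("no pocket heavy atoms found in topology")
    sc = traj.coords[:, side]  # (F, k, 3)
    pk = traj.coords[:, pocket]  # (F, m, 3)
    dists = np.linalg.norm(sc[:, :, None, :] - pk[:, None, :, :], axis=-1)
    per_frame_min = dists.reshape(traj.n_frames, -1).min(axis=1)
    return float((per_frame_min <= cutoff).mean())


def classify_anchored(
    trajs: Sequence[Trajectory],
    motif_residue: int,
    pocket_residues: Iterable[int],
    cutoff: float = 4.5,
    frame_fraction_threshold: float = 0.5,
) -> AnchoringResult:
    """Anchored/unanchored call per replicate and the aggregate count."""
    if not 0 < frame_fraction_threshold <= 1:
        raise ValidationError("frame_fraction_threshold must be in (0, 1]")
    pocket = list(pocket_residues)
    fractions = [
        in_pocket_fraction(t, motif_residue, pocket, cutoff=cutoff) for t in trajs
    ]
    return AnchoringResult(
        fractions=fractions,
        anchored=[f >= frame_fraction_threshold for f in fractions],
        threshold=frame_fraction_threshold,
    )


def contact_map_to_frame(cmap: ContactMap) -> pd.DataFrame:
    """Dense frequency table, prey residues as rows and bait as columns."""
    return pd.DataFrame(
        cmap.freq.T,
        index=pd.Index(cmap.prey_axis, name="prey_idx"),
        columns=pd.Index(cmap.bait_axis, name="bait_idx"),
    )
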