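"""Synthetic fixtures with planted interfaces.

Everything downstream of structure prediction and MD depends only on
interatomic distances, so the generators build pseudo-atom residues with
no physical geometry: bait residues sit on a widely spaced line, prey
residues on a parallel offset grid, and each planted (bait, prey) residue
pair receives a dedicated bait pseudo-atom placed exactly at the requested
contact distance from the prey residue's base atom. All non-planted
inter-chain residue pairs are kept at or beyond a background separation.
Every construction is verified against its own constraints by a direct
distance scan before being returned, and an infeasible request raises
:class:`ConstructionError` instead of silently degrading.

The mock prediction scan emulates the statistical structure the consensus
analysis assumes: motif-to-pocket contacts recur in every run whose
fragment covers the motif residue, while spurious contacts flip on
independently per off-pair per run with probability ``noise_rate``
(Bernoulli noise — the simplest null under which the covering-run
denominator logic is testable). Run confidences are drawn higher for
motif-covering runs than for the rest, emulating the contrast between
confident motif-fragment predictions and poor full-length ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .errors import ConstructionError
from .fragment_scan import RunEntry
from .md_analysis import Trajectory
from .model_contacts import ContactSet, StructureModel, model_from_atoms
from .sequences import Span

_EXTRA_NAMES = ("CG", "CD")


@dataclass(frozen=True)
class ToyComplexSpec:
    """A two-chain pseudo-atom complex with planted residue contacts.

    ``planted_pairs`` are 1-based local (bait_idx, prey_idx) pairs whose
    closest-atom distance will equal ``contact_distance`` exactly; every
    other inter-chain pair stays at least ``background_min_distance`` away.
    ``bait_res_start``/``prey_res_start`` set the author residue numbering
    written to the PDB (1 for fragment-local models, global indices for MD
    topologies).
    """

    bait_length: int
    prey_length: int
    planted_pairs: tuple = ()
    contact_distance: float = 4.0
    background_min_distance: float = 8.0
    include_hydrogens: bool = False
    bait_res_start: int = 1
    prey_res_start: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bait_length < 1 or self.prey_length < 1:
            raise ConstructionError("chain lengths must be >= 1")
        if self.contact_distance >= self.background_min_distance:
            raise ConstructionError(
                "contact_distance must be smaller than background_min_distance"
            )
        pairs = tuple(tuple(p) for p in self.planted_pairs)
        if len(set(pairs)) != len(pairs):
            raise ConstructionError("duplicate planted pairs")
        for i, j in pairs:
            if not (1 <= i <= self.bait_length and 1 <= j <= self.prey_length):
                raise ConstructionError(f"planted pair ({i}, {j}) outside chain lengths")
        object.__setattr__(self, "planted_pairs", pairs)


def _complex_atoms(spec: ToyComplexSpec) -> struc.AtomArray:
    """Deterministic coordinates realising the planted-contact constraints."""
    bg = spec.background_min_distance
    spacing = max(20.0, bg + 8.0)
    z_plane = bg + 2.0
    z_far = z_plane + 40.0

    partners: dict[int, list[int]] = {}
    for i, j in spec.planted_pairs:
        partners.setdefault(j, []).append(i)

    bait_base = {i: np.array([(i - 1) * spacing, 0.0, 0.0]) for i in range(1, spec.bait_length + 1)}
    prey_base = {}
    for j in range(1, spec.prey_length + 1):
        if j in partners:
            mean_x = float(np.mean([bait_base[i][0] for i in partners[j]]))
            prey_base[j] = np.array([mean_x, (j - 1) * spacing, z_plane])
        else:
            prey_base[j] = np.array([(j - 1) * spacing, 0.0, z_far])

    rows = []  # (chain, res_idx_local, atom_name, element, xyz)

    def add(chain: str, res: int, name: str, element: str, xyz: np.ndarray) -> None:
        rows.append((chain, res, name, element, np.asarray(xyz, float)))

    prey_of_bait: dict[int, list[int]] = {}
    for i, j in spec.planted_pairs:
        prey_of_bait.setdefault(i, []).append(j)
    for i in range(1, spec.bait_length + 1):
        base = bait_base[i]
        add("A", i, "CB", "C", base)
        for k in range(i % 3):
            add("A", i, _EXTRA_NAMES[k], "C", base + [0.0, 0.0, -0.4 * (k + 1)])
        if spec.include_hydrogens:
            add("A", i, "H", "H", base + [0.3, 0.0, -0.3])
        # dedicated pseudo-atoms realising this residue's planted contacts
        for k, j in enumerate(prey_of_bait.get(i, ()), start=1):
            direction = base - prey_base[j]
            direction = direction / np.linalg.norm(direction)
            add("A", i, f"CX{k}", "C", prey_base[j] + spec.contact_distance * direction)

    for j in range(1, spec.prey_length + 1):
        base = prey_base[j]
        add("B", j, "CB", "C", base)
        for k in range(j % 3):
            add("B", j, _EXTRA_NAMES[k], "C", base + [0.0, 0.0, 0.4 * (k + 1)])
        if spec.include_hydrogens:
            add("B", j, "H", "H", base + [0.3, 0.0, 0.3])

    atoms = struc.AtomArray(len(rows))
    atoms.chain_id = np.array([r[0] for r in rows])
    atoms.res_id = np.array(
        [
            r[1] + (spec.bait_res_start - 1 if r[0] == "A" else spec.prey_res_start - 1)
            for r in rows
        ]
    )
    atoms.res_name = np.full(len(rows), "ALA")
    atoms.atom_name = np.array([r[2] for r in rows])
    atoms.element = np.array([r[3] for r in rows])
    atoms.hetero = np.zeros(len(rows), bool)
    atoms.coord = np.stack([r[4] for r in rows])
    _verify_constraints(atoms, spec)
    return atoms


def _verify_constraints(atoms: struc.AtomArray, spec: ToyComplexSpec) -> None:
    """Brute distance scan proving the construction met its constraints."""
    from scipy.spatial.distance import cdist

    heavy = atoms.element != "H"
    a = atoms[(atoms.chain_id == "A") & heavy]
    b = atoms[(atoms.chain_id == "B") & heavy]
    d = cdist(a.coord, b.coord)
    planted = set(spec.planted_pairs)
    n_a = spec.bait_length
    n_b = spec.prey_length
    mins = np.full((n_a, n_b), np.inf)
    ia = a.res_id - spec.bait_res_start
    jb = b.res_id - spec.prey_res_start
    idx = (ia[:, None] * n_b + jb[None, :]).ravel()
    np.minimum.at(mins.reshape(-1), idx, d.ravel())
    planted_mask = np.zeros((n_a, n_b), bool)
    for i, j in planted:
        planted_mask[i - 1, j - 1] = True
    # coordinates are float32 and PDB columns carry 3 decimals, so planted
    # distances are exact only to coordinate precision
    tol = 2e-3
    bad_planted = planted_mask & (np.abs(mins - spec.contact_distance) > tol)
    bad_background = ~planted_mask & (mins < spec.background_min_distance - tol)
    if bad_planted.any() or bad_background.any():
        i, j = next(zip(*np.nonzero(bad_planted | bad_background)))
        raise ConstructionError(
            f"infeasible geometry: pair ({i + 1}, {j + 1}) realised at "
            f"{mins[i, j]:.3f} Å violates its constraint"
        )


def make_toy_complex(spec: ToyComplexSpec) -> StructureModel:
    """Build the complex in memory as a two-chain model."""
    return model_from_atoms(_complex_atoms(spec), "A", "B")


from functools import lru_cache


@lru_cache(maxsize=64)
def _pdb_text(spec: ToyComplexSpec) -> str:
    pdb = PDBFile()
    pdb.set_structure(_complex_atoms(spec))
    return "\n".join(pdb.lines) + "\n"


def write_toy_complex(spec: ToyComplexSpec, path: str | Path) -> None:
    Path(path).write_text(_pdb_text(spec))


# ---------------------------------------------------------------------------
# mock prediction scan


def _run_rng(seed: int, run_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, run_index, stream])


def _sample_run_pairs(
    entry: RunEntry,
    run_index: int,
    motif_span: Span,
    pocket_span: Span,
    noise_rate: float,
    seed: int,
) -> tuple[list, list]:
    """(planted local pairs, noise local pairs) for one run.

    A run plants pocket contacts for every motif residue its fragment
    covers, but only when its bait domain actually contains the pocket —
    the interface is specific to one domain; runs against the other
    domains receive noise only. Each remaining (bait, prey) local pair
    flips to a spurious contact independently with probability
    ``noise_rate``.
    """
    frag = entry.fragment
    bait = entry.bait
    planted = []
    overlap = frag.global_span.overlap(motif_span)
    if not bait.span.contains_span(pocket_span):
        overlap = None
    if overlap is not None:
        for j_global in overlap.indices():
            for i_global in pocket_span.indices():
                planted.append(
                    (i_global - bait.span.start + 1, j_global - frag.global_span.start + 1)
                )
    noise = []
    if noise_rate > 0:
        rng = _run_rng(seed, run_index, 0)
        flips = rng.random((bait.span.length, frag.length)) < noise_rate
        planted_set = set(planted)
        noise = [
            (int(i) + 1, int(j) + 1)
            for i, j in zip(*np.nonzero(flips))
            if (int(i) + 1, int(j) + 1) not in planted_set
        ]
    return planted, noise


def simulate_run_contact_sets(
    manifest: Sequence[RunEntry],
    motif_span: Span,
    pocket_span: Span,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> list[tuple[RunEntry, ContactSet]]:
    """Global-frame contact sets of a mock scan, without touching disk.

    Draws from the same per-run random streams as :func:`make_mock_scan`,
    so the file-based route recovers exactly these sets.
    """
    out = []
    for run_index, entry in enumerate(manifest):
        planted, noise = _sample_run_pairs(
            entry, run_index, motif_span, pocket_span, noise_rate, seed
        )
        pairs = frozenset(
            (entry.bait.span.start + i - 1, entry.fragment.global_span.start + j - 1)
            for i, j in planted + noise
        )
        out.append((entry, ContactSet(pairs=pairs, frame="global")))
    return out


def make_mock_scan(
    manifest: Sequence[RunEntry],
    motif_span: Span,
    pocket_span: Span,
    out_dir: str | Path,
    noise_rate: float = 0.05,
    n_models: int = 5,
    seed: int = 0,
    contact_distance: float = 4.0,
    background_min_distance: float = 8.0,
    confident_range: tuple = (0.75, 0.90),
    background_range: tuple = (0.20, 0.40),
) -> dict[str, Path]:
    """Write one prediction-run directory per manifest entry.

    Each run directory holds ``n_models`` PDB models plus a
    ``metadata.json`` with a permuted ranking; only the first-ranked model
    carries the planted interface (lower-ranked decoys have no inter-chain
    contacts), so selecting anything but the top model is detectable.
    Returns run_id -> directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_dirs: dict[str, Path] = {}
    for run_index, entry in enumerate(manifest):
        planted, noise = _sample_run_pairs(
            entry, run_index, motif_span, pocket_span, noise_rate, seed
        )
        rng = _run_rng(seed, run_index, 1)
        run_dir = out_dir / entry.run_id
        run_dir.mkdir(parents=True, exist_ok=True)
        base = dict(
            bait_length=entry.bait.span.length,
            prey_length=entry.fragment.length,
            contact_distance=contact_distance,
            background_min_distance=background_min_distance,
        )
        top_spec = ToyComplexSpec(planted_pairs=tuple(planted + noise), **base)
        decoy_spec = ToyComplexSpec(planted_pairs=(), **base)
        names = [f"model_{k}" for k in range(n_models)]
        ranking = [names[k] for k in rng.permutation(n_models)]
        for name in names:
            spec = top_spec if name == ranking[0] else decoy_spec
            write_toy_complex(spec, run_dir / f"{name}.pdb")
        lo, hi = confident_range if planted else background_range
        metadata = {
            "ranking": ranking,
            "confidence": round(float(rng.uniform(lo, hi)), 4),
            "pae": None,
        }
        (run_dir / "metadata.json").write_text(json.dumps(metadata, indent=1))
        run_dirs[entry.run_id] = run_dir
    return run_dirs


# ---------------------------------------------------------------------------
# toy trajectories


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Replicate trajectory over a toy complex topology.

    ``bound_fraction`` of the frames (the leading ones) keep the bound
    geometry; the rest translate the prey chain far from the bait. If
    ``unbinding_frame`` is set it overrides the fraction: frames before it
    are bound, frames from it on are unbound. ``jitter_sigma`` adds seeded
    isotropic Gaussian noise (Å) to every atom in every frame.
    """

    complex: ToyComplexSpec
    n_frames: int
    bound_fraction: float = 1.0
    jitter_sigma: float = 0.0
    unbinding_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ConstructionError("n_frames must be >= 1")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ConstructionError("bound_fraction must be in [0, 1]")
        if self.unbinding_frame is not None and not 0 <= self.unbinding_frame <= self.n_frames:
            raise ConstructionError("unbinding_frame outside the frame range")


def make_toy_trajectory(spec: ToyTrajectorySpec) -> Trajectory:
    """Build the replicate trajectory in memory."""
    atoms = _complex_atoms(spec.complex)
    n_atoms = atoms.array_length()
    if spec.unbinding_frame is not None:
        n_bound = spec.unbinding_frame
    else:
        n_bound = int(round(spec.bound_fraction * spec.n_frames))
    coords = np.repeat(atoms.coord[None, :, :], spec.n_frames, axis=0)
    prey = atoms.chain_id == "B"
    shift = spec.complex.background_min_distance + 42.0
    coords[n_bound:, prey, 2] += shift
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter_sigma, size=coords.shape)
    return Trajectory(atoms=atoms, coords=coords, bait_chain="A", prey_chain="B")


def write_toy_trajectory(spec: ToyTrajectorySpec, path: str | Path) -> Trajectory:
    """Build the trajectory and also write it as a multi-model PDB."""
    from .md_analysis import write_trajectory

    traj = make_toy_trajectory(spec)
    write_trajectory(traj, path)
    return traj
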