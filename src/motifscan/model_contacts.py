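"""Per-run structure models, ranking metadata and inter-chain contacts.

The model-contact rule: two residues, one per chain, are in contact when
at least one heavy atom of one is less than 5 Å (strict) from a heavy atom
of the other. Heavy means element not hydrogen/deuterium; elements are
taken from the PDB element column and inferred from atom names when blank.
Distances are plain double-precision Euclidean distances over all atom
pairs — no spatial index, so the computation is trivially auditable against
a brute-force scan.

MD frame contacts (see :mod:`motifscan.md_analysis`) reuse the same kernel
with an inclusive <= 4.5 Å rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

from .errors import FormatError, RunError, ValidationError
from .fragment_scan import BaitDomain, Fragment

logger = logging.getLogger(__name__)

#: Elements excluded by the heavy-atom rule.
_LIGHT_ELEMENTS = {"H", "D"}


@dataclass
class ChainView:
    """One chain of a model: atoms plus residue bookkeeping.

    ``positions`` maps every atom to the 1-based sequential position of its
    residue in chain order (the fragment-local frame for prey chains);
    ``res_ids`` holds the author residue number of each sequential position.
    """

    chain_id: str
    atoms: struc.AtomArray
    positions: np.ndarray
    res_ids: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def heavy_mask(self) -> np.ndarray:
        elements = np.char.upper(self.atoms.element.astype("U4"))
        return ~np.isin(elements, list(_LIGHT_ELEMENTS))


@dataclass
class StructureModel:
    """A two-chain (bait, prey) atomic model."""

    bait: ChainView
    prey: ChainView
    source: Path | None = None


@dataclass
class RunMetadata:
    """Ranking metadata of one prediction run."""

    run_id: str
    confidence: float
    ranking: list[str]
    pae: np.ndarray | None = None


@dataclass(frozen=True)
class ContactSet:
    """Inter-chain residue contacts as (bait_index, prey_index) pairs.

    ``frame`` is ``"fragment_local"`` (1-based chain positions) or
    ``"global"`` (full-sequence numbering). ``min_dist`` optionally records
    the closest-atom distance per pair.
    """

    pairs: frozenset
    frame: str = "fragment_local"
    min_dist: dict | None = None

    def __len__(self) -> int:
        return len(self.pairs)


def _chain_view(atoms: struc.AtomArray, chain_id: str) -> ChainView:
    mask = atoms.chain_id == chain_id
    if not mask.any():
        raise FormatError(f"chain {chain_id!r} not present in structure")
    chain = atoms[mask]
    if (chain.element == "").any():
        chain.element = struc.infer_elements(chain)
    # residue order as it appears in the file
    starts = struc.get_residue_starts(chain)
    positions = np.zeros(chain.array_length(), dtype=int)
    res_ids = []
    for pos, start in enumerate(starts, start=1):
        end = starts[pos] if pos < len(starts) else chain.array_length()
        positions[start:end] = pos
        res_ids.append(int(chain.res_id[start]))
    return ChainView(
        chain_id=chain_id,
        atoms=chain,
        positions=positions,
        res_ids=np.asarray(res_ids, dtype=int),
    )


def model_from_atoms(
    atoms: struc.AtomArray,
    bait_chain: str = "A",
    prey_chain: str = "B",
    source: Path | None = None,
) -> StructureModel:
    """Wrap an atom array as a two-chain model, dropping other chains."""
    if atoms.array_length() == 0:
        raise FormatError("structure contains no atoms")
    extra = set(np.unique(atoms.chain_id)) - {bait_chain, prey_chain}
    if extra:
        logger.warning("dropping chains %s (keeping %s, %s)", sorted(extra), bait_chain, prey_chain)
    if not np.isfinite(atoms.coord).all():
        raise FormatError("structure contains non-finite coordinates")
    return StructureModel(
        bait=_chain_view(atoms, bait_chain),
        prey=_chain_view(atoms, prey_chain),
        source=source,
    )


def load_structure(
    path: str | Path, bait_chain: str = "A", prey_chain: str = "B"
) -> StructureModel:
    """Read a PDB model, keeping the named bait and prey chains.

    Hydrogens are retained in storage (the heavy-atom rule filters them at
    measurement time); only the highest-occupancy altloc is kept.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    return model_from_atoms(atoms, bait_chain, prey_chain, source=path)


def _min_residue_distance_matrix(
    coords_a: np.ndarray,
    pos_a: np.ndarray,
    n_a: int,
    coords_b: np.ndarray,
    pos_b: np.ndarray,
    n_b: int,
) -> np.ndarray:
    """(n_a, n_b) matrix of closest-atom distances between residue pairs."""
    out = np.full(n_a * n_b, np.inf)
    if len(coords_a) and len(coords_b):
        d = cdist(coords_a, coords_b)
        idx = ((pos_a[:, None] - 1) * n_b + (pos_b[None, :] - 1)).ravel()
        np.minimum.at(out, idx, d.ravel())
    return out.reshape(n_a, n_b)


def interchain_contacts(
    model: StructureModel,
    cutoff: float = 5.0,
    heavy_only: bool = True,
    inclusive: bool = False,
) -> ContactSet:
    """Residue pairs whose closest atoms are within ``cutoff`` Å.

    The default rule is strict ``< cutoff`` over heavy atoms (predicted
    models); pass ``inclusive=True`` for the ``<=`` variant used on MD
    frames. Returned indices are fragment-local 1-based chain positions.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    views = []
    for view in (model.bait, model.prey):
        mask = view.heavy_mask() if heavy_only else np.ones(view.atoms.array_length(), bool)
        views.append((view.atoms.coord[mask], view.positions[mask]))
    dmat = _min_residue_distance_matrix(
        views[0][0], views[0][1], model.bait.n_residues,
        views[1][0], views[1][1], model.prey.n_residues,
    )
    hit = dmat <= cutoff if inclusive else dmat < cutoff
    pairs = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(*np.nonzero(hit)))
    min_dist = {(int(i) + 1, int(j) + 1): float(dmat[i, j]) for i, j in zip(*np.nonzero(hit))}
    return ContactSet(pairs=pairs, frame="fragment_local", min_dist=min_dist)


def remap_contacts(
    contacts: ContactSet, fragment: Fragment, bait_domain: BaitDomain
) -> ContactSet:
    """Shift fragment-local contacts into global sequence numbering."""
    if contacts.frame != "fragment_local":
        raise ValidationError("contacts are not in the fragment_local frame")
    remapped = {}
    for bait_idx, prey_idx in contacts.pairs:
        if not 1 <= prey_idx <= fragment.length:
            raise ValidationError(
                f"prey index {prey_idx} exceeds fragment length {fragment.length}"
            )
        if not 1 <= bait_idx <= bait_domain.span.length:
            raise ValidationError(
                f"bait index {bait_idx} exceeds bait-domain length {bait_domain.span.length}"
            )
        pair = (
            bait_domain.span.start + bait_idx - 1,
            fragment.global_span.start + prey_idx - 1,
        )
        if contacts.min_dist is not None:
            remapped[pair] = contacts.min_dist[(bait_idx, prey_idx)]
    return ContactSet(
        pairs=frozenset(
            (bait_domain.span.start + i - 1, fragment.global_span.start + j - 1)
            for i, j in contacts.pairs
        ),
        frame="global",
        min_dist=remapped if contacts.min_dist is not None else None,
    )


NATIVE_METADATA = "metadata.json"
RANKING_DEBUG = "ranking_debug.json"


def load_run_metadata(run_dir: str | Path, run_id: str | None = None) -> RunMetadata:
    """Read run metadata from a prediction-run directory.

    Two dialects are understood: the package's native ``metadata.json``
    (``{"ranking": [...], "confidence": x, "pae": [[...]]}``, PAE optional)
    and the AlphaFold ``ranking_debug.json`` (``{"order": [...]}`` plus a
    score map such as ``"iptm+ptm"``), in which case the confidence is the
    score of the first-ranked model.
    """
    run_dir = Path(run_dir)
    run_id = run_id or run_dir.name
    native, legacy = run_dir / NATIVE_METADATA, run_dir / RANKING_DEBUG
    if native.exists():
        data = json.loads(native.read_text())
        ranking = list(data["ranking"])
        confidence = float(data["confidence"])
        pae = np.asarray(data["pae"], dtype=float) if data.get("pae") is not None else None
    elif legacy.exists():
        data = json.loads(legacy.read_text())
        ranking = list(data["order"])
        scores = next(
            (data[k] for k in ("iptm+ptm", "ranking_confidences", "plddts") if k in data),
            None,
        )
        if not ranking or scores is None:
            raise RunError(f"run {run_id}: unusable ranking metadata in {legacy}")
        confidence = float(scores[ranking[0]])
        pae = None
    else:
        raise RunError(f"run {run_id}: no metadata file in {run_dir}")
    if not ranking:
        raise RunError(f"run {run_id}: empty model ranking")
    if not 0.0 <= confidence <= 1.0:
        raise ValidationError(
            f"run {run_id}: model confidence {confidence} outside [0, 1]"
        )
    if pae is not None and (pae.ndim != 2 or pae.shape[0] != pae.shape[1]):
        raise ValidationError(f"run {run_id}: PAE matrix is not square")
    return RunMetadata(run_id=run_id, confidence=confidence, ranking=ranking, pae=pae)


def select_top_model(run_dir: str | Path) -> Path:
    """Path of the first-ranked ('ranked_0') model of a run directory.

    The ranking decides, not file-name order: the model named first in the
    metadata is returned, falling back to a literal ``ranked_0.pdb`` when
    models are stored under rank-based names.
    """
    run_dir = Path(run_dir)
    meta = load_run_metadata(run_dir)
    candidates = [run_dir / f"{meta.ranking[0]}.pdb", run_dir / "ranked_0.pdb"]
    for cand in candidates:
        if cand.exists():
            return cand
    raise RunError(
        f"run {meta.run_id}: top-ranked model {meta.ranking[0]!r} not found in {run_dir}"
    )


def contacts_to_frame(run_contacts: Iterable[tuple[str, ContactSet]]) -> pd.DataFrame:
    """Long-format contact table: run_id, bait_idx, prey_idx, min_distance."""
    rows = []
    for run_id, cs in run_contacts:
        for bait_idx, prey_idx in sorted(cs.pairs):
            dist = cs.min_dist.get((bait_idx, prey_idx)) if cs.min_dist else np.nan
            rows.append(
                {"run_id": run_id, "bait_idx": bait_idx, "prey_idx": prey_idx,
                 "min_distance": dist}
            )
    return pd.DataFrame(rows, columns=["run_id", "bait_idx", "prey_idx", "min_distance"])
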