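"""Cross-run contact-frequency consensus and hotspot detection.

Each bait domain gets its own matrix. For a residue pair (i on the bait,
j on the prey tail) the frequency is hits / denom, where hits counts the
runs in which the pair was in contact and denom counts the runs whose
fragment covers prey residue j — every run of a bait domain contains the
full domain, so coverage reduces to prey coverage. Pairs never covered
carry no frequency. An alternative all-runs denominator is available for
sensitivity analysis.

A hotspot is a maximal 8-connected component of cells at or above a
frequency threshold; the threshold (default 0.5), connectivity and minimum
component size (default 3) operationalise the qualitative notion of a
region of residues consistently predicted in contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConsistencyError, ValidationError
from .fragment_scan import RunEntry
from .model_contacts import ContactSet


@dataclass
class ConsensusMatrix:
    """Contact-frequency matrix of one bait domain.

    ``hits[i, j]`` and ``denom[i, j]`` are indexed by position along
    ``bait_axis`` x ``prey_axis`` (global residue indices). ``freq`` is
    NaN where the denominator is zero.
    """

    bait_name: str
    bait_axis: np.ndarray
    prey_axis: np.ndarray
    hits: np.ndarray
    denom: np.ndarray
    n_runs: int

    @property
    def freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.denom > 0, self.hits / self.denom, np.nan)

    def cell(self, bait_res: int, prey_res: int) -> tuple[int, int]:
        i = int(np.searchsorted(self.bait_axis, bait_res))
        j = int(np.searchsorted(self.prey_axis, prey_res))
        if (
            i >= len(self.bait_axis) or self.bait_axis[i] != bait_res
            or j >= len(self.prey_axis) or self.prey_axis[j] != prey_res
        ):
            raise KeyError(f"pair ({bait_res}, {prey_res}) outside matrix axes")
        return i, j

    def frequency(self, bait_res: int, prey_res: int) -> float:
        i, j = self.cell(bait_res, prey_res)
        return float(self.freq[i, j])


@dataclass
class Hotspot:
    """A connected high-frequency region of the consensus matrix."""

    bait_name: str
    cells: frozenset  # of (bait_res, prey_res) global pairs
    peak_freq: float
    mean_freq: float

    @property
    def bait_residues(self) -> tuple[int, ...]:
        return tuple(sorted({i for i, _ in self.cells}))

    @property
    def prey_residues(self) -> tuple[int, ...]:
        return tuple(sorted({j for _, j in self.cells}))

    def __len__(self) -> int:
        return len(self.cells)


def accumulate_runs(
    runs: Sequence[tuple[RunEntry, ContactSet]],
    cover_denominator: bool = True,
) -> dict[str, ConsensusMatrix]:
    """Aggregate per-run global contact sets into one matrix per bait domain.

    ``cover_denominator=False`` divides by the total run count of the bait
    domain instead of the covering-run count (sensitivity alternative).
    """
    by_bait: dict[str, list[tuple[RunEntry, ContactSet]]] = {}
    for entry, contacts in runs:
        if contacts.frame != "global":
            raise ValidationError(f"run {entry.run_id}: contacts not in global frame")
        by_bait.setdefault(entry.bait.name, []).append((entry, contacts))

    matrices: dict[str, ConsensusMatrix] = {}
    for bait_name, bait_runs in by_bait.items():
        span = bait_runs[0][0].bait.span
        prey_lo = min(e.fragment.global_span.start for e, _ in bait_runs)
        prey_hi = max(e.fragment.global_span.end for e, _ in bait_runs)
        bait_axis = np.arange(span.start, span.end + 1)
        prey_axis = np.arange(prey_lo, prey_hi + 1)
        hits = np.zeros((len(bait_axis), len(prey_axis)), dtype=int)
        denom = np.zeros_like(hits)
        for entry, contacts in bait_runs:
            fspan = entry.fragment.global_span
            if cover_denominator:
                denom[:, fspan.start - prey_lo : fspan.end - prey_lo + 1] += 1
            else:
                denom += 1
            for bait_res, prey_res in contacts.pairs:
                if not span.contains(bait_res) or not fspan.contains(prey_res):
                    raise ConsistencyError(
                        f"run {entry.run_id}: contact ({bait_res}, {prey_res}) outside "
                        f"bait domain ({span.start}, {span.end}) or fragment "
                        f"({fspan.start}, {fspan.end})"
                    )
                hits[bait_res - span.start, prey_res - prey_lo] += 1
        if (hits > denom).any():
            raise ConsistencyError(f"bait {bait_name}: hits exceed denominator")
        matrices[bait_name] = ConsensusMatrix(
            bait_name=bait_name,
            bait_axis=bait_axis,
            prey_axis=prey_axis,
            hits=hits,
            denom=denom,
            n_runs=len(bait_runs),
        )
    return matrices


def observed_submatrix(matrix: ConsensusMatrix) -> ConsensusMatrix:
    """Restrict axes to residues observed in contact at least once."""
    rows = matrix.hits.sum(axis=1) > 0
    cols = matrix.hits.sum(axis=0) > 0
    return ConsensusMatrix(
        bait_name=matrix.bait_name,
        bait_axis=matrix.bait_axis[rows],
        prey_axis=matrix.prey_axis[cols],
        hits=matrix.hits[np.ix_(rows, cols)],
        denom=matrix.denom[np.ix_(rows, cols)],
        n_runs=matrix.n_runs,
    )


#: 8-connectivity stencil on the frequency grid.
_EIGHT = np.ones((3, 3), dtype=int)


def detect_hotspots(
    matrix: ConsensusMatrix,
    freq_threshold: float = 0.5,
    min_size: int = 3,
) -> list[Hotspot]:
    """Maximal 8-connected components of cells with freq >= threshold.

    Components smaller than ``min_size`` cells are discarded; the result
    is sorted by peak frequency, then mean frequency, descending.
    """
    if not 0 < freq_threshold <= 1:
        raise ValidationError(f"freq_threshold must be in (0, 1], got {freq_threshold}")
    freq = matrix.freq
    mask = np.nan_to_num(freq, nan=0.0) >= freq_threshold
    labels, n_comp = ndimage.label(mask, structure=_EIGHT)
    hotspots = []
    for comp in range(1, n_comp + 1):
        ii, jj = np.nonzero(labels == comp)
        if len(ii) < min_size:
            continue
        vals = freq[ii, jj]
        hotspots.append(
            Hotspot(
                bait_name=matrix.bait_name,
                cells=frozenset(
                    (int(matrix.bait_axis[i]), int(matrix.prey_axis[j]))
                    for i, j in zip(ii, jj)
                ),
                peak_freq=float(vals.max()),
                mean_freq=float(vals.mean()),
            )
        )
    hotspots.sort(key=lambda h: (-h.peak_freq, -h.mean_freq, min(h.cells)))
    return hotspots


def consensus_to_long_frame(matrix: ConsensusMatrix, observed_only: bool = True) -> pd.DataFrame:
    """Long-format table (bait_idx, prey_idx, hits, denom, freq)."""
    m = observed_submatrix(matrix) if observed_only else matrix
    ii, jj = np.meshgrid(np.arange(len(m.bait_axis)), np.arange(len(m.prey_axis)), indexing="ij")
    df = pd.DataFrame(
        {
            "bait_idx": m.bait_axis[ii.ravel()],
            "prey_idx": m.prey_axis[jj.ravel()],
            "hits": m.hits.ravel(),
            "denom": m.denom.ravel(),
            "freq": m.freq.ravel(),
        }
    )
    return df[df["denom"] > 0].reset_index(drop=True)


def consensus_to_dense_frame(matrix: ConsensusMatrix) -> pd.DataFrame:
    """Dense frequency matrix, prey residues as rows, bait as columns."""
    return pd.DataFrame(
        matrix.freq.T,
        index=pd.Index(matrix.prey_axis, name="prey_idx"),
        columns=pd.Index(matrix.bait_axis, name="bait_idx"),
    )


def hotspots_to_frame(hotspots: Iterable[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "bait_name": h.bait_name,
            "n_cells": len(h),
            "peak_freq": h.peak_freq,
            "mean_freq": h.mean_freq,
            "bait_residues": ",".join(map(str, h.bait_residues)),
            "prey_residues": ",".join(map(str, h.prey_residues)),
        }
        for h in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=["bait_name", "n_cells", "peak_freq", "mean_freq", "bait_residues", "prey_residues"],
    )


def plot_heatmap(matrix: ConsensusMatrix, path: str | Path, observed_only: bool = True) -> None:
    """Render the consensus heatmap (prey rows, bait columns) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = observed_submatrix(matrix) if observed_only else matrix
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(m.freq.T, aspect="auto", cmap="coolwarm", vmin=0, vmax=1,
                   interpolation="nearest")
    ax.set_xticks(range(len(m.bait_axis)), m.bait_axis, rotation=90, fontsize=5)
    ax.set_yticks(range(len(m.prey_axis)), m.prey_axis, fontsize=6)
    ax.set_xlabel(f"{m.bait_name} residue")
    ax.set_ylabel("prey residue")
    fig.colorbar(im, ax=ax, label="contact frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
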