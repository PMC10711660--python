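"""Shared fixtures: bundled sequences, the standard scan layout and
random two-chain model builders used by the oracle-equivalence tests."""

from __future__ import annotations

import math

import biotite.structure as struc
import numpy as np
import pytest
from hypothesis import settings

from motifscan.fragment_scan import (
    BaitDomain,
    ScanConfig,
    build_manifest,
    enumerate_fragments,
)
from motifscan.sequences import Span, bundled_sequences

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TAIL_SPAN = Span(63, 101)
MOTIF_SPAN = Span(97, 101)
POCKET_SPAN = Span(742, 762)
BAIT_DOMAINS = [
    BaitDomain("AF-eTD0", Span(520, 700)),
    BaitDomain("AF-eTD1", Span(701, 880)),
    BaitDomain("AF-eTD2", Span(881, 1060)),
]


@pytest.fixture(scope="session")
def records():
    return bundled_sequences()


@pytest.fixture(scope="session")
def prey(records):
    return records["BmGtsf1L"]


@pytest.fixture(scope="session")
def bait(records):
    return records["BmVreteno"]


@pytest.fixture(scope="session")
def scan_config():
    return ScanConfig(tail_span=TAIL_SPAN, init_len=5, step=5)


@pytest.fixture(scope="session")
def fragments(scan_config):
    return enumerate_fragments(scan_config)


@pytest.fixture(scope="session")
def manifest(fragments):
    return build_manifest(fragments, BAIT_DOMAINS)


def make_atoms(rows) -> struc.AtomArray:
    """Build an AtomArray from (chain, res_id, atom_name, element, xyz)."""
    atoms = struc.AtomArray(len(rows))
    atoms.chain_id = np.array([r[0] for r in rows])
    atoms.res_id = np.array([r[1] for r in rows], dtype=int)
    atoms.res_name = np.full(len(rows), "ALA")
    atoms.atom_name = np.array([r[2] for r in rows])
    atoms.element = np.array([r[3] for r in rows])
    atoms.hetero = np.zeros(len(rows), bool)
    atoms.coord = np.array([r[4] for r in rows], dtype=np.float32)
    return atoms


def random_two_chain_atoms(
    rng: np.random.Generator,
    max_res: int = 10,
    max_atoms_per_res: int = 3,
    box: float = 12.0,
    hydrogen_prob: float = 0.2,
) -> struc.AtomArray:
    """A random pair of chains in a small box (so many near-cutoff pairs)."""
    rows = []
    for chain in ("A", "B"):
        n_res = int(rng.integers(2, max_res + 1))
        for res in range(1, n_res + 1):
            n_at = int(rng.integers(1, max_atoms_per_res + 1))
            for k in range(n_at):
                if rng.random() < hydrogen_prob:
                    name, element = f"H{k + 1}", "H"
                else:
                    name, element = f"C{k + 1}", "C"
                rows.append((chain, res, name, element, rng.uniform(0, box, 3)))
    return make_atoms(rows)


def brute_force_contacts(
    atoms: struc.AtomArray,
    cutoff: float,
    heavy_only: bool = True,
    inclusive: bool = False,
) -> set:
    """Independent O(n^2) reference: plain python loops over atom pairs,
    grouping by sequential residue position per chain."""

    def chain_atoms(chain):
        sub = [
            (int(r), tuple(float(c) for c in xyz), str(e))
            for ch, r, xyz, e in zip(atoms.chain_id, atoms.res_id, atoms.coord, atoms.element)
            if ch == chain
        ]
        positions = {}
        out = []
        for res_id, xyz, element in sub:
            if res_id not in positions:
                positions[res_id] = len(positions) + 1
            if heavy_only and element.upper() in ("H", "D"):
                continue
            out.append((positions[res_id], xyz))
        return out

    a, b = chain_atoms("A"), chain_atoms("B")
    pairs = set()
    for pa, xa in a:
        for pb, xb in b:
            d = math.dist(xa, xb)
            if (d <= cutoff) if inclusive else (d < cutoff):
                pairs.add((pa, pb))
    return pairs
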