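"""Model loading, ranking metadata and heavy-atom contact extraction."""

import json

import numpy as np
import pytest

from motifscan.errors import FormatError, RunError, ValidationError
from motifscan.fragment_scan import BaitDomain, Fragment
from motifscan.model_contacts import (
    ContactSet,
    interchain_contacts,
    load_run_metadata,
    load_structure,
    model_from_atoms,
    remap_contacts,
    select_top_model,
)
from motifscan.sequences import Span

from conftest import brute_force_contacts, make_atoms, random_two_chain_atoms


def pair_model(distance):
    """Two single-atom residues, one per chain, at the given separation."""
    rows = [
        ("A", 1, "C1", "C", (0.0, 0.0, 0.0)),
        ("B", 1, "C1", "C", (distance, 0.0, 0.0)),
    ]
    return model_from_atoms(make_atoms(rows))


def test_strict_rule_at_boundary():
    """The model rule is strictly 'less than': 4.99 Å counts, 5.00 does not."""
    assert len(interchain_contacts(pair_model(4.99), cutoff=5.0)) == 1
    assert len(interchain_contacts(pair_model(5.00), cutoff=5.0)) == 0


def test_inclusive_rule_at_boundary():
    assert len(interchain_contacts(pair_model(4.5), cutoff=4.5, inclusive=True)) == 1
    assert len(interchain_contacts(pair_model(4.6), cutoff=4.5, inclusive=True)) == 0


def test_hydrogens_excluded_by_heavy_rule():
    rows = [
        ("A", 1, "C1", "C", (0.0, 0.0, 0.0)),
        ("A", 1, "H1", "H", (5.0, 0.0, 0.0)),
        ("B", 1, "C1", "C", (8.0, 0.0, 0.0)),
    ]
    model = model_from_atoms(make_atoms(rows))
    assert len(interchain_contacts(model, cutoff=5.0, heavy_only=True)) == 0
    assert len(interchain_contacts(model, cutoff=5.0, heavy_only=False)) == 1


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("heavy_only", [True, False])
def test_contacts_match_brute_force_oracle(seed, heavy_only):
    rng = np.random.default_rng(seed)
    atoms = random_two_chain_atoms(rng)
    model = model_from_atoms(atoms)
    for cutoff, inclusive in ((5.0, False), (4.5, True)):
        got = interchain_contacts(model, cutoff, heavy_only=heavy_only, inclusive=inclusive)
        want = brute_force_contacts(atoms, cutoff, heavy_only=heavy_only, inclusive=inclusive)
        assert got.pairs == want


def test_contacts_match_brute_force_on_large_model():
    rng = np.random.default_rng(1234)
    atoms = random_two_chain_atoms(rng, max_res=60, max_atoms_per_res=8, box=40.0)
    assert atoms.array_length() > 300
    model = model_from_atoms(atoms)
    got = interchain_contacts(model, 5.0)
    assert got.pairs == brute_force_contacts(atoms, 5.0)


def test_contact_monotonicity_in_cutoff():
    rng = np.random.default_rng(7)
    model = model_from_atoms(random_two_chain_atoms(rng))
    previous = frozenset()
    for cutoff in (2.0, 4.0, 6.0, 9.0):
        current = interchain_contacts(model, cutoff).pairs
        assert previous <= current
        previous = current


def test_rigid_motion_leaves_contacts_unchanged():
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(11)
    atoms = random_two_chain_atoms(rng)
    before = interchain_contacts(model_from_atoms(atoms), 5.0).pairs
    rot = Rotation.from_rotvec([0.4, 1.1, -0.6]).as_matrix().astype(np.float32)
    moved = atoms.copy()
    moved.coord = atoms.coord @ rot.T + np.float32([10.0, -3.0, 7.0])
    after = interchain_contacts(model_from_atoms(moved), 5.0).pairs
    assert before == after


def test_load_structure_keeps_two_chains(tmp_path):
    rows = (
        [("A", r, "C1", "C", (r * 3.0, 0, 0)) for r in (1, 2, 3)]
        + [("B", r, "C1", "C", (r * 3.0, 4, 0)) for r in (1, 2)]
        + [("C", 1, "C1", "C", (0, 0, 9))]
    )
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(make_atoms(rows))
    path = tmp_path / "m.pdb"
    pdb.write(str(path))
    model = load_structure(path, "A", "B")
    assert model.bait.n_residues == 3
    assert model.prey.n_residues == 2
    with pytest.raises(FormatError):
        load_structure(path, "A", "Z")


def _write_run_dir(tmp_path, ranking, confidence=0.87, dialect="native", pae=None):
    from motifscan.synthetic import ToyComplexSpec, write_toy_complex

    for k, name in enumerate(ranking):
        spec = ToyComplexSpec(3, 2, planted_pairs=((1, 1),) if k == 0 else ())
        write_toy_complex(spec, tmp_path / f"{name}.pdb")
    if dialect == "native":
        meta = {"ranking": ranking, "confidence": confidence, "pae": pae}
        (tmp_path / "metadata.json").write_text(json.dumps(meta))
    else:
        meta = {"order": ranking, "iptm+ptm": {n: confidence for n in ranking}}
        (tmp_path / "ranking_debug.json").write_text(json.dumps(meta))
    return tmp_path


def test_select_top_model_follows_ranking_not_filename(tmp_path):
    """A permuted ranking must win over lexicographic file order."""
    run = _write_run_dir(tmp_path, ["model_3", "model_0", "model_1"])
    assert select_top_model(run).name == "model_3.pdb"


def test_select_top_model_single_model(tmp_path):
    run = _write_run_dir(tmp_path, ["model_0"])
    assert select_top_model(run).name == "model_0.pdb"


def test_select_top_model_missing_metadata(tmp_path):
    with pytest.raises(RunError):
        select_top_model(tmp_path)


def test_metadata_confidence_passthrough(tmp_path):
    run = _write_run_dir(tmp_path, ["model_0"], confidence=0.87)
    meta = load_run_metadata(run)
    assert meta.confidence == 0.87
    assert meta.pae is None


def test_metadata_ranking_debug_dialect(tmp_path):
    run = _write_run_dir(tmp_path, ["model_2", "model_0"], confidence=0.64, dialect="legacy")
    meta = load_run_metadata(run)
    assert meta.ranking[0] == "model_2"
    assert meta.confidence == 0.64


def test_metadata_rejects_out_of_range_confidence(tmp_path):
    run = _write_run_dir(tmp_path, ["model_0"], confidence=1.3)
    with pytest.raises(ValidationError):
        load_run_metadata(run)


def test_metadata_pae_roundtrip(tmp_path):
    pae = [[0.0, 2.5], [2.5, 0.0]]
    run = _write_run_dir(tmp_path, ["model_0"], pae=pae)
    meta = load_run_metadata(run)
    assert np.allclose(meta.pae, pae)


def test_remap_contacts_arithmetic():
    frag = Fragment("end", 5, Span(33, 39), Span(95, 101))
    bait = BaitDomain("AF-eTD1", Span(700, 880))
    local = ContactSet(pairs=frozenset({(43, 5)}), frame="fragment_local")
    remapped = remap_contacts(local, frag, bait)
    assert remapped.frame == "global"
    assert remapped.pairs == {(742, 99)}


def test_remap_rejects_out_of_range_indices():
    frag = Fragment("start", 5, Span(1, 5), Span(63, 67))
    bait = BaitDomain("d", Span(1, 10))
    with pytest.raises(ValidationError):
        remap_contacts(ContactSet(frozenset({(1, 6)})), frag, bait)
    with pytest.raises(ValidationError):
        remap_contacts(ContactSet(frozenset({(11, 1)})), frag, bait)
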