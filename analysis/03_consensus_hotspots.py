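#!/usr/bin/env python
"""Extract contacts from every run's top-ranked model and build the
cross-run consensus.

For each of the 72 runs the first-ranked model is read, inter-chain
residue contacts are extracted under the 5 Å heavy-atom rule, remapped to
global residue numbering, and aggregated into one contact-frequency
matrix per bait domain (hits / covering runs). Hotspots are maximal
8-connected regions with frequency >= 0.5 covering >= 3 cells.

Writes results/consensus_AF-eTD1_observed.tsv (dense observed submatrix),
results/consensus_summary.tsv, results/hotspots.tsv and a heatmap under
scratch/plots/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from motifscan.consensus import (
    accumulate_runs,
    consensus_to_dense_frame,
    detect_hotspots,
    hotspots_to_frame,
    observed_submatrix,
    plot_heatmap,
)
from motifscan.fragment_scan import read_manifest
from motifscan.model_contacts import (
    interchain_contacts,
    load_structure,
    load_run_metadata,
    remap_contacts,
    select_top_model,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--runs-root", type=Path, default=ROOT / "scratch" / "mock_scan")
    parser.add_argument("--cutoff", type=float, default=5.0)
    args = parser.parse_args()

    manifest_path = RESULTS / "manifest.tsv"
    if not manifest_path.exists() or not args.runs_root.exists():
        raise SystemExit("run analysis/01 and analysis/02 first")
    manifest = read_manifest(manifest_path, tail_start=63)

    runs, confidences = [], []
    for entry in manifest:
        run_dir = args.runs_root / entry.run_id
        model = load_structure(select_top_model(run_dir))
        local = interchain_contacts(model, cutoff=args.cutoff)
        runs.append((entry, remap_contacts(local, entry.fragment, entry.bait)))
        confidences.append(load_run_metadata(run_dir, entry.run_id).confidence)
    print(f"extracted contacts from {len(runs)} top-ranked models "
          f"(cutoff {args.cutoff} Å, heavy atoms, strict <)")

    matrices = accumulate_runs(runs)
    summary_rows, hotspot_frames = [], []
    for name, matrix in sorted(matrices.items()):
        obs = observed_submatrix(matrix)
        hotspots = detect_hotspots(matrix)
        hotspot_frames.append(hotspots_to_frame(hotspots))
        summary_rows.append({
            "bait_domain": name,
            "n_runs": matrix.n_runs,
            "observed_pairs": int((obs.hits > 0).sum()),
            "max_freq": float(np.nan_to_num(matrix.freq).max()),
            "n_hotspots": len(hotspots),
        })
        print(f"{name}: {summary_rows[-1]['observed_pairs']} observed pairs, "
              f"max frequency {summary_rows[-1]['max_freq']:.2f}, "
              f"{len(hotspots)} hotspot(s)")
        if hotspots:
            top = hotspots[0]
            print(f"  top hotspot: bait residues {top.bait_residues[0]}-"
                  f"{top.bait_residues[-1]}, prey residues {top.prey_residues[0]}-"
                  f"{top.prey_residues[-1]}, peak {top.peak_freq:.2f}")

    pd.DataFrame(summary_rows).to_csv(RESULTS / "consensus_summary.tsv", sep="\t", index=False)
    non_empty = [f for f in hotspot_frames if not f.empty]
    (pd.concat(non_empty, ignore_index=True) if non_empty else hotspot_frames[0]).to_csv(
        RESULTS / "hotspots.tsv", sep="\t", index=False
    )
    dense = consensus_to_dense_frame(observed_submatrix(matrices["AF-eTD1"]))
    dense.round(3).to_csv(RESULTS / "consensus_AF-eTD1_observed.tsv", sep="\t")

    plots = ROOT / "scratch" / "plots"
    plots.mkdir(parents=True, exist_ok=True)
    for name, matrix in matrices.items():
        plot_heatmap(matrix, plots / f"consensus_{name}.png")
    print(f"mean confidence, motif-covering runs vs rest: "
          f"{np.mean([c for c in confidences if c > 0.5]):.2f} vs "
          f"{np.mean([c for c in confidences if c <= 0.5]):.2f}")
    print(f"tables -> {RESULTS}, heatmaps -> {plots}")


if __name__ == "__main__":
    main()
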