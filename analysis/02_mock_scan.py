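#!/usr/bin/env python
"""Generate the synthetic 72-run prediction scan with a planted interface.

Stands in for the structure-prediction engine: every run directory gets
five ranked models plus ranking metadata. Runs whose fragment covers the
tail motif (residues 97-101) and whose bait domain contains the pocket
(residues 742-762) carry planted motif-pocket contacts in their top-ranked
model; all runs receive independent per-pair contact noise (p = 0.05) and
confidences mirroring the confident-motif vs background contrast.

Run directories are bulky scratch data: they go under scratch/mock_scan.
"""

import argparse
from pathlib import Path

from motifscan.fragment_scan import read_manifest
from motifscan.sequences import Span
from motifscan.synthetic import make_mock_scan

ROOT = Path(__file__).resolve().parent.parent
MOTIF = Span(97, 101)
POCKET = Span(742, 762)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise-rate", type=float, default=0.05)
    args = parser.parse_args()

    manifest_path = ROOT / "results" / "manifest.tsv"
    if not manifest_path.exists():
        raise SystemExit("run analysis/01_fragment_design.py first")
    manifest = read_manifest(manifest_path, tail_start=63)
    out = ROOT / "scratch" / "mock_scan"
    dirs = make_mock_scan(manifest, MOTIF, POCKET, out,
                          noise_rate=args.noise_rate, seed=args.seed)
    print(f"wrote {len(dirs)} mock prediction-run directories under {out}")
    print(f"planted interface: pocket {POCKET.start}-{POCKET.end} x "
          f"motif {MOTIF.start}-{MOTIF.end}, noise rate {args.noise_rate}, "
          f"seed {args.seed}")


if __name__ == "__main__":
    main()
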