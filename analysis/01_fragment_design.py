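#!/usr/bin/env python
"""Design the fragment scan of the prey tail and build the run manifest.

The disordered C-terminal tail of the 101-residue prey (BmGtsf1L) spans
residues 63-101 (39 aa). Tiling it with fragments of growing length
(5, 10, ..., clipped full tail) from three anchors gives 24 fragments;
pairing each with the three bait eTudor domains gives the 72-run manifest.

Writes results/fragments.tsv and results/manifest.tsv.
"""

from pathlib import Path

from motifscan.fragment_scan import (
    BaitDomain,
    ScanConfig,
    build_manifest,
    enumerate_fragments,
    write_manifest,
)
from motifscan.sequences import Span, bundled_sequences, locate_unique_residue, subsequence

RESULTS = Path(__file__).resolve().parent.parent / "results"

BAIT_DOMAINS = [
    BaitDomain("AF-eTD0", Span(520, 700)),
    BaitDomain("AF-eTD1", Span(701, 880)),
    BaitDomain("AF-eTD2", Span(881, 1060)),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    prey = bundled_sequences()["BmGtsf1L"]
    tail = Span(len(prey) - 39 + 1, len(prey))
    print(f"prey {prey.id}: {len(prey)} aa, tail {tail.start}-{tail.end} "
          f"({tail.length} aa): {subsequence(prey, tail).residues}")
    w = locate_unique_residue(prey, tail, "W")
    print(f"unique tail tryptophan at residue {w} "
          f"(flanks: {prey.residue_at(w - 1)}{w - 1}, {prey.residue_at(w + 1)}{w + 1})")

    config = ScanConfig(tail_span=tail, init_len=5, step=5)
    fragments = enumerate_fragments(config)
    print(f"{len(fragments)} fragments "
          f"({len(fragments) // 3} nominal lengths x 3 anchors)")
    with open(RESULTS / "fragments.tsv", "w") as fh:
        fh.write("fragment_id\tanchor\tnominal_len\tfrag_start\tfrag_end\n")
        for f in fragments:
            fh.write(f"{f.fragment_id}\t{f.anchor}\t{f.nominal_len}"
                     f"\t{f.global_span.start}\t{f.global_span.end}\n")

    manifest = build_manifest(fragments, BAIT_DOMAINS)
    write_manifest(manifest, RESULTS / "manifest.tsv")
    print(f"{len(manifest)} prediction runs "
          f"({len(fragments)} fragments x {len(BAIT_DOMAINS)} bait domains) "
          f"-> {RESULTS / 'manifest.tsv'}")


if __name__ == "__main__":
    main()
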