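"""Tiling of a disordered tail into anchored fragments and the run manifest.

The scan starts with a short fragment (default five residues) anchored at
the start, middle and end of the tail and grows it by a fixed step until
the fragment first reaches the tail length, at which point it is clipped
to the full tail and the series stops. Every fragment is paired with every
bait domain; each pairing is one interface-prediction run. Fragments whose
spans coincide across anchors are deliberately kept as separate runs:
prediction is stochastic, so replicates carry information, and this is the
convention under which 8 lengths x 3 anchors x 3 domains gives 72 runs for
a 39-residue tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError
from .sequences import Span

ANCHORS = ("start", "middle", "end")


@dataclass(frozen=True)
class ScanConfig:
    """Fragment-scan parameters.

    ``tail_span`` is the global span of the disordered tail on the prey
    sequence; ``init_len`` and ``step`` are the initial fragment length and
    the growth increment (both default 5); ``anchors`` is an ordered subset
    of ``{"start", "middle", "end"}``.
    """

    tail_span: Span
    init_len: int = 5
    step: int = 5
    anchors: tuple[str, ...] = ANCHORS

    def __post_init__(self) -> None:
        if self.init_len < 1 or self.step < 1:
            raise ConfigError("init_len and step must be >= 1")
        if not self.anchors:
            raise ConfigError("at least one anchor is required")
        unknown = set(self.anchors) - set(ANCHORS)
        if unknown:
            raise ConfigError(f"unknown anchors: {sorted(unknown)}")
        if len(set(self.anchors)) != len(self.anchors):
            raise ConfigError("anchors must be unique")
        if self.init_len > self.tail_span.length:
            raise ConfigError(
                f"init_len {self.init_len} exceeds tail length {self.tail_span.length}"
            )


@dataclass(frozen=True)
class Fragment:
    """One tiled tail peptide.

    ``nominal_len`` is the length the growth series asked for; the actual
    span may be shorter only when the final fragment is clipped at the tail
    boundary. ``tail_local_span`` is in tail coordinates (1 = first tail
    residue); ``global_span`` is on the prey sequence.
    """

    anchor: str
    nominal_len: int
    tail_local_span: Span
    global_span: Span

    @property
    def fragment_id(self) -> str:
        return f"{self.anchor}:{self.nominal_len}"

    @property
    def length(self) -> int:
        return self.global_span.length


@dataclass(frozen=True)
class BaitDomain:
    """A named residue span on the bait sequence."""

    name: str
    span: Span


@dataclass(frozen=True)
class RunEntry:
    """One prediction run: a fragment paired with a bait domain."""

    run_id: str
    bait: BaitDomain
    fragment: Fragment


def _local_span(anchor: str, length: int, tail_len: int) -> Span:
    """Span of an ``anchor``-anchored fragment of ``length`` in tail coords.

    Middle-anchored fragments are centred on ceil(L/2) with left bias and
    shifted minimally to fit inside the tail — never shortened, so that all
    same-length fragments stay comparable.
    """
    if anchor == "start":
        return Span(1, length)
    if anchor == "end":
        return Span(tail_len - length + 1, tail_len)
    centre = math.ceil(tail_len / 2)
    start = centre - length // 2
    start = min(max(start, 1), tail_len - length + 1)
    return Span(start, start + length - 1)


def enumerate_fragments(config: ScanConfig) -> list[Fragment]:
    """All fragments of the scan, ordered by anchor then increasing length.

    Per anchor the nominal lengths are ``init_len, init_len + step, ...``;
    the first length to reach or exceed the tail length yields the full
    (clipped) tail and ends the series.
    """
    tail_len = config.tail_span.length
    fragments: list[Fragment] = []
    for anchor in config.anchors:
        nominal = config.init_len
        while True:
            clipped = nominal >= tail_len
            local = Span(1, tail_len) if clipped else _local_span(anchor, nominal, tail_len)
            fragments.append(
                Fragment(
                    anchor=anchor,
                    nominal_len=nominal,
                    tail_local_span=local,
                    global_span=local.shift(config.tail_span.start - 1),
                )
            )
            if clipped:
                break
            nominal += config.step
    return fragments


def build_manifest(
    fragments: Sequence[Fragment], bait_domains: Sequence[BaitDomain]
) -> list[RunEntry]:
    """Cartesian product of fragments and bait domains, in deterministic
    order (bait-domain order, then fragment order); run ids encode both."""
    if not fragments or not bait_domains:
        raise ConfigError("need at least one fragment and one bait domain")
    names = [b.name for b in bait_domains]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate bait-domain names in {names}")
    entries = []
    for bait in bait_domains:
        for frag in fragments:
            run_id = f"{bait.name}__{frag.anchor}_{frag.nominal_len:03d}"
            entries.append(RunEntry(run_id=run_id, bait=bait, fragment=frag))
    return entries


def manifest_to_frame(entries: Iterable[RunEntry]) -> pd.DataFrame:
    rows = [
        {
            "run_id": e.run_id,
            "bait_name": e.bait.name,
            "bait_start": e.bait.span.start,
            "bait_end": e.bait.span.end,
            "anchor": e.fragment.anchor,
            "nominal_len": e.fragment.nominal_len,
            "frag_start": e.fragment.global_span.start,
            "frag_end": e.fragment.global_span.end,
        }
        for e in entries
    ]
    return pd.DataFrame(rows)


def write_manifest(entries: Iterable[RunEntry], path: str | Path) -> None:
    manifest_to_frame(entries).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, tail_start: int) -> list[RunEntry]:
    """Rebuild run entries from a manifest TSV.

    ``tail_start`` (global index of the first tail residue) is needed to
    recover tail-local fragment coordinates.
    """
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        global_span = Span(int(row.frag_start), int(row.frag_end))
        entries.append(
            RunEntry(
                run_id=str(row.run_id),
                bait=BaitDomain(str(row.bait_name), Span(int(row.bait_start), int(row.bait_end))),
                fragment=Fragment(
                    anchor=str(row.anchor),
                    nominal_len=int(row.nominal_len),
                    tail_local_span=global_span.shift(1 - tail_start),
                    global_span=global_span,
                ),
            )
        )
    return entries
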