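# Methods notes

## Fragment tiling

The tail span is 1-based inclusive; for the packaged 101-residue prey the
tail defaults to (63, 101) so that its length is the stated 39 residues.
(The zinc-finger region of the same protein is elsewhere delimited at
residue 64; the two conventions overlap by two residues and cannot both be
exact. Tail start is config-exposed for that reason, with 63 as the
default because it preserves the 39-residue tail length.)

Per anchor, nominal fragment lengths grow as `init_len, init_len + step,
…`; the first length to reach or exceed the tail length is clipped to the
full tail and ends the series. For a 39-residue tail with `init_len = 5`
and `step = 5` this yields nominal lengths 5–40 (the 40 clipped to 39),
i.e. 8 fragments per anchor and 24 in total. Three design choices matter:

- **Middle anchoring.** No centring convention is fixed by the source
  analysis, so the package centres on `ceil(L/2)` with left bias
  (`start = c − floor(len/2)`) and shifts the span minimally to fit the
  tail rather than shortening it, keeping all same-length fragments the
  same length and hence comparable. This is a reconstruction and is
  flagged as such.
- **Coinciding spans are kept.** The full-tail fragment appears once per
  anchor; these duplicates are retained as separate runs. Interface
  prediction is stochastic, so replicate runs are informative — and this
  is the only convention under which 8 lengths × 3 anchors × 3 domains
  reproduces a 72-run manifest.
- **The series stops at the first clipped fragment**; no lengths beyond
  the tail are generated.

## Contact rules

Predicted models use the strict rule: residues are in contact when some
heavy-atom pair is at distance `< 5.0 Å` (ties at exactly the cutoff are
excluded). MD frames use the inclusive rule `≤ 4.5 Å`. "Heavy" means
element ∉ {H, D}, with elements read from the PDB element column and
inferred from atom names when absent. Whether the 4.5 Å MD rule should
count hydrogens is not specified by the source analysis; the default here
is heavy atoms only, for consistency with the model rule, and
`include_h=True` restores all-atom distances. Distances are computed in
double precision over all atom pairs with no spatial index — the
computation is the contribution, so it stays trivially auditable against
the brute-force oracle used in the tests. Only the highest-occupancy
altloc of each atom is kept on reading.

## Consensus frequency

One matrix per bait domain (no cross-domain pooling). `hits[i, j]` counts
runs with the pair in contact; the denominator counts the runs whose
fragment covers prey residue j — every run contains its full bait domain,
so pair coverage reduces to prey coverage. This covering-run reading
normalises short fragments correctly; a flag switches to an all-runs
denominator for sensitivity analysis. Pairs with zero denominator carry no
frequency (NaN, excluded from outputs). The heatmap restriction to
residues observed in contact at least once (`observed_submatrix`) mirrors
the published display convention; the long-format TSV is canonical.

The hotspot rule — frequency ≥ 0.5, 8-connectivity, minimum component
size 3 — operationalises the qualitative notion of a "clear hotspot"; all
three knobs are exposed. Components are ranked by peak, then mean
frequency.

## MD analyses

Replicate contact maps are averaged elementwise (plain mean over
replicates; within a trajectory the frequency is the fraction of frames).
Marginal profiles are row/column sums of the pair-frequency matrix — sums
of probabilities, so values above 1 are expected for residues with several
partners.

The hydrogen-bond criterion (donor–acceptor ≤ 3.5 Å, D–H–A angle ≥ 150°,
distance-only when no hydrogen is present) is a standard geometric
definition adopted here as a reconstruction: the original quantification
follows a published criterion whose exact thresholds are not restated in
the package's sources, so both knobs are config-exposed.

Anchoring: a replicate is anchored when the motif residue's side-chain
heavy atoms (non-backbone; glycine is rejected) come within 4.5 Å (the MD
contact rule, reused deliberately) of any pocket heavy atom in at least
50% of frames. Both numbers are parameters; the qualitative published
observation ("nine of ten replicates anchored") fixes neither.

## Superposition

Kabsch via SVD of the coordinate cross-covariance, with the determinant
correction so reflections are never returned; RMSD is computed after the
transform. Sequence-independent alignment search (CE-style) is out of
scope — residue correspondences are supplied by the caller, defaulting to
alpha-carbons for range-based selections. The zinc-finger reference
ranges (predicted Gtsf fingers 8–34/35–64 onto 6X46 chain A 14–41/48–75)
ship as a preset; note these ranges differ in length (57 vs 56 CA) because
the original superposition used a sequence-aligning tool, so an exact 1:1
correspondence must be chosen by the user.

## Synthetic data: what it emulates, and what it does not

Generators build pseudo-atom residues (1–4 atoms, no physical geometry):
bait residues on a widely spaced line, prey residues offset on a parallel
grid, and one dedicated bait pseudo-atom per planted pair placed exactly
at the contact distance (4.0 Å by default) from the prey residue's base
atom; all other inter-chain pairs stay ≥ 8.0 Å apart. Every construction
is verified after the fact by a direct distance scan (tolerance 2×10⁻³ Å,
the float32/PDB coordinate precision); infeasible requests raise instead
of degrading. Because every downstream statistic depends only on
interatomic distances, this suffices to exercise the full pipeline — but
fixtures carry no stereochemistry, no side-chain packing and no predictor
confidence calibration, so passing tests demonstrate the correctness of
the bookkeeping and statistics, not predictive accuracy on real proteins.

The mock scan plants pocket contacts in a run only when the run's bait
domain contains the pocket *and* its fragment covers the motif residue
(contacts are planted per covered motif residue, so partially covering
fragments contribute partial columns); spurious contacts flip on
independently per off-pair per run with probability p (default 0.05) —
the simplest Bernoulli null against which the covering-run denominator is
testable. Lower-ranked decoy models contain no inter-chain contacts, so
any failure to honour the ranking is detectable. Confidences are drawn
from U(0.75, 0.90) for motif-covering runs and U(0.20, 0.40) otherwise,
emulating the confident-motif vs background contrast without asserting
any particular published score.

Trajectories repeat the complex geometry with seeded Gaussian jitter; the
leading `round(bound_fraction · n_frames)` frames are bound and the rest
translate the prey chain far from the bait (`unbinding_frame` overrides
the fraction). With jitter σ → 0 the in-pocket frame fraction equals the
planted bound fraction exactly.

## Study conditions and problem sizes

The worked configuration uses the packaged 101-residue prey and
1063-residue bait. The bait eTudor spans (eTD0 520–700, eTD1 701–880,
eTD2 881–1060) are illustrative package choices of realistic eTudor size
(~180 aa) positioned so that the pocket residues 742–762 fall inside
eTD1; no numeric domain boundaries are asserted by the package's sources.
The planted interface is pocket (742–762) × motif (97–101). Replicate
trajectory analyses use 10 replicates of 200 frames over a 180-residue
bait chain with a 10-residue peptide (92–101), nine bound and one
unbound; test-suite variants use smaller chains and frame counts, chosen
as the smallest sizes at which every statistic is still exercised across
its full range.

## Numerical conventions

- All residue coordinates are 1-based inclusive; 0-based storage is
  hidden behind the span type.
- Ties: strict `<` for model contacts, inclusive `≤` for MD contacts,
  `≥` for hotspot threshold and anchoring fraction.
- Degenerate inputs: empty spans, inverted spans, collinear point sets,
  glycine anchoring queries and out-of-range confidences all raise typed
  errors rather than returning sentinel values.
- Determinism: all generators are pure functions of (spec, seed); the
  pipeline sorts every iteration and rewrites byte-identical outputs on
  rerun, with a provenance header (package version, config digest, seed)
  on each table.

## Known limitations

- PAE matrices are consumed only from the package's JSON metadata
  dialect; the native pickle emitted by prediction engines is not read.
- Model confidence is read as-is and never recomputed; its precise
  definition for multimer predictions is owned by the prediction engine.
- Trajectory input is multi-model PDB; binary MD formats would need an
  adapter.
- Hotspot detection assigns no statistical significance, matching the
  descriptive use of the consensus map.
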