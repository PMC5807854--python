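# Methods

This note documents the models, conventions, and numerical choices behind
`cleavemap`, and what the synthetic world does and does not establish.

## Coordinates and data model

All internal coordinates are 1-based inclusive; BED (0-based half-open) is
converted only at I/O boundaries. Per-bp profiles are numpy vectors per
chromosome (index i ↔ bp i+1). The midpoint of an even-length fragment is
the floor of the arithmetic mean — a deterministic, strand-agnostic rule;
nothing downstream depends on the half-bp choice. Duplicate fragments are
kept: the chemistry legitimately produces identical fragments from
identical nucleosomes in different cells, so deduplication would bias
counts. Records on unknown chromosomes are dropped with a logged count
rather than raising, to tolerate partial genomes.

## Cleavage geometry

The generator parameterizes the chemistry by the released core length
(`core = 51` bp) and the bp destroyed per cut (`gap = 4`), not by absolute
strand offsets. A nucleosome with dyad d owns two cleavage sites; a cut at
the left site ends the upstream piece at d − (c + gap + 1) and starts the
downstream piece at d − c, with c = (core − 1)/2 = 25; the right site is
the mirror image. Consequences, all exercised by tests:

- both sites cut → a core fragment of exactly 51 bp centered on d;
- dyad-proximal cuts of two neighbors spaced NRL apart → a "medium"
  fragment of NRL − core − 2·gap = NRL − 59 bp;
- one intervening site skipped → a "long" fragment of NRL − gap bp, which
  is why NRL = long-fragment length + gap.

Fragments are the maximal uncut intervals between consecutive *realized*
cuts; chromosome-terminal pieces are bounded by a free end, not a cut, and
are not emitted (they would be megabase-scale and unsequenceable anyway).
Background fragments (free-phenanthroline cutting, library junk) are
uniform random intervals with lengths resampled from the real fragments —
the simplest model consistent with "noise with the same length spectrum".

## The synthetic world

Defaults state the experimental conditions: 147-bp cores (odd, so the dyad
is one bp), linkers drawn from {5, 15, 25} bp with equal weights (the
10n+5 ladder), per-site cut probability 0.8, 4-bp gaps, 5% background,
40 cells over 150 genes (~113k fragments — enough for all end-correlation
and histogram analyses to resolve single-bp structure). NDR widths are
drawn uniformly from 80–160 bp, the typical promoter-NDR scale in yeast,
once per gene (not per cell) so the NDR center and flanking dyads are
well-defined ground truth; cell-to-cell variability enters through the
linkers. The +1 dyad sits 60 bp downstream of the TSS, the common
arrangement where the TSS lies just inside the +1 nucleosome.

Each gene tiles nucleosomes outward from its +1 dyad within a "territory"
bounded by midpoints to neighboring promoters. Where two genes' arrays
meet, the junction spacing is an arbitrary value ≥ 147 bp — deliberately
so: real arrays lose phase mid-gene, and these junction fragments create
the low, wiggly histogram floor the mode-caller must reject. What a green
test does **not** establish: robustness to sequence-dependent affinities,
MNase-style biases, remodeler/transcription dynamics, or core-length
jitter (the real chemistry spreads cores over 44–58 bp; the generator's
cores are exact, and the 44–58 selection window is carried anyway).

A note on the NRL ladder: with a 147-bp core and linkers {5,15,25}, the
repeat lengths are {152,162,172} and the long-fragment modes {148,158,168}.
The equivalent bookkeeping with a 146-bp core prints {151,161,171} — the
1-bp ambiguity is inherent to the core-length convention, not to the data.

## NDR detection and flank refinement

NDRs: within a transcription-oriented window (TSS−500..TSS+150), the
widest maximal run of footprint occupancy below 0.4× the chromosome mean,
at least 50 bp long. All parameters are exposed; the defaults recover the
generator's ground truth and behave sensibly on oscillatory occupancy.
Because the published upstream procedure is not restated anywhere, this
threshold-run definition is our own.

Provisional flanking dyads are the argmax of dyad counts within 147 bp
beyond each run edge. An occupancy-local-maximum rule was tried first and
rejected: the 101-bp footprint of a well-positioned nucleosome is a
flat-top plateau whose first local maximum sits at the plateau *edge*,
~50 bp from the dyad — outside the ±25-bp refinement window. The dyad
profile localizes the flank directly; the occupancy walk remains as a
fallback when no dyad profile is supplied.

Refinement scans ±25 bp around the provisional dyad, scoring each
candidate c by Σ_x dyads(c+x)·D0(x) over x ∈ [−35, 35]; D0 is the
symmetric Gaussian comb at 0, ±10, ±20, ±30 bp with weights 1/0.75/0.5/0.25
and σ = 2 bp. The cross-correlation is a plain lag-scan of that inner
product (no local-variance normalization), and "dyad counts" means pooled
counts over cells, not a running cumulative sum. Ties break toward the
smallest |shift|, then the lower coordinate. Two NDR "width" fields are
reported, since the published convention is ambiguous: the low-occupancy
run length, and the distance between half-maximum crossings adjacent to
the flanks.

## Gap, NRL spectrum, and spacing scores

End-count vectors are strand-agnostic interval termini (left = lower
coordinate). The gap cross-correlation scans lags 1..20 between
short-class (44–58) right ends and the partner-class left ends; the
partner defaults to the medium class (70–130) — the source text gives the
medium window inconsistently (70–130 for classification, 130–170 in the
cross-correlation passage), so the partner window is a parameter. Gap =
lag − 1: two fragments abutting with no loss have ends 1 bp apart.

The NRL spectrum smooths the long-class (135–175) histogram with a
centered 3-bp moving average, calls peaks with topographic prominence
≥ 5% of the curve maximum (rejecting the junction-fragment floor), and
snaps each peak to the raw-count argmax within the smoothing window
(removing the ±1-bp bias smoothing introduces on sharp modes). Modal
NRLs are modes + gap; linkers are NRL − 147.

Per-gene scores assign long fragments to the gene body containing their
midpoint (full-overlap assignment would discard boundary fragments
asymmetrically) and report the mean long-fragment length — a direct
readout of that gene's average spacing. The genome-scale inclusion
threshold is 5000 fragments per gene; synthetic runs scale it down (60 at
default depth) since the criterion is a depth cutoff, not a biological
constant. Quintiles split the ranked genes with remainders to the earlier
groups; window averages use the gene-body (D−73, D+750) and promoter
(D−500, D−73) windows relative to the +1 dyad D.

## Hard-rod model

Energies are in kT (β = 1) throughout. Rods of a = 147 bp with hard-core
exclusion; only u − μ is identifiable from shapes, so the model is
parameterized by u − μ plus the barrier (H, σ, x₀). The barrier anchors at
the called −1/+1 dyads in genomic orientation (it is mirror-symmetric):
centers c_l = p_l + x₀ and c_r = p_r − x₀, flat top of height H between
them, half-Gaussian shoulders outside; overlapping promoters combine by
pointwise maximum; crossed centers (very narrow NDR) degrade to the
pointwise max of the two shoulders, flagged. Shoulder terms are evaluated
only within 8σ of the centers — beyond that they are < H·e⁻³² — keeping
genome-scale landscapes cheap to rebuild inside the fit loop.

The partition function uses forward/backward prefix recursions carried in
the log domain (numba-compiled, with a manual log-sum-exp), stable for
lattices up to 10⁷ bp; a brute-force enumeration oracle (L ≤ 30) pins the
recursion to 10⁻¹⁰ relative accuracy on random instances. Occupancy is
the exact ±73-bp sum over dyad probabilities, clipped to [0, 1] only
against rounding.

Fitting maximizes the Pearson correlation between +1-aligned heatmaps
(rows = training-chromosome genes, window −500..+1000 bp) of observed and
predicted dyad density. The optimizer is differential evolution (seeded,
bounded budget; bounds H ∈ [0.5, 15] kT, σ ∈ [5, 60] bp, x₀ ∈ [10, 120] bp,
u − μ ∈ [−6, 0] kT) followed by a Nelder–Mead refinement. The refinement
is essential, not cosmetic: once H exceeds a few kT the barrier is
effectively a hard wall and (H, σ, x₀) trade off along a narrow curved
valley; population search alone stalls partway down the valley, while the
simplex follows it to the optimum (the recovery control then returns the
generating parameters to < 0.1%). Any global method passing the recovery
control is conformant — the original fit used a genetic algorithm with
unstated hyperparameters.

## Known limitations

- The NDR caller is a replacement for an unpublished procedure; parameters
  were chosen against the generator and qualitative promoter behavior, not
  against the original calls.
- The equilibrium model ignores sequence-dependent affinity by design and
  cannot represent remodeler- or transcription-driven (non-equilibrium)
  positioning; barriers exist only at called promoter NDRs, not at tRNA
  genes or replication origins.
- The 2D "relative occupancy" normalization (counts / anchors × mean
  occupancy) is one reasonable convention among several; counts are always
  accumulated first and normalized once.
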