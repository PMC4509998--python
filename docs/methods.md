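# Methods

This note records the models, conventions and numerical choices behind
`cgishores`, and what the simulation-based tests do and do not demonstrate.

## Coordinates and input model

All coordinates are 0-based half-open (BED convention); BED I/O is
bit-identical to the internal representation.  A methylome is a per-CpG
count table (chrom, pos, n_meth, n_unmeth) where `pos` is the plus-strand C
of the CpG.  Evidence from the two strands of a CpG dyad is merged onto
that position before analysis (the Bismark-style importer pools adjacent
positions): CpG methylation is symmetric, and merging halves the site count
and stabilises per-site estimates.  Percent methylation is
100·n_meth/(n_meth+n_unmeth); zero-coverage sites are dropped at read time
(`min_coverage`, default 1).

## Island detection

The scanner assigns +`cg_reward` (default 17) to each CpG dinucleotide and
−`per_base_penalty` (default 1) to every other position, and reports the
Ruzzo–Tompa *all maximal scoring subsequences* of that score sequence with
segment score ≥ `min_score` (default 17), then filters to ≥ 200 bp.  These
constants are the conventional ones for this scanner family and are fully
configurable; the package's own validation is downstream — on default
simulations ≥ 90 % of detected ≥ 200 bp islands must satisfy the classical
GC > 50 % and O/E > 0.6 criteria, which does not depend on exact parity
with any particular upstream implementation.

Properties worth knowing:

- **Tie semantics.**  Where an equal-score extension exists (e.g. two CpGs
  separated by exactly `cg_reward` penalty bases), the Ruzzo–Tompa
  decomposition keeps separate minimal segments rather than one bridged
  segment.  Empirically (100k random sequences, including tie-stressed
  compositions and small rewards) this equals a recursive best-substring
  decomposition with ties broken max-score → shortest → leftmost.  The
  production scanner uses the linear-time RT list algorithm with a
  nearest-smaller-L pointer chain; the test oracle enumerates all
  substrings.
- **N handling.**  N scores as a penalty and can never form a CpG, so
  hard-masked regions cannot seed or silently bridge islands (a masked
  stretch longer than a flanking segment's score separates it).
- **Boundary trimming.**  Segments start and end on CpGs, and a maximal
  boundary implies the nearest outside CpG is ≥ `cg_reward` bp away.  Two
  visible consequences: detected islands trim CpG-poor island edges (the
  recovery checks therefore score ≥ 80 % coverage of a truth island rather
  than exact coordinates), and the 1–500 bp slope range is structurally
  n.d. for detected islands because its 10-bp y₁ window is empty — the
  same n.d. behaviour real slope tables show.  Analyses that need offset-1
  CpGs should profile truth/annotation intervals instead of detected ones.

Gardiner–Garden statistics: GC = (#C+#G)/L; O/E = (#CpG·L)/(#C·#G), defined
as 0 when #C·#G = 0; dinucleotides counted at every position (CpGs cannot
overlap, so the count is unambiguous).

Unique/repeat classification follows the masked-vs-unmasked coordinate
comparison exactly: identical (start, end) in both → unique, anything else
→ repeat.  Repeat typing is decided on half-open interval algebra; a repeat
sharing ≥ 1 base across an island boundary is a partial overlap.  A repeat
exactly coextensive with the island counts as containing it (type 1).

## Island classification

An island's methylation level is the *unweighted mean* of per-CpG percents
over covered CpGs (a coverage-weighted pooled variant is available via
`weighted=True`); islands with fewer than `min_cpgs` (default 3) covered
CpGs are not-determined and excluded from classification, which is a value,
not an error.  Class thresholds are strict inequalities — < 20 % low,
> 80 % high — so exactly 20.0/80.0 fall in intermediate.  Single/paired
status uses edge-to-edge gaps (< 10 kb → paired).

## Shores and slopes

Offsets are 1-based distances from the island's outermost base; bin k
covers offsets ((k−1)·w, k·w] so a 2-kb shore at the 250-bp default is
exactly 8 bins per side.  Aggregation weights each island-side equally
(grand mean over islands with ≥ 1 CpG in the bin; SEM = sd/√n, defined 0 at
n = 1).  CpGs inside *any* island never contribute to a bin, slope window,
or shore difference.

Slope over a range (a, b): y₁ = mean percent over offsets [a, a+10),
y₂ over (b−10, b], slope = y₂ − y₁; n.d. when either window is empty
(minimum CpGs per window configurable, default 1).  The y₁ window anchors
at the low end and y₂ at the high end of the range — a symmetric,
deterministic placement consistent with reading the slope as the change in
% methylation across 500 bp.  For a linear ramp the estimator's expectation
is slope·(b−a−9)/500, a −0.4 % relative bias at the defaults; this is far
inside the recovery tolerances and left uncorrected.  Slopes are pooled
over all islands of a class and both sides by default (class-level,
genome-average curves); `per_island=True` gives the per-island variant.

Shore difference between two methylomes: over CpGs covered in both samples
within offsets 1–2000, the signed sum of per-CpG percent differences.  It
is deliberately not length- or coverage-normalised — the cumulative form
rewards consistent differences across many CpGs, and ranking shores by its
magnitude is the DMR candidate screen (descriptive ranking only; no
significance testing).

## Pairs and crosstalk

Pairs are adjacent islands (nearest neighbours; in a cluster an island may
join two pairs) within a half-open separation stratum, measured
edge-to-edge.  Pair classes come from the members' methylation classes,
orientation-normalised; intermediate or undetermined members put the pair
in `other`.  Intervening CpGs are binned by distance from the left island's
right boundary (100-bp default) and aggregated across pairs like shore
profiles; intervening slopes reuse the endpoint-window semantics.

## Trajectories

Future classes are a function of the designated terminal methylome only
(low → future_low, high → future_high, else excluded), so permuting earlier
time points cannot change them.  Per time point and class the pipeline
reports the aggregate profile, pooled slope table and mean island-body
methylation; islands uncovered at an intermediate time point are dropped
per-time-point and counted.  Slope fold-changes between consecutive time
points are reported only when both slopes are determined and the
denominator magnitude is ≥ 0.5 points per range — ratios of near-zero
slopes are unstable — with raw slopes always available alongside.

## Simulator

The generator is the package's definition of its study conditions.

*Genome.*  One chromosome; islands placed left to right with 12-kb default
spacing (so singles stay single at the 10-kb window), pairs at exact
separations.  The CG-free fill is sampled i.i.d. at the target composition
and scrubbed of accidental CpGs by swapping CG → GC (composition-exact;
each pass moves Gs strictly leftward, so it terminates); CpGs are then
implanted as Bernoulli events at per-region rates with minimum spacing 2,
so the emitted CpG set is exactly the implanted one.  Rates: open sea 10
CpG/kb (human-like); shores 40/kb by default — CpG density is elevated near
real islands, and this value stays below the scanner's break-even density
(1000/19 ≈ 52.6/kb) so shores never score positive and island boundaries
stay crisp; islands O/E·(GC/2)² with defaults GC 0.65, O/E 1.0 (a strong
CGI, giving a scan drift of ≈ +1/bp and clean boundaries).  Fill GC is
corrected for the implanted mass so measured island GC ≈ the target.

*Methylome.*  True probability p per CpG: island level inside islands
(`meth_level`; None = track the plateau, the future-high behaviour);
plateau in the open sea (80 % somatic-like default, 90 % sperm-like);
within 2 kb of a boundary, a shore model — linear ramp from island level to
plateau over `ramp_length` (true slope (plateau−level)·500/ramp_length per
500 bp), logistic, or flat.  Counts: n ~ Poisson(λ) with zero-coverage
sites omitted, n_meth ~ Binomial(n, p) — the standard minimal WGBS noise
model (no strand, conversion-failure or read-level structure).  Crosstalk
OFF assigns a CpG in reach of several islands the isolated value of the
*nearest* island; ON combines islands as independent protection events,
p = plateau·∏(pᵢ/plateau), so overlapping hypomethylated shores depress
intervening CpGs below either single-island value — the direction and
rough magnitude of the observed low-low pair behaviour, and strictly more
depressive than the nearest-island rule (a minimum over increasing ramps
would equal it and could not produce the effect).  Per-shore model
overrides implant differential shores between two samples.  Trajectory
series apply one plateau per time point, so future-low ramps rescale with
the genome and future-high islands track it with flat shores — the
bookmarking structure.

*Determinism.*  All streams are numpy PCG64 generators keyed by the config
seed plus a fixed stream index (and an Adler-32 of the methylome label), so
every artifact is byte-reproducible for a seed and distinct labels are
independent.

## Problem sizes and power

The recovery suites run at the sizes their tolerances need: slope recovery
uses 500 islands at Poisson(10) with shore density 60/kb so each 10-bp
endpoint window pools several hundred CpGs (sampling sd of a slope
≈ 0.7–0.9 points, comfortably inside the ±3/±2-point tolerances);
classification uses 200 islands at 50×; crosstalk 150 pairs + 150 singles
at 20×; DMR 20 implants among 500 shores at 10×; trajectories 500 islands
× 4 time points at 30×.  Detection-facing runs (Gardiner–Garden validation,
the demo) keep the default 40/kb shores instead, trading endpoint-window
occupancy for crisp island boundaries; accordingly the demo checks use
slightly wider demo-scale tolerances (±5 ramp, < 4 flat).

## What passing tests show — and don't

The simulator reproduces the *structure* the analysis assumes: graded
ramps, flat high-island shores, binomial counting noise, island crosstalk
of a chosen direction.  Real WGBS adds mappability gaps, coverage
autocorrelation, bisulfite conversion failure, strand asymmetries,
non-monotone shore shapes and biological variance between replicates —
none of which are modelled.  Passing recovery tests therefore demonstrates
that the pipeline measures what it claims on data with known truth, not
that any particular biological dataset will show these effect sizes.

## Known limitations

- No smoothing or kernel regression of profiles, and no significance
  testing of shore differences (ranking is descriptive).
- Detection does not merge islands across short gaps; whether to do so is
  genuinely open, and we chose not to.
- Island-level methylation weighting (unweighted vs pooled) subtly changes
  borderline classifications; both modes are exposed.
- Plotting is out of scope; all outputs are TSV/JSON for external plotting.
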