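# Methods

## The problem

Two eucalypt taxa can be compared structurally without assembling either
genome: a high-density genetic linkage map built in one taxon is aligned to
the other taxon's reference genome through the mapped markers' tag
sequences. Where marker order on a linkage group disagrees with the
homologous chromosome coherently and over a long stretch, a chromosomal
rearrangement (an inversion, possibly transposed within the chromosome) is
inferred. ptxmap implements that entire workflow — pseudo-testcross map
construction from dominant/SNP marker matrices, and the synteny/collinearity
analysis on top — together with a forward simulator that generates
ground-truthed data with the study's design: two outbred F1 families
(default n = 115 and n = 245) sharing one pollen parent, 11 chromosomes,
and a reference genome differing from the mapped genome by a configurable
set of rearrangements.

## Simulation model

**Meiosis.** Crossovers follow a stationary gamma-renewal process on the cM
scale with one event per 100 cM on average. The shape parameter
(`interference_shape`, default 2.5) controls crossover interference: shape 1
is the memoryless Poisson process (recombination fractions exactly at the
inverse-Haldane value of the cM separation), larger shapes suppress double
crossovers over short intervals, as plant meiosis does. The default is not
cosmetic: the cleaning rule used during map construction excludes markers
involved in more than one double crossover, and at the ~3 cM bin-marker
spacing of these maps a no-interference process would produce
n·r² ≈ 0.3–0.5 *genuine* doubles per marker at n = 360 — enough to strike
most markers and, because every removal widens the spacing, to cascade.
Real interference is what makes the rule meaningful; shape 2.5 keeps the
short-range suppression strong while avoiding the rf-overshoot artefacts of
extreme shapes. Markers are placed uniformly in bp with cM proportional to
bp (uniform recombination along the chromosome).

**Marker observation.** Each testcross marker reports the inherited
haplotype of its informative parent, with an arbitrary scoring phase per
locus (all downstream counting is therefore phase-free). Fully informative
1:1:1:1 markers split into one locus per parent; 1:2:1 and dominant 3:1
intercross markers are emitted as genotype codes but are not ordered on
maps (the mapped sets are the testcross and split loci — the design the
workflow itself argues for). Per-call missing rates vary between markers
(Beta distributed, mean `missing_rate` = 0.10, concentration 2, so ~27% of
markers exceed the 10% missing filter while most sit well below it).
Reproducibility is a marker-level property drawn once per scenario; per-call
miscall rates are tied to it — near zero for markers scoring 1.0,
concentrated in the low tier — and normalised so the *population* mean
per-call error equals `error_rate` (default 1%). This is what supplier
repeatability scores measure, and it is the only error structure under
which a fixed "more than one double crossover" removal rule is coherent at
these sample sizes.

**Rearrangements.** The default scenario plants nine events on seven of the
11 chromosomes: five in-place inversions (chromosomes 4, 8, 9, and terminal
ones on 10 and 11) and four transposed inversions (one on chromosome 2,
three on chromosome 6), with spans of 5–13 Mb. In-place inversions reflect
reference coordinates about the interval; transposed segments are excised,
inverted and reinserted at an insertion point, shifting intervening
coordinates so chromosome length is conserved. Ground truth (true order,
cM, rearranged reference coordinate, parental phases) is retained and used
only by scoring functions.

**Anchors.** Synthetic tabular alignment hits place a configurable fraction
of markers (default 0.8) at their true rearranged-reference coordinate;
`anchor_noise` (default 5%) of them are corrupted to a uniform position on
a *different* chromosome — wrong-homolog hits, the signature of a search
matching a paralogue. Same-chromosome duplicate hits are not simulated as
noise because the anchor filter collapses equal-scoring hits within 2 Mb
deterministically. A small share of hits lands on unanchored scaffolds and
is recorded but never accepted.

**What the simulator does not emulate.** Sequence-level representation
(restriction sites, tag composition), recombination-rate variation along
chromosomes (cM is linear in bp), segregation distortion (exposed as a
per-marker knob, default off), relatedness beyond a single F1 cross, and
reference mis-assembly. Passing tests therefore demonstrate that the
pipeline recovers structure under the stated noise model at the study's
sample sizes — not that any particular real dataset is error-free.

## Map construction

**Quality classes.** Dominant markers: class 1 at reproducibility 1.0, call
rate > 95%, PIC > 0.35; class 2 at > 0.9 / > 90% / > 0.25; class 3 at
> 0.9 / > 80% / > 0.15 (SNP PIC floors 0.20 / 0.15 / 0.10). PIC is the
gene-diversity form 1 − Σp², which equals 0.5 at perfect 1:1 segregation.
Markers and then individuals with > 10% missing data are removed before
mapping (markers re-checked after the individual sweep).

**Binning.** Markers are grouped into bins in which *every* pair shows at
most the repulsion threshold of recombination events, via complete-linkage
agglomerative clustering on phase-free recombinant counts (cutting one
dendrogram guarantees the all-pairs property and makes thresholds nest).
The threshold is the largest count whose implied rf (or Kosambi cM) stays
below the 3% / 3 cM bound: 3 at n = 115, 7 at n = 245, 10 at n = 360. The
bin representative is the member with the best quality class, then the
highest call rate, then the smallest id.

**Two-point analysis and grouping.** r̂ = R/N with phase-free R;
LOD = R·log₁₀r̂ + (N−R)·log₁₀(1−r̂) + N·log₁₀2. Groups are connected
components of the LOD ≥ 3 graph, with two safeguards against the sampling
tail of the folded LOD across ~10⁵ pairs: edges must sit at r̂ ≤ 0.30
(chromosome connectivity only ever needs short edges), and must have at
least one common neighbour (a genuine edge is redundantly supported by the
dense local graph). This is the algorithmic analogue of choosing stable
nodes in an interactive grouping tree.

**Ordering.** The regression ordering is Stam-style incremental insertion:
seed with the highest-LOD pair, insert markers by decreasing total LOD at
the slot minimising the LOD²-weighted least-squares lack of fit between
fitted additive distances and pairwise Kosambi estimates
(d = 25·ln((1+2r)/(1−2r)); inverse r = ½·tanh(d/50)), with positions fit by
non-negative least squares on interval lengths. Pairs at r̂ ≥ 0.40 carry no
weight — they hold no order information, and under interference the folded
rf of very distant pairs can dip below 0.5 spuriously. Small groups
(≤ 12 markers) are refined by exhaustive window-3 ripples against the full
objective; larger groups use a fast chain-position surrogate, a 2-opt
segment-reversal pass (which escapes "folded chromosome" optima), a final
ripple, and an independent restart from the minimum-recombination path,
keeping the better objective. The verification ordering minimises the sum
of adjacent recombinant counts (greedy nearest-neighbour from every start
plus delta-evaluated 2-opt). Everything is deterministic: ties break on
marker id and no step draws random numbers.

**Iterative cleaning.** Each round removes the worst violators (at most 5%
of the group, testcross before intercross) of three criteria, then
re-orders: (i) goodness-of-fit contribution > 1.0 (bin maps) or > 2.0
(combined rounds) — operationalised as the LOD²-weighted mean of squared
map-distance residuals standardised by the delta-method sampling variance
of each pairwise Kosambi estimate, so clean markers sit well below 1 and
error-carrying markers rise above it; (ii) presence in more than one double
crossover (a call differing from both nearest non-missing flanking calls,
counted after greedy phase alignment along the order); (iii) segregation
distortion at χ² p < 0.001 that departs from the median distortion of
markers within 5 cM by more than 0.10 — distortion shared with close
neighbours is biology, an isolated departure is a genotyping artefact.
After convergence, the regression and minimum-recombination orders are
compared: while any marker's position implied by its rank in one order
shifts more than 1 cM on the other's scale (a pure order statistic,
insensitive to the two estimators' different length scales), the least
supported shifting marker is removed and both maps are rebuilt.

**Combining families and reintegration.** The two crosses of the shared
parent are pooled into one population (offspring columns concatenated)
after phase alignment: on the graph of marker pairs firmly linked in both
crosses, relative scoring-phase flips are propagated from the unfolded
mismatch fractions. The combined dataset is re-binned at its own threshold
(10) and mapped with class 1–2 bin markers. Binned markers are then
reintegrated at representative ± Kosambi(R/N), on the side of the
neighbouring representative with the smaller recombinant fraction;
representative positions stay fixed.

## Comparative analysis

**Anchor filtering.** Per marker the highest bit-score hit is kept, and
accepted iff query coverage > 0.95 and e-value < 1e-10 on an anchored
chromosome; equal-score hits on one chromosome collapse deterministically
(lowest bp, then subject id). A linkage group's homologous chromosome is
the modal chromosome of its accepted anchors (ties are an error); groups
are renamed and oriented to the reference convention before flagging.

**Collinear order.** The trend is a weighted longest monotone subsequence
of reference positions along the map (best of increasing/decreasing), with
two refinements that make it behave like the dot-plot judgement it stands
in for: a link whose local slope exceeds 1.5× the group's overall Mb/cM
ratio (plus a 1 Mb slack) costs a 6-point penalty — a genuine jump past a
transposed segment's insertion point recruits the rest of the chromosome
and pays for itself, whereas weaving through the leading edge of an
inverted segment gains only a few noise points — and the trend is anchored
at virtual chromosome-boundary points (a full-coverage group runs from
~bp 0 to its anchored maximum), with terminal trend points inconsistent
with those anchors pruned. Displacement is each marker's |bp − interpolated
trend bp at its cM| and markers at ≥ 2 Mb are non-collinear.

**Calls.** Runs of consecutive non-collinear markers are read along the
anchored markers only (unanchored markers are invisible; a single
interleaved wrong-homolog marker is tolerated; a collinear marker breaks
the run). Runs split by the sub-threshold core of an inversion are merged
when both parts have ≥ 2 members, their envelopes lie within 2× the
threshold, the combination stays monotone (|ρ| ≥ 0.8) and the interposed
collinear markers fall inside the merged envelope. A run preserving both
the trend orientation and the bp order of its neighbours is a coordinate
offset (the downstream shift past an insertion point), not a rearrangement,
and is dropped. Surviving runs spanning > 5 cM become calls, named
<taxon>-in(<LG>)[tp]<k> in map order; a run is *inverted* when its internal
slope opposes the trend and *transposed* when its reference interval sits
away from the interpolated window by more than both the threshold and the
two intervals' spans (a partially anchored in-place inversion shows a gap
up to its own span, a genuinely moved segment shows far more).

**Replication.** A call is replicated when another parent's map carries a
call on the homologous chromosome whose spanning reference interval
overlaps by ≥ 50% of the *shorter* interval — the span a map recovers
scales with its local marker density, so requiring reciprocal overlap
would conflate density with absence.

## Problem sizes and determinism

The default scenario covers ~6,000 markers across all segregation types,
giving ~3,000 testcross loci for the combined shared-parent dataset at
n = 360; a full pipeline run (five map builds, three comparative analyses)
takes a few minutes on one CPU. The calibration harness screens
single-chromosome groups of 50 markers at n = 360. All randomness flows
from explicit seeds; identical config + seed reproduces byte-identical
outputs.

## Known limitations

Order recovery for markers separated by less than ~1/(2n) in rf is
statistically undecidable and such local swaps occur; the binning step is
what keeps them from mattering. The collinearity trend assumes a roughly
linear cM–bp relation (true in the simulator; real recombination deserts
would need a locally adaptive slope cap). Typing of a rearrangement with a
single anchored member is "unknown". Intercross 1:2:1 / 3:1 markers are
classified and reported but not mapped. The duplication screen requires
map-consecutive markers and so has no power below three consecutive
duplicated anchors.
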