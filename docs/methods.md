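# Methods

This note documents the models and procedures implemented in `oceanmags`, the
assumptions behind them, the parameters that matter, and what the synthetic
data generator does and does not emulate.

## Scope and data model

The package operates strictly downstream of assembly, binning, read mapping,
and annotation. Its inputs are tab-separated summaries that upstream tools
emit: genome records (length, BUSCO-style completion/redundancy, lineage),
pairwise genome similarity (ANI and the aligned fraction of the smaller
genome), genome × metagenome recruitment profiles (recruited reads, breadth of
coverage, mean vertical coverage) with metagenome metadata, gene annotation
tables (orthologous-group and remote-homology cluster ids), RNA-polymerase
marker best-hit identities, station environments, and gridded climatologies
for two periods. Computing any of these from sequence data (alignment, ANI,
HMM search, annotation, climate modelling) is out of scope by design.

All intermediates are TSV with a mandatory header; grids carry explicit
lat/lon cell centers in decimal degrees (1° default resolution). Validation is
strict by default; a permissive flag downgrades row-level type errors to
warnings and drops the rows. A run is fully described by a flat key=value
config plus one seed, and identical config + seed + inputs reproduce outputs
byte for byte.

## Dereplication

A pair is redundant iff ANI > `ani_threshold` (default 98%) **and** the
aligned fraction of the smaller genome > `align_fraction_threshold` (default
0.25); both inequalities are strict, so values exactly at the threshold are
non-redundant. Redundancy groups are the connected components of the
redundant-pair graph: the pairwise rule is closed transitively, since a "group
of redundant genomes" can extend beyond direct pairs. Because the grouping
convention is genuinely open (an iterative greedy removal is equally
defensible), a `transitive=False` mode visits pairs by decreasing ANI and
absorbs the shorter genome of each surviving pair. In both modes the
representative is the longest member, with length ties broken
lexicographically by id for determinism.

## Biogeography

Detection is per metagenome: breadth of coverage strictly above
`detection_breadth_threshold` (default 0.25), a guard against non-specific
read recruitment. Read counts from non-detections are zeroed before any
aggregate. Filtered counts are projected to complete-genome equivalents by
`reads × 100 / completion`, rounded half-up to an integer; genomes below
`completion_floor` (default 10%) keep their observed counts, because dividing
by a near-zero completion estimate would amplify its error unboundedly.

Station-level detection is the OR over a station's metagenomes. The
cosmopolitan score of a genome over a named metagenome subset is the fraction
of that subset's stations with at least one detection; the raw station count
is emitted alongside, as the two are monotone equivalents and the published
definition of the score's scale is not reproduced here. The recruited-read
fraction is reported both pooled (sum of filtered reads over sum of total
reads) and per metagenome, since either convention may be wanted.

The upstream 90% read-mapping identity criterion is carried as metadata only
(`mapping_identity_note`); it is never recomputed.

## Marker novelty

Each genome carries up to six RNA-polymerase markers (RNAP-a and RNAP-b
subunits of Pol I/II/III). The novelty score is `100 − mean(best-hit %
identity)` with an unweighted mean across available markers — no length
weighting, as none is defined for these markers. When a genome has several
curated copies of one marker, copies are averaged within the marker first so
each marker contributes equally; the case is logged. Genomes without markers
are excluded and listed. For tree figures the score is additionally clipped
into [30, 60], the display convention for this layer.

## Functional landscape

The occurrence matrix counts annotated genes per genome and orthologous group;
unannotated genes are ignored and all-zero genomes are flagged. Functional
redundancy of a genome is the fraction of its annotated genes whose function
occurs at least twice in that genome.

Before clustering, excluded genomes are dropped and function columns are
removed when they exceed `occurrence_cap` (default 500, strict) in a named
reference genome (the gigabase-scale assembly in the study design) **and**
carry a retrotransposon flag. The conjunction matters: repeat-driven runaway
functions connect otherwise unrelated genomes, but high copy number alone is
not evidence of a repeat artifact. The retrotransposon linkage is an input
flag column, since it originates from manual curation upstream.

Clustering is agglomerative with Euclidean distance and Ward linkage on raw
occurrence counts; a log10(x+1) transform is available but off by default —
the stated method clusters occurrences, the log scale being a display
convention. Outgroup genomes (small animals) are included in the full
dendrogram but excluded from group extraction; the remaining subtree is cut
into `group_count` (default 4) groups as a deterministic proxy for reading
groups off the dendrogram. Genomes are sorted by id before linkage and group
labels (A, B, …) follow first appearance along the dendrogram leaf order, so
the partition and labels are invariant to input row order.

Differential occurrence uses Welch's heteroscedastic one-way ANOVA per
function (the group variances of count data are not homogeneous), with
significance at `p < anova_p_threshold` (default 10⁻⁵) on raw p-values — no
multiplicity correction, matching the strict fixed threshold of the analysis
design; Benjamini–Hochberg q-values are reported alongside for transparency.
Functions with a zero-variance group are skipped with a recorded reason.
Significant functions receive Games-Howell pairwise comparisons
(`t = Δx̄/√(sᵢ²/nᵢ + sⱼ²/nⱼ)`, Welch–Satterthwaite df, p from the
studentized-range distribution with `q = |t|√2` and k groups). The
implementation is validated in the test suite against an independent
plain-formula oracle and against `pingouin`.

Consensus annotation of remote-homology gene clusters uses strict-majority
voting over annotated members (> 50% of votes; the quorum fraction is not
published, so strict majority is the declared choice, and ties are
unresolved/unknown). Clusters sharing an identical resolved consensus are
merged; unknown clusters pass through unmerged. Groups present in fewer than
`min_group_prevalence` (default 2%) of genomes are excluded — the rule is a
strict "less than", so a group at exactly 2% prevalence is retained.

## Niche model and projection

The niche model family used in the original analyses is an ensemble described
in prior work; this package instead defines a single explicit, fully
reproducible default. Each of the 7 parameters (SST, salinity, silicate,
nitrate, phosphate, iron, nitrate seasonality index) is standardized by the
training-station mean/sd. For a genome detected at `n ≥ min_stations_for_niche`
(default 5) stations, the niche optimum `m` is the mean of the presence
stations in standardized space and the spread `s` their (population) sd,
floored at `niche_spread_floor` (default 0.5 standardized units) so degenerate
axes stay finite. The presence probability on a cell with standardized
parameters `z` is

    P = exp(−½ κ D²),   D² = (1/7) Σⱼ ((zⱼ − mⱼ)/sⱼ)²,

with `κ = 2 ln 2 / mean(D² over presence stations)`, so that `P = 1` exactly
at the optimum and `P = 0.5` at the mean presence-station distance — anchoring
the probability midpoint at the data the model was fitted to. Land cells and
cells with missing parameters carry no values.

Presence area sums spherical cell areas `R² Δλ (sin φ_top − sin φ_bot)`
(`R = 6371 km`) over ocean cells with `P > presence_threshold` (default 0.5,
the midpoint of the probability scale). `ΔP = P₂ − P₁`; expansion cells have
`ΔP > delta_p_threshold` (default 0.1, strict) and reduction cells the mirror.

Driver attribution substitutes one parameter at a time: for a flagged cell,
`ΔPⱼ = P(period-1 grid with parameter j at its period-2 value) − P(period 1)`,
and the driver is the parameter with maximal `|ΔPⱼ|` (lexicographic
tie-break). Region-level shares are the percent of flagged expansion
(respectively reduction) cells attributed to each driver; an
`magnitude_weighted` flag weights cells by `|ΔP|` instead of counting them.
This one-at-a-time scheme is the simplest attribution consistent with
"parameters driving the shift"; it ignores parameter interactions, which a
Gaussian envelope keeps mild but nonzero.

## Synthetic data generator

The generator emulates the *structure* of the study inputs, not the ocean:

- **Genomes** — lengths log-uniform over [10 Mbp, 1.3 Gbp] (the observed range
  up to the gigabase-scale assembly), completions uniform over 5–95%.
  `n_redundant_pairs` (default 10 of 120 genomes) disjoint pairs get ANI ~
  U(98.1, 99.9) with aligned fraction > 0.25; background comparisons stay
  below 97% ANI, leaving a margin around the threshold so recovery is exact.
- **Environment** — analytic climatology fields with latitudinal gradients
  (SST decreasing poleward, macronutrients increasing, a longitudinal iron
  pattern), an analytic land mask, and a period-2 grid offset by per-parameter
  shifts (default +2 °C SST, −0.5 µmol/L nitrate, a plausible end-of-century
  magnitude). Stations (default 60, two depth layers each) sample ocean cells,
  so station environments are exactly co-located with the grid.
- **Recruitment** — each genome receives a Gaussian niche centered near a
  randomly chosen station with widths 0.6–1.6 station-level sds; stations with
  mean squared standardized distance ≤ 1 are inside. Inside stations get
  breadth ~ U(0.3, 0.9), outside ~ U(0, 0.2) — both clear of the 0.25
  detection threshold, so detection truth is recovered exactly. Reads are
  proportional to length × coverage; per-metagenome totals put the recruited
  fraction in roughly 5–30%.
- **Annotations** — occurrence counts are Poisson(λ_base = 1); each planted
  group's marker functions (default 20 per group, half known OGs, half
  unknown) get Poisson(λ_base + effect) in member genomes with effect size 5
  by default. Poisson is the simplest count model producing both the
  within-genome redundancy and the between-group separation the classification
  relies on. A configurable set of retrotransposon-like functions exceeds the
  occurrence cap in the largest genome. Each function's genes form one
  remote-homology cluster with 5% label noise (minority votes) and a 44%
  unknown-function share; 30% additional genes are unannotated.
- **Markers** — 1–6 RNA-polymerase markers per genome with identities around
  a genome-level baseline in U(40, 95).

Defaults were chosen once as desk-scale stand-ins for the study conditions and
are not tuned per test. What the generator does **not** emulate: sequence
content, assembly/binning error, compositional coupling between lineage and
function, spatial autocorrelation of detections, ocean circulation, or
non-Gaussian realized niches. Passing recovery tests therefore demonstrates
that each stage correctly inverts its own declared generative structure — not
that the defaults reflect any particular ocean.

## Numerical choices and degenerate inputs

- Read projection rounds half-up; completion 0 falls in the preserved branch.
- All rule boundaries are strict (ANI 98, aligned fraction 0.25, breadth 0.25,
  occurrence cap 500, |ΔP| 0.1); the prevalence floor is inclusive (≥ 2%).
- Welch ANOVA raises on groups with < 2 observations and skips functions with
  a zero-variance group, recording them. With equal group sizes and variances
  it agrees with the classical F to within its small-sample correction term
  (a few percent at n = 30), which the tests assert at 5% relative tolerance.
- Zero spread on a niche axis is floored at 0.5 standardized units; a zero
  mean presence distance (all presence stations identical) sets κ = 1.
- Dendrogram group labels and dereplication representatives use lexicographic
  tie-breaks; every stochastic step flows from a single seed.

## Problem sizes

The bundled test suite and the acceptance script run at desk scale by choice:
120 genomes, 60 stations × 2 metagenomes, 600 functions, and a 1° grid for the
acceptance run; smaller grids (5–15°) in unit tests. The statistical
calibration check uses 10,000 null functions with 4 groups of 30. These sizes
make every planted signal comfortably recoverable while keeping a full run in
seconds.

## Known limitations

- The Gaussian envelope is a deliberate simplification of the ensemble niche
  models used in the source analyses; absolute presence areas and driver
  percentages depend on it and on the κ calibration.
- The cosmopolitan score's published scale is not reproduced; the
  fraction-of-stations definition here is monotone-equivalent.
- Consensus voting quorum (strict majority) and the occurrence-matrix
  transform (raw counts) are declared choices where the source method is
  underspecified; both have documented alternatives in the API.
- Welch/Games-Howell p-values assume approximate normality of within-group
  occurrence counts; at λ = 1 counts are skewed, which the strict 10⁻⁵
  threshold absorbs in practice (the null calibration test passes at α = 0.05)
  but which matters for marginal p-values.
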