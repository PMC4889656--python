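# Methods

## Coordinate system

A chromosome is a circle of `L` bp with a point *oriC* and a point *ter*
(supplied as DoriC-style intervals; the interval midpoint is used). A locus
at coordinate `c` has normalized origin distance
`d = min(cw, ccw) / (L/2)` where `cw = (c − oriC) mod L` and
`ccw = (oriC − c) mod L`; its replichore is R when `cw ≤ ccw` (the exactly
antipodal point, a measure-zero tie, is assigned to R), else L. Four equal
bins partition the circle, anchored on *oriC* alone: O is
`[oriC − L/8, oriC + L/8)` and R, T, L follow in increasing-coordinate
order. Genes are anchored at the midpoint of `start..end` on the circle —
midpoint because it is strand-neutral and insensitive to annotation
differences at gene ends; genes wrapping the sequence origin take their
midpoint modulo `L`.

Two consequences of this design are accepted rather than corrected:

- When the two replichores are unequal (*ter* not antipodal to *oriC*),
  *ter* sits off-centre inside the T bin, and genes on the longer replichore
  can approach `d = 1` before reaching *ter*. Normalization is by `L/2`
  regardless. The per-pair results table reports `ter_offcenter_frac` so
  users can see how far a genome deviates from the antipodal ideal.
- Bins are quarters by *coordinate*, so an L/R-bin gene is exactly a gene
  with `d ∈ [0.25, 0.75)` on that replichore.

Internally all parsing converts to validated 1-based inclusive records;
coordinates in every output are 1-based inclusive.

## Orthology

Orthologs are bidirectional best hits between proteomes: `(a, b)` is kept
iff `b` is `a`'s best-scoring hit, `a` is `b`'s best hit in the reverse
search, and both directions pass the E-value cutoff (default 1e-10). Score
ties are broken by lexicographic protein id, so the map is a deterministic
function of its inputs. The scorer is pluggable:

- `ProteinAlignmentScorer` (default): BLOSUM62 global alignment
  (Bio.Align.PairwiseAligner, gaps −11/−1) with the pseudo E-value
  `m·n·2^(−score)` — a strictly monotone transform of the score at fixed
  lengths, which is all the best-hit contract uses; it is not a statistical
  E-value. This keeps the full BBH logic exercised without an external
  search tool.
- `PhmmerScorer`: a pyhmmer-backed phmmer search for real proteomes.

16S identity is a full Needleman–Wunsch global alignment with affine gaps
(open 10, extend 0.5 per column, EDNAFULL-like match 5 / mismatch −4, `N`
scores −2 and never counts as a match; end gaps penalized), identity =
100·matches/columns. Among co-optimal alignments the reported identity is
canonical: the DP maximizes (score, matches, −columns) lexicographically by
packing the triple into one exact integer objective (all scoring parameters
are required to be multiples of 0.5), so the result does not depend on any
traceback tie-break. Pair selection requires ≥ 97% identity, equal 16S copy
number (a growth-rate proxy), both genomes ≥ 1.3 Mb (excluding obligate
parasites, whose reduced genomes are anomalously stable), distinct species
(identical genus+species tokens of the organism name), and one pair per
unordered species pair (lexicographically smallest accession pair — a
reproducible stand-in for random pruning). For genomes with several 16S
copies, callers should supply the copy nearest *oriC*.

## Topology statistics

- **ρ_GOC**: Spearman correlation (configurable to Pearson) between the two
  `d` vectors of the ortholog pairs. Spearman is the default because rank
  correlation is the package's correlation of choice throughout. Undefined
  below 3 pairs.
- **LOESS correction**: `loess_residual(y, identity_16s, span=0.75)` uses
  statsmodels' lowess (locally weighted linear regression). Residuals are
  observed − predicted, so positive residuals mean more conservation than
  expected at that phylogenetic distance. A degenerate predictor (all
  identities equal) raises with advice to use raw `y`.
- **Bin matrix**: 4×4 counts of (bin in A) × (bin in B); row-normalized
  rates give `P_i` on the diagonal and `T_i−j` off it. Empty rows have NaN
  rates rather than zeros (no denominator, no rate).
- **T_L−R/R−L**: computed from the L and R bins only — the quarters adjacent
  to *oriC* and *ter* are deliberately excluded because they are inversion
  hotspots that would masquerade as interreplichore translocations. The
  pooled rate divides summed numerators by summed denominators; both
  directional rates are reported alongside it, since how single quoted
  values combine directions is ambiguous in general.
- **Translocation profile**: every ortholog pair whose replichore label
  differs between the genomes (all bins — O/T-local interreplichore moves
  are visible here even though they are excluded from the rate).
  `D_inter = |d_A − d_B|`; a pair is "symmetric" when `D_inter < 0.1`. A
  gene is *leading* when transcribed co-directionally with its fork: `+` on
  replichore R or `−` on L; a strand flip is a change of leading status.
- **Randomized null**: partner genes are re-paired by a uniform seeded
  permutation *within the interreplichore-translocated set*; positions and
  strands move together (one permutation per replicate). D_inter and the
  flip rate are recomputed per replicate. For uniform positions the null
  mean D_inter is 1/3 (`E|U − U′|`), and for balanced strands the null flip
  rate is 1/2 — both used as analytic checks.
- **Topology call**: longitudinal iff `T_L−R/R−L > 0.1` strictly; the
  threshold separates the observed bimodal regime (rates near a few percent
  vs near 0.45).
- **Contact enrichment**: given a symmetric normalized contact matrix on
  fixed bins, the test set is the contact values of cells containing at
  least one translocated interreplichore locus pair (each pair contributes
  its own midpoint and the partner position mapped onto this genome's
  opposite replichore at the partner's `d`); the control set is every other
  interreplichore cell. A cell in both is assigned to the test set only.
  Loci map to matrix bins by midpoint. Two-sided Wilcoxon rank-sum
  (Mann–Whitney, continuity-corrected, mid-ranked ties).
- **Expression symmetry**: Spearman correlations of expression profiles
  across conditions for all interreplichore gene pairs; `|Δd|` for strongly
  co-expressed pairs (ρ > 0.5) is compared to pairs with ρ ≤ 0 by the same
  rank-sum test. Constant-profile genes are dropped.

## Growth physiology

`T_R = (L/2)/v` with fork speed `v` defaulting to 600 nt/s — a single
average figure applied to all bacteria, overridable per organism since real
fork speeds vary and are mostly unmeasured. `R_f = T_R/T_D`; `fast` is the
strict inequality `R_f > 1` (more than one replication round per division).
Doubling times absent from direct measurements are estimated from 16S rRNA
copy number: the per-copy-number class median of a user-supplied reference
table, log-linearly interpolated between the nearest observed classes
(doubling times are positive and span orders of magnitude) and clamped at
the observed extremes. A class-median estimator was chosen over a parametric
regression because the reference relationship is monotone but noisy and the
functional form is not established.

## Enrichment tests

Per genome, 23 single-letter COG classes (the poorly characterized R and S
classes excluded) are tested for enrichment in each bin with one-sided
Fisher's exact tests over all COG-annotated genes; Bonferroni correction
uses the fixed family of 92 tests per genome (4 bins × 23 classes), and
results are reported as −log10(corrected p) with 1.3 (p = 0.05) as the
significance line. Horizontally acquired genes (midpoint inside any supplied
predicted-HGT interval; BED input is converted from 0-based half-open) are
tested per bin for *depletion*, Bonferroni family of 4. Sidedness follows
the direction each hypothesis names. Compositional HGT prediction is only
trusted for genomes with GC in [40, 60]%; outside that window the analysis
returns an explicit skipped status instead of results. The exact tests are
conservative on discrete tables: under uniform placement the fraction of
raw p < 0.05 is slightly below 0.05 for small class counts and approaches
0.05 at realistic sizes (~2000 annotated genes).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth:

- **Ancestor**: `n` genes laid out one per equal slot on the circle (no
  overlap), lengths ~U(0.3, 0.8) of a slot in whole codons; strand drawn so
  a gene is leading with probability 0.75 by default (the observed majority
  bias); COG classes drawn from a realistic weight table with class J
  four-fold up-weighted within `d < 0.25`, emulating the translation-gene
  concentration near *oriC*; *oriC*/*ter* antipodal; random seeded proteome
  and 16S sequence.
- **Events** (per gene, one seeded generator): loss with probability `q`
  (default 0.28, matching ~72% median ortholog conservation between closely
  related pairs); for surviving L/R-bin genes, translocation to the mirrored
  position on the opposite replichore with probability `f` plus Gaussian
  noise σ in `d` units (default σ = 0.02); for surviving O/T-bin genes,
  local inversion across the *oriC*–*ter* axis at rate 0.05 (position
  reflected, strand and replichore flip together so leading status is
  preserved — these genes appear in the translocation profile but not in
  T_L−R/R−L, mirroring the hotspot exclusion). Translocated genes keep
  leading-strand status with probability `p_s` (default 0.9). The default
  crossing fraction is 0.45, the median of the high-translocation regime;
  the low regime is simulated at 0.03.
- **Noise folding**: the symmetry noise of a translocated gene is folded
  back at the quarter boundaries (`d` reflected into [0.25, 0.75]),
  preserving the magnitude distribution of the noise while keeping every
  translocated gene an L/R-bin gene. This makes `f` exactly the quantity
  T_L−R/R−L estimates, so parameter recovery is unbiased instead of biased
  low by boundary leakage.
- **Layout**: surviving genes are placed at their own target coordinates,
  swept in circular order starting after the widest target gap and nudged
  forward only on collision. Positional error is therefore local (about one
  gene length, ~1e-4 in `d`); a rank-into-slots layout was rejected because
  random gene loss makes its cumulative rank displacement grow like √n,
  which at n = 2000 contributes ~0.02 in `d` — as large as the symmetry
  noise itself.
- **Sequences**: partner proteins diverge by 2% per-site substitution and
  the 16S by 1%, small enough that BBH recovers the true map essentially
  perfectly at the default cutoff — orthology error is tested separately,
  not confounded with topology statistics.
- **Contact maps**: `(1 + s)^(−α)` circular distance decay (α = 1 default),
  in longitudinal mode multiplied by `1 + β·exp(−δ²/2)` where δ is the
  distance (in bins) of the cell from the anti-diagonal through *oriC*
  (β = 3 default), then symmetric multiplicative log-normal noise
  (sd 0.15). Matrices are exactly symmetric.

What the generator does *not* emulate: real sequence evolution (codon
models, indels, rate heterogeneity), operon structure, annotation error,
unequal replichores, multi-chromosome genomes, macrodomain-scale contact
structure, or phylogenetic correlation between pairs. Passing tests
therefore demonstrate that the statistics recover the rearrangement signal
they are defined on, not that real annotations are free of the artefacts
the filters are meant to contain.

## Numerical and testing choices

Problem sizes: simulation-based tests and the acceptance script use
2000-gene, 2-Mb genomes (20 seeds per parameter setting; 100 replicates for
topology discrimination) and 40-bin contact matrices — large enough that
binomial sampling error is well inside the stated tolerances, small enough
to keep the whole suite around half a minute. Alignment DP is exact in
float64 by construction (all quantities are integers after packing); Fisher
tests use scipy's exact implementation, verified against integer
hypergeometric enumeration for every 2×2 table with total N ≤ 30. All
stochastic components take explicit seeds; every output file records its
configuration and seed in commented header lines.

Known limitations: only the first chromosome of a genome is modelled;
*oriC*/*ter* are inputs, never predicted; the topology call is a two-class
coarse label with a fixed 0.1 threshold and says nothing about finer
structure (macro/microdomains, inversion breakpoints); the pseudo E-value of
the internal scorer must not be interpreted statistically; `T_D` estimation
from rRNA copy number inherits the scatter of the reference table.
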