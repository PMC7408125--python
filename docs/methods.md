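# Methods

This note documents the models, conventions and numerical choices behind
`strainscope`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Ion-formula conventions and mass arithmetic

All mass bookkeeping is in the neutral frame using embedded IUPAC/AME
monoisotopic atomic masses. Two conventions map a written formula to an
observed positive-ion m/z, and published compound tables mix them freely:

- *protonated-neutral*: m/z = (M + z·m_p)/z — the formula is the neutral
  molecule, the ion is [M+H]⁺;
- *formula-is-cation*: m/z = (M − z·m_e)/z — the formula already contains
  the charge-carrying proton and only the electron deficit is corrected.

The electron correction (~0.55 mDa) is required for four-decimal agreement
with high-resolution values. The packaged compound table resolves the
convention per row by testing which reading reproduces the printed m/z
within 1 ppm. Four of the 33 rows are reproducible under neither convention
(formula or m/z typos in the source table); they are flagged `inconsistent`,
keep their transcribed annotations, and are excluded from mass arithmetic
rather than silently corrected. Four further rows agree within 1 ppm but
not within their own printed Δm; the tests pin this partition explicitly.

Formula decomposition enumerates the bounded CHNOS lattice (defaults
C ≤ 60, H ≤ 80, N ≤ 6, O ≤ 15, S ≤ 3, 3 ppm) with hydrogen solved from the
mass residual, filters by RDBE ≥ −0.5 (optionally the nitrogen rule), and
ranks by |ppm| then atom count. The isotope-pattern check is a first-order
binomial approximation (single heavy-isotope substitutions for M+1; ¹⁸O,
³⁴S and the double-¹³C term for M+2) — a qualitative plausibility filter,
not a fine-structure prediction.

## Molecular networking

The modified cosine weights fragments by the square root of intensity
(L2-normalized per spectrum), and admits a fragment pair when the m/z agree
within the fragment tolerance (0.5 Da default) either directly or shifted
by the precursor-mass difference. Matching is one-to-one, greedy by
descending weight product with deterministic index tie-breaks. The greedy
score is a lower bound on the optimal assignment and equals it whenever no
peak has two candidate partners; both facts are asserted against an
exhaustive matching oracle, and the whole scorer is cross-checked against
an independent modified-cosine implementation to machine precision.

Consensus clustering is a greedy single pass over spectra sorted by
precursor m/z: a scan joins the open cluster when its precursor lies within
the parent tolerance (0.01 Da) of the cluster median and its plain cosine
to the running consensus reaches the threshold (0.7); clusters below the
minimum size (4 scans) are discarded. Consensus peaks are tolerance-merged,
intensity-weighted centroids. This is order-deterministic by construction —
a requirement for reproducible tests — and makes no claim to reproduce any
specific clustering tool's internals. Networking applies the same 0.7
cosine threshold to all node pairs; no topology pruning is applied by
default (an optional top-k neighbour filter exists). Edge attributes carry
the cosine and matched-peak count; exports are GraphML plus node/edge TSV.

Spectral-library matching uses the plain (unshifted) cosine and requires
score ≥ 0.5 with at least two matched fragment peaks — one shared peak
never constitutes a hit regardless of score.

## Diagnostic tag classification

Three tag fragments define the compound groups: m/z 121.06 (group 1,
p-vinylphenol moiety), 255.04 (group 2, N-acetylcysteine conjugates) and
178.05 (group 3, bagrelactones; 176.0706 as the unsaturated alternative).
The printed m/z values are authoritative for matching — the published
group-1 formula (C₈H₈O⁺) computes to 120.06 and is recorded as a note only.
Matching tolerance is absolute (0.01 Da default, configurable), matching
the two-decimal precision at which tags are defined.

A tag whose moiety departs uncharged is detected as a neutral loss:
precursor − fragment within tolerance of (tag m/z − proton mass), enabled
for groups 1 and 3. In classification, directly observed tags outrank
neutral-loss inferences within a member spectrum. This precedence is not
cosmetic: a precursor sitting one group-1-tag-mass above the group-3 tag's
neutral mass (e.g. an ion near m/z 298.10) produces a spurious neutral-loss
coincidence that would otherwise overrule an observed fragment. Nodes whose
(direct) evidence spans several groups, or whose member votes tie, are ND
with an ambiguity flag; one group per node, never multi-label.

## Semi-quantification

EIC channels within a m/z tolerance are summed on the shared retention-time
grid; peak areas are trapezoidal integrals of the baseline-subtracted trace
over apex ± 3σ windows (σ from a local Gaussian fit, falling back to the
grid spacing), with the baseline estimated as the median intensity outside
the window — robust, and exact for the flat-baseline synthetic traces.
Relative abundance is 100 × area / reference-strain area per compound.
When the reference strain does not produce a compound there is no
denominator: those cells keep absolute areas and carry a
`reference-nonproducer` flag instead of a fabricated percentage. Best
producers are per-compound argmaxes, lexicographic on ties with a tie flag.
The quantification is semi-quantitative by design; no absolute calibration
is attempted.

## Metabolite profiles

Presence defaults to any nonzero abundance (threshold 0; configurable as a
fraction of the per-compound maximum). Profile heatmaps use the
generalized-log transform glog(x) = log((x + √(x² + λ²))/2) with λ
defaulting to the matrix's smallest nonzero entry (the upstream tool that
popularized the transform does not publish its λ), followed by Pareto
scaling (centre, divide by √sd). Clustering is agglomerative with Euclidean
distance and complete linkage on both axes, deterministic under scipy's
ordering; dendrograms export as Newick.

## Pan-BGC statistics and mutation profiling

Pan-BGC analysis is set algebra over a binary strains × family matrix:
union, core (present in every strain), strain-specific complement, the type
strain's complement, and single-carrier families. "Strain specific" is
operationalized as *absent from at least one strain* (non-core); fractions
are reported exactly and never rounded internally, because published
percentages for such counts often round inconsistently against their own
integers. The grape network places one node per (family, strain) presence
and a complete intra-family subgraph weighted by the family's orthology
score (default 1).

CDS comparison uses global affine-gap alignment (match +2, mismatch −3,
open −10, extend −0.5, deterministic first-alignment tie-break) and
classifies differences at codon resolution under the bacterial codon table
(NCBI table 11): substitution codons are silent iff the translations agree;
codon-aligned gap runs of length divisible by three are single
in-frame-deletion events; any frame-breaking gap is flagged `frameshift`
and excluded from the silent/non-silent tally rather than interpreted.
Mutation bookkeeping distinguishes *distinct* events (an identical change
shared by several strains counts once) from per-strain totals (counted per
strain), matching the shared-symbol convention of mutation maps. Events are
counted at codon level.

## Synthetic data

The generators emulate the structure of a strain-resolved study with the
first strain as reference: 7 strains on the metabolomics side, 24 compounds
across the three diagnostic groups (eight per group in expectation), a 15%
strain-exclusive production probability with 55% per-strain presence
otherwise, log-normal abundances (μ = 10, σ = 1 on the natural-log scale —
a wide, multiplicative spread over exact structural zeros), four replicate
scans per produced pair (so the minimum consensus-cluster size retains
every compound), 5 noise peaks per scan capped at 5% of the base peak,
2 mDa m/z jitter, and Gaussian chromatographic peaks (σ = 3 s) whose areas
equal the true abundances. Compounds of one group share a fragment pool:
four dominant "core" scaffold fragments every member carries plus minor
fragments sampled per compound, and the group's tag (or its neutral-loss
twin). Pools are disjoint between groups and precursors are kept ≥ 0.5 Da
apart. The genomics side defaults to an 18-strain collection with an
18-family core, 22 accessory and 2 single-carrier families, and plants
single-nucleotide substitutions (classified at planting time) plus
single-codon deletions chosen so the deletion gap cannot slide — the
optimal alignment is unique and codon-aligned, which is what makes exact
truth-table recovery a fair test rather than a coin flip.

What the generator does **not** model: realistic fragmentation chemistry,
chimeric spectra, retention-time drift between samples, detector
saturation, isotope envelopes in MS/MS, or sequencing error. Passing
recovery tests therefore demonstrate the correctness of the pipeline's
algorithms under clean, well-separated conditions — not its robustness to
every artefact of real instrument data.

## Problem sizes and determinism

Tests run the simulation at 3–7 strains and 4–24 compounds, 50 seeded
mutation configurations (3 genes × 60 codons), and 100-matrix batches for
the set-identity properties; the full suite completes in well under a
minute. Every generator is a pure function of (inputs, seed); the pipeline
derives per-stage seeds from the single run seed, so identical
configurations produce byte-identical TSV outputs (asserted in the tests).

## Known limitations

- The consensus-clustering pass is greedy and precursor-sorted; heavily
  overlapping precursor distributions (closer than the parent tolerance)
  would merge compounds that a multi-pass clusterer might separate.
- The compound table's four internally inconsistent rows cannot participate
  in mass arithmetic; their annotations (groups, producers) remain usable.
- Neutral-loss tag detection is inherently collision-prone at 0.01 Da on
  two-decimal tag definitions; the direct-over-NL precedence mitigates but
  cannot eliminate this.
- In-frame insertions are logged and ignored (the mutation model targets
  substitutions and deletions); frameshifts are surfaced as flags only.
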