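# Methods

## Scope and study design

The package analyses intra-individual sequence variation and absolute copy
number of rDNA marker genes from single-cell amplicon clone libraries and
digital/quantitative PCR, and asks whether within-species haplotype
variation disturbs phylogenetic placement. Wet-lab steps (staining, DNA
extraction, cloning, Sanger sequencing) and large-scale likelihood/Bayesian
phylogenetics are outside its scope; the phylogenetic component is a
deliberately desk-scale distance analysis (see below).

## Clone alignment

Clones from one individual differ by at most a handful of sites, so a
star alignment is used instead of a progressive MSA: the modal (most
frequent) sequence is the reference — ties broken toward the longer, then
lexicographically smaller sequence — every clone is globally aligned to it,
and insertions are merged into shared, labelled columns. Coordinates are
1-based on the ungapped reference; the k-th insertion column after
position p is labelled `p.k`. Removing gaps from any row reproduces the
input clone byte-exactly, which is asserted at construction time.

Pairwise alignment is Needleman–Wunsch with linear gap cost (defaults
match +1, mismatch −1, gap −2). Two conventions make coordinates
deterministic where the optimum is degenerate:

* traceback prefers diagonal, then up, then left;
* a gap that can slide without changing the score (i.e. inside a
  homopolymer run) is normalised to the 3′-most position of the run.

The indel-placement convention is ours; for reporting polymorphic sites it
only matters that it is fixed. The DP is exact (scores are checked against
an exhaustive enumeration oracle in the test suite for short sequences).

Primer trimming accepts IUPAC ambiguity codes in the primer (M, R, …
match any expansion at zero cost) and tolerates a configurable mismatch
budget (default 2) at each site; the best site wins, with ties resolved
toward the relevant sequence end.

## Polymorphism calling

Identical full-length (primer-trimmed) sequences constitute one haplotype;
haplotype 1 is the most common and is treated as the true underlying
sequence. Variant states are read per haplotype, never per clone, so clone
counts do not weight site discovery. A polymorphic site is an alignment
column with more than one state; multi-allelic columns count once (the
per-column convention matches how polymorphic-site matrices are reported).
Variants are typed insertion / deletion / transition (A↔G, C↔T) /
transversion relative to the haplotype-1 state, and flagged when inside or
immediately adjacent to a maximal poly-A or poly-T run of ≥ `min_run`
(default 3) bases — the shortest run in which a single-base indel remains
recognisably homopolymeric; no standard definition of "poly-A/T region"
exists, so the threshold is exposed in the configuration.

Singleton haplotypes (one clone) are annotated as probable
replication/sequencing error but are never filtered: annotation must not
change counts.

A species is split into separate reporting units when the dominant
haplotypes of its individuals differ by more than `max_intra_divergence`
(default 1% p-distance, single-linkage over individuals). This emulates the
cryptic-species convention of reporting divergent individuals separately;
the 1% threshold is this package's own choice. Multi-unit species report
per-unit site counts and lengths joined with "/".

## Copy-number estimation

Digital PCR: with k positive partitions of n, Poisson occupancy gives the
mean copies per partition λ = −ln(1 − k/n); the reaction total is λ·n and

    copies/cell = λ · n · dilution_factor / (fraction_loaded · cells_in_extract).

Partition volume cancels in per-cell reporting and is therefore not
required. Saturated reactions (k = n) have no finite estimate and raise a
dedicated error; the pipeline flags such rows and continues. The 95%
confidence interval is the Wilson score interval on the positive fraction
pushed through the same transform. It models partition sampling only, not
the binomial thinning of the cell's molecules into the loaded aliquot, so
reactions should be run at a mean occupancy high enough (λ ≳ 4) for
partition noise to dominate; the simulation-based coverage checks in the
test suite run at λ = 6, where empirical coverage is ~95%.

qPCR absolute quantification inverts a user-supplied standard curve
copies = 10^((Cq − intercept)/slope); no curve is bundled, and the
simulator's defaults (slope −3.32 ≈ 100% efficiency, intercept 38) are
synthetic values for testing, not calibration data.

Cell volume uses the two shape approximations common for ciliate cells:
elongate bell/cone forms V = ⅓·π·L·(W/2)·(T/2), otherwise the cuboid
V = L·W·T, with thickness T = width / (width:thickness ratio). The
packaged cell-dimension table is synthetic (plausible magnitudes for the
benchmark species, clearly labelled); published dimension figures are not
machine-readable, so volume operations are validated by closed form.

The packaged survey transcription stores the printed per-species
mean ± sd values; one species (Tetrahymena) is quoted in the source
narrative with a slightly different mean (1.0 × 10⁴) than the printed table
(1.1 × 10⁴) — the table value is shipped, the narrative variant is kept as
a documented constant. Correlations computed from the rounded table
(r ≈ 0.12 between markers) are reported, not asserted to more precision
than the rounding supports.

## Synthetic data

The clone simulator draws each cloned molecule's haplotype from the
designed frequencies and then mutates it once — a clone-level error model,
not a PCR-cycle model, consistent with interpreting singleton variants as
accumulated replication/sequencing error. Substitutions are iid per base
(`p_sub`, default 10⁻⁴); homopolymer errors are single-base insertions or
deletions of the tract base at the 3′ end of each poly-A/T tract
(`p_homo_indel`, default 10⁻² per tract). Both defaults are calibration
choices exposed in the configuration; no per-clone error rates are
published for the emulated protocol. Haplotype counts use deterministic
largest-remainder allocation of the design frequencies, with the RNG
shuffling clone order: the benchmark must reproduce its designed haplotype
table under every seed, and multinomial draws would occasionally drop rare
designed haplotypes.

The dPCR simulator thins the cell's copies binomially by
fraction_loaded/dilution_factor, scatters the surviving molecules uniformly
(multinomially) over partitions and counts occupied partitions. The qPCR
simulator is the standard curve plus Gaussian Cq noise.

The 13-species benchmark copies a published polymorphism survey
row-for-row: per-species amplicon length (959–1608 nt), clone numbers
(10 or 30 per individual; 38 individuals, two for the Epistylis-like
species), designed polymorphic-site counts and variant styles, including a
two-unit cryptic-species design (2/1 sites, 1604/1608 nt) whose second unit
is 2.5% divergent, and a cytosine deletion outside any homopolymer tract.
Benchmark libraries are simulated noise-free — all variation is designed —
which is what makes the five zero-variation rows exact. Species references
descend from a common synthetic ancestor (950 nt conserved core carrying
planted 5-nt poly-A/T tracts and SNP slots, plus a species-specific prefix
of a 700-nt variable region, with per-species substitution rates drawn from
8–18%): unrelated random references would not be alignable across species,
and the complete-deletion gap mode would retain almost no columns.

What passing the benchmark shows — and does not show: the pipeline
recovers designed variation exactly under the stated error model; it says
nothing about chimeras, PCR efficiency bias between haplotypes,
quality-score-dependent errors, or real chromatogram artefacts, none of
which are modelled.

## Phylogenetic congruence

The claim under test is topological — do conspecific haplotypes form
monophyletic groups, robustly to gap handling? — so neighbour joining on
p-distances suffices at desk scale, and bootstrap/posterior supports are
not reproduced. Cross-species alignment uses MAFFT; within the package,
distances support pairwise deletion (gapped columns dropped per pair) and
complete deletion (columns with any gap dropped globally), mirroring the
two-alignment practice of marker studies. NJ uses the canonical Q-matrix
agglomeration with ties broken to the first row-major minimum and negative
branch estimates clipped to zero; it provably recovers the topology of any
additive matrix, which the tests exercise on random 5–10-taxon trees.
Robinson–Foulds distance is the symmetric difference of nontrivial splits.
Only the direction of between-marker discordance (RF > 0 on discordant
input) is meaningful here; deep-node discordance on real taxon-rich
datasets is out of scope.

## Problem sizes and determinism

Default runs use 25,000 partitions per dPCR reaction, 100 replicates for
estimator-recovery summaries and 500 for interval-coverage checks, and the
full 13-species benchmark (1,170 clones) for polymorphism and congruence;
these sizes keep a complete pipeline run within a few seconds on one CPU
while leaving Monte-Carlo error well below the tolerances being checked.
Every random draw flows from a single configured seed; reruns with the same
seed are byte-identical, which the test suite asserts on file digests.

## Known limitations

* The star alignment is exact only for near-identical inputs; it is not a
  general MSA and the per-individual→species merge on a shared reference is
  this package's construction.
* The Wilson interval understates uncertainty at low occupancy where
  loading (thinning) noise is non-negligible.
* p-distances are uncorrected; for the benchmark's divergence range
  (≲ 30%) NJ topology is unaffected, but branch lengths are not
  substitution-model estimates.
* The error model injects at most one indel per tract per clone and does
  not model PCR cycles, chimeras or inter-haplotype amplification bias.
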