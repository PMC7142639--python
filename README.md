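# ciliate-rdna

Comparative analysis of mitochondrial and nuclear small-subunit rDNA
(mtSSU / nSSU) as marker genes for microbial eukaryotes, packaged as a
tested, reproducible pipeline.

Marker-gene surveys of ciliates and other microbial eukaryotes usually read
abundance and diversity from nSSU (18S) rDNA, but that gene varies in both
copy number and sequence within a single cell, which can distort
environmental-sequencing results. This package implements the desk side of
a study design that evaluates mtSSU rDNA as an alternative marker:

* **Clone-library haplotyping** (`clone_align`, `polymorphism`) — amplicon
  clones from single cells are primer-trimmed (IUPAC-aware), star-aligned
  against the modal sequence, collapsed into haplotypes (identical
  sequences = one haplotype; haplotype 1 = most common), and scanned for
  polymorphic sites classified as insertion / deletion / transition /
  transversion with poly-A/T homopolymer context. Species whose individuals
  carry dominant haplotypes > 1% p-distance apart are split into separate
  reporting units (putative cryptic species).
* **Copy-number estimation** (`copy_number`) — digital-PCR partition counts
  are converted to absolute copies per cell under Poisson occupancy,
  λ = −ln(1 − k/n) for k positive of n partitions and
  copies = λ·n·dilution / (fraction loaded · cells), with a 95% Wilson
  interval; qPCR Cq values invert a standard curve
  Cq = intercept + slope·log₁₀(copies). Summaries cover per-species
  mean ± sd, intraspecific fold ranges, nSSU:mtSSU ratios, Pearson
  correlations and cell volumes (cuboid L·W·T or bell/cone
  ⅓·π·L·(W/2)·(T/2)).
* **Phylogenetic congruence** (`phylo_check`) — neighbour-joining trees on
  p-distances over all species' haplotypes, under both pairwise- and
  complete-deletion gap handling, with per-species monophyly tests and
  Robinson–Foulds distances between the mode trees.
* **Synthetic data** (`synthetic_data`) — seeded generators for references
  with designed poly-A/T tracts, clone libraries with a clone-level error
  model (substitutions plus single-base indels in homopolymer tracts), and
  dPCR/qPCR readouts. A packaged 13-species benchmark reproduces a
  published survey's designed site counts, variant styles, clone numbers
  (10–30 per individual, 38 individuals) and amplicon lengths (959–1608 nt)
  row-for-row.

## Worked example

```python
from ciliate_rdna.copy_number import (
    PartitionData, dpcr_copies_per_cell, load_reference_survey, marker_comparison,
)

# one single-cell dPCR reaction: 24,938 of 25,000 droplets positive,
# half of a 2.7x-diluted extract loaded
est = dpcr_copies_per_cell(
    PartitionData(n_partitions=25_000, n_positive=24_938,
                  fraction_loaded=0.5, dilution_factor=2.7)
)
print(f"{est.copies_per_cell:.3g} copies/cell  (95% CI {est.ci_low:.3g}-{est.ci_high:.3g})")
# 8.1e+05 copies/cell  (95% CI 7.76e+05-8.43e+05)

cmp = marker_comparison(load_reference_survey())
print(cmp["mtssu_min"], cmp["mtssu_max"], cmp["n_nssu_below_mtssu"])
# 10000.0 810000.0 3
```

The packaged survey table spans 1.0 × 10⁴ – 8.1 × 10⁵ mtSSU copies per cell
(81-fold) versus 5.8 × 10³ – 1.1 × 10⁶ for nSSU (~190-fold); three of the 13
species carry fewer nSSU than mtSSU copies, and the two markers' copy
numbers are only weakly correlated (r ≈ 0.12).

The whole pipeline runs from the command line:

```bash
ciliate-rdna all --seed 316 --out results/
```

which simulates the benchmark fixture (clone FASTAs, partition/Cq/cell-size
tables), writes the survey-style polymorphism summary (five species with no
variation, eight with polymorphism, e.g. 10 sites from 90 clones in the
Trithigmostoma-like species), the copy-number and correlation reports, and
Newick trees in which every species' haplotypes form a monophyletic clade
under both gap modes.

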