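# Methods

## Model and rationale

`oxytrait` treats microbial O₂ utilization as a three-class problem —
Aerobe, Anaerobe, Facultative — predicted from sequence composition
alone. Two mechanisms make unannotated sequences informative. First,
proteome chemistry adapts to O₂: aerobic proteomes deplete redox-active
groups (cysteine thiols, methionine thioethers) and shift toward more
oxidized carbon, summarized by the average carbon oxidation state Z_C.
Second, O₂ utilization is phylogenetically conserved, and k-mer
composition is a proxy for phylogenetic proximity. K-mer features encode
both signals at once; the chemical descriptors isolate the first; the
random-relative baseline isolates the second. The evaluation machinery
exists to tell the two apart.

Raw source phenotype strings are harmonized onto the ternary scheme:
{Anaerobe, Obligate anaerobe} → Anaerobe; {Facultative, Facultative
anaerobe} → Facultative; {Aerobe, Microaerophilic, Obligate aerobe} →
Aerobe. Matching is case-insensitive after trimming, and the map can be
overridden from a two-column TSV. The binary task collapses the ternary
one: facultative organisms grow in the presence of O₂, so Aerobe and
Facultative map to Tolerant and Anaerobe to Intolerant.

## Features

K-mers are counted in overlapping windows (stride 1). Windows containing
any character outside the canonical alphabet (ACGT for DNA; the 20
standard residues for protein) are skipped rather than expanded — this
is deterministic and keeps the count conservation property exact: a
fully canonical sequence of length L contributes L − k + 1 windows.
Feature vectors always span the full lexicographic 4^k or 20^k space, so
matrix dimensions never depend on which k-mers were observed. The
default normalization is per-genome frequency, which removes genome-size
confounding (genome size is available separately as the gene-count
feature); raw counts are an option. DNA k-mers are not
reverse-complement-canonicalized by default — both strands' counts stay
distinct — with a `collapse_revcomp` switch for the folded 
representation.

Chemical descriptors use *residue* (polymerized) formulas: free amino
acid minus one water per peptide bond; ribonucleoside 5′-monophosphate
minus one water per phosphodiester bond. CDS thymine is read as uracil
for the chemical features only (they describe the RNA-coding sequence);
CDS k-mers are computed on the DNA as given. Z_C is computed by
electronegativity bookkeeping, Z_C = (z − n_H + 3 n_N + 2 n_O + 2 n_S) /
n_C, with phosphorus contributing nothing since it is never bonded to
carbon. Z_C is invariant to adding or removing water (Δ(−n_H + 2 n_O) =
0), so the free-monomer and residue conventions agree — the test suite
asserts this on all 20 amino acids and 4 ribonucleotides — and the
pooled-sequence Z_C equals the carbon-weighted mean of per-monomer
values. Nucleotide formulas are neutral (fully protonated) species;
alternative tables can be supplied by editing the formula mapping, which
is a plain module-level dict.

## Classifiers

Both model families standardize features to z-scores with statistics
fitted on the training split only (zero-variance columns pass through
unscaled); the standardizer and a hash of the feature schema travel with
the model, and prediction refuses matrices built under a different
schema. Logistic regression uses scikit-learn with C = 100 and max_iter
= 10,000, unweighted fitting by default (a class-weight flag exists).

The perceptron (input → 512 ReLU units → softmax) is implemented
directly in numpy: mini-batch gradient descent with batch size 16,
learning rate 10⁻⁴, at most 100 epochs, and L2 weight decay (default
10⁻⁴). After every epoch the balanced accuracy on a held-out validation
set is computed; the returned model carries the weights of the best
epoch (earliest on ties) and records the epoch index and the full
validation history. Plain SGD is the default optimizer with Adam as an
option; interaction-structure demonstrations (the XOR check) use Adam
at learning rate 10⁻³ because plain SGD at 10⁻⁴ needs far more than 100
epochs to traverse that loss surface at toy dimensionality. Argmax ties
break toward the alphabetically first class, and class order is fixed
alphabetically everywhere, so repeated runs are bit-reproducible given a
seed.

## Phylogeny-aware evaluation

Grouped holdout shuffles the taxa at the chosen rank and accumulates
whole taxa into the held set until it first reaches the target fraction
(default 20%), so no taxon ever straddles the boundary; the no-leakage
invariant is asserted programmatically on every emitted plan. A taxon
larger than (1 − fraction) of the dataset makes a leakage-free split
impossible and raises. Genomes lacking a name at the rank are excluded
with a warning count. Singleton strata stay in training in the
stratified test split so every class remains scoreable.

The random-relative baseline samples one labeled taxon-mate (excluding
the query) uniformly at the prescribed rank and returns its label,
abstaining when none exists; abstention is a first-class outcome, and
the curve operation reports accuracy on covered queries and coverage
separately, using leave-one-out over the dataset.

## Synthetic data

The generator emulates exactly the structure the evaluation machinery is
sensitive to, and nothing more. Proteins are i.i.d. draws from a
20-letter categorical distribution: a near-uniform base (0.05 each)
shifted along a fixed direction that enriches cysteine and methionine in
anaerobes and depletes them in aerobes (facultative organisms sit at the
base), scaled by `composition_effect`. Clades at a configurable rank can
carry their own deterministic zero-sum composition offsets
(`clade_effect`), which is what lets features encode clade identity when
labels are clade-linked but composition-free. Phenotypes are drawn per
conservation-rank taxon from the class priors and inherited, with
per-genome label flips at `phenotype_flip_prob`; a conservation rank of
None yields taxonomy-independent labels. CDS are reverse-translated with
synonymous codons weighted toward a class-specific GC target (aerobes
0.60, facultative 0.50, anaerobes 0.40 — giving nucleotide models a
signal of their own), and the genomic sequence is the shuffled CDS
concatenation with ~10% random intergenic spacers.

Defaults: 50 genes per genome of mean length 150 residues, effect size
0.05. The planted-signal recovery studies use 300 genomes with effect
0.08 (near the feasibility bound of 0.1, past which amino-acid
probabilities would go negative — an error, with an explicit opt-in
clip) and 200 genes × 250 residues, since trimer frequencies over the
8,000-dimensional AA 3-mer space need on the order of 50,000 residues
per genome before per-genome sampling noise stops dominating a
realistic compositional signal. Real genomes are 10–100× larger still.

What the generator does *not* emulate: higher-order sequence structure
(it is i.i.d. within a genome; real k-mer spectra have strong
neighbor dependence), horizontal gene transfer, genome incompleteness
and contamination, GTDB-scale taxonomic imbalance, and any correlation
between genome size and phenotype. Passing tests therefore demonstrate
that the machinery recovers the signals it is pointed at, not that real
genomes carry signals of that strength.

The depth fixture plants log10(aerobe/anaerobe) = slope ·
log10([O₂]/[H₂S]) + intercept + ε over a six-order chemical gradient
split between a decreasing O₂ trace and an increasing H₂S trace, with a
constant 10% facultative share; community abundances are exact
functions of the planted ratio, so the noiseless case recovers slope,
intercept, and ρ = 1 to machine precision.

## Environmental operations

Habitat summaries are unweighted MAG-count fractions; filters apply in
order (completeness ≥ 0.5, then ≥ 10 MAGs per sample, then ≥ 10 samples
per habitat) and the summary records surviving counts so bookkeeping is
auditable. Depth profiles are abundance-weighted, normalized within the
classified fraction of each sample, making them invariant to per-sample
rescaling. The redox correlation is Pearson's ρ between
log10([O₂]/[H₂S]) and log10(aerobe/anaerobe) with an OLS fit; per-point
relative error inverts the fitted line to predict the chemical ratio
from the biological one and compares against the measurement. Depths
with a zero anaerobe fraction have an undefined ratio and are excluded
(an epsilon floor exists but is off by default). Contig evaluation
accepts only genomic nucleotide k-mer models — CDS or protein features
would require ORF prediction on arbitrary genome slices — and splits the
concatenated genome into floor(n/l) consecutive length-l contigs,
discarding the remainder; the aggregate call is the class with highest
mean probability across contigs (majority vote optional).

## Numerical and design choices

* All randomness flows through seeded numpy generators; derived seeds
  use `SeedSequence` and stay below 2³¹.
* Frequency-normalized rows sum to 1 within 10⁻⁹; probability rows
  likewise.
* Completeness values above 1 in manifests are treated as percentages
  (the common convention for completeness-estimator output).
* Model serialization is JSON (logistic) or JSON plus an `.npz` weight
  blob (perceptron), embedding the feature-schema hash and the full
  training configuration.
* Problem sizes in the test suite and acceptance script (300-genome
  recovery studies, 128-genome holdout contrasts, 20-depth profiles
  with 200 Monte-Carlo draws, 8-genome contig sweeps) were chosen as the
  smallest sizes at which the studied effects are comfortably resolved.

## Known limitations

* The i.i.d. sequence model makes genomic k-mer signals weaker and
  cleaner than real ones; nucleotide-model results on synthetic data
  should be read qualitatively.
* The random-relative baseline matches on rank labels, not tree
  distances; two genomes in sister families count as unrelated at the
  family rank.
* The perceptron is exactly the published architecture (one hidden
  layer); it is not a general neural-network framework.
* Habitat summaries require caller-supplied habitat labels; ontology
  mapping from raw sample annotations is out of scope.
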