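# Methods

## Genotype model and scoring

A panel is a sample × locus grid of codominant calls over the allele
alphabet {I, J, X}: `II`, `JJ`, `IJ`, `IX`, `JX`, `XX`, plus the null call
`NN`. Raw band profiles are scored by matching each observed band to the
nearest catalogued band of the locus within a tolerance (`tolerance_bp`,
default 0 bp because the bundled catalogue records capillary-verified sizes;
gel-estimated inputs can pass 2 bp). A band equal to the *indica* reference
band is an I allele, the *japonica* reference band a J allele, any other
catalogued band an X allele. One distinct allele doubles to a homozygote,
two give the ordered heterozygote (I < J < X), none gives `NN`, and three or
more raise a scoring error naming the cell — such profiles need manual
review. Scoring is a pure function of the *set* of matched alleles, so it is
deterministic and invariant to band order.

One marker in the bundled catalogue is dominant (a single scorable band
carried by the *japonica* reference): band presence scores as the carrier
homozygote and absence as the homozygote of the other reference, not as
missing data — absence is the alternative allele at such a marker.

The binary band matrix expands each call into per-band presence columns
(reference bands first, *indica* before *japonica*, then non-reference bands
by decreasing size). A null call masks all of its marker's columns;
masked cells are excluded pairwise from every distance computation. An X
allele sets the marker's non-reference column(s); with a single
non-reference band per triallelic locus this is exact.

The bundled catalogue adopts one convention the source table leaves
unstated: for biallelic markers the first listed band is the *indica*
reference allele and the second the *japonica* one, with the triallelic
locus overridden (its smallest band is the *indica* allele, the largest the
*japonica* allele, the middle band non-reference). The catalogue is
recorded as published, including its published per-marker statistics
columns, which the consistency sweep checks rather than silently replaces.

## InDel molecular index and classification

Per accession, F_i = (2·#II + #IJ + #IX) / (2·N_eff) and
F_j = (2·#JJ + #IJ + #JX) / (2·N_eff), where N_eff counts non-null loci.
Null loci are excluded from the denominator (they contribute no scorable
allele); X alleles enter the denominator only, diluting both frequencies
symmetrically, and are flagged in the output (`n_x`) so users can rerun
without triallelic loci. For X-free, null-free accessions F_i + F_j = 1
exactly.

Classification is keyed on F_j alone; the published F_i and F_j bands are
complements of each other. The printed class bands are two-decimal
roundings with gaps (0.10/0.11, 0.25/0.26, ...), so the map closes each gap
at its midpoint, giving total, single-valued, half-open intervals:
[0, 0.105) typical indica, [0.105, 0.255) indica, [0.255, 0.395) close to
indica, [0.395, 0.605) intermediate, [0.605, 0.745) close to japonica,
[0.745, 0.895) japonica, [0.895, 1] typical japonica. Exact boundary values
are assigned to the upper class by convention.

Heterozygosity per accession is reported as 100 × n_het / n_scored to one
decimal, where het calls are those with two distinct alleles (IJ, IX, JX).

## Marker informativeness

Allele frequencies per marker are gene counts (homozygote = 2 copies,
heterozygote = 1 of each, nulls excluded); PIC = 1 − Σp². Band
informativeness uses the proportion of *genotypes containing the band*
(computed over unmasked samples), not the allele frequency — an all-
heterozygous marker therefore has PIC 0.5 but I_b = 0 per band and R_p ≈ 0,
which is what the published all-heterozygous marker row shows. NPA in
recomputation mode is the number of observed polymorphic bands and
PPA = NPA / catalogued bands, labelled `ppa_recomputed` because the
published PPA values (1 for biallelic, 2 for the triallelic marker) are not
derivable from a stated formula; the published table's own EMR/MI columns
are consumed as printed by the consistency sweep. Rare alleles are bands
present in strictly fewer than 5% of the panel's samples (observed at least
once).

## AMOVA

The two-level partition operates on the squared-Euclidean band distance
(count of mutually unmasked columns where presence differs), mirroring the
standard binary Phi-PT workflow for dominant/codominant band data:

- SS_total = (1/N) Σ_{i<j} d²; SS_within = Σ_p (1/n_p) Σ_{i<j∈p} d²;
  SS_among by difference; df = P−1 and N−P.
- n0 = (N − Σn_p²/N)/(P−1); Va = (MS_among − MS_within)/n0, clamped at 0
  for reporting (keeps Phi_PT in [0, 1]); Vw = MS_within.
- Significance: random reassignment of samples to populations preserving
  sizes; P = (1 + #{permuted ≥ observed}) / (1 + n_perm) (add-one
  estimator, never exactly 0 — a run that no permutation reaches reports
  P = 1/(n_perm+1)). Default 10,000 permutations, seeded and reproducible.

One deliberate numerical choice: the permutation ranking compares the
**unclamped** statistic on both sides. If both sides were clamped, every
panel whose observed estimate truncates to 0 would count all permutations
as ties and report P = 1, putting an atom at 1 in the null P-value
distribution; ranking the raw statistic keeps null P-values uniform (the
calibration test verifies this by KS test across replicate label
shufflings). The reported Phi_PT itself is still the clamped estimate.

With masked data the pairwise-complete distance matrix need not be exactly
Euclidean-embeddable, so SS_among can in principle go slightly negative;
it is carried through as-is and only the variance component is clamped.

Diversity indices per population and locus use gene-count frequencies over
scored samples: Na (alleles observed), Ne = 1/Σp², Shannon I = −Σ p ln p
(0·ln 0 = 0), He = 1 − Σp², uHe = (2n/(2n−1))·He. Loci with no scored
sample in a population are skipped with a warning. Across-locus summaries
report mean ± SE with SE = sd(ddof=1)/√L.

## Clustering and ordination

Jaccard similarity counts shared over united present-bands on mutually
unmasked columns; distance is 1 − S, reported as percent in text output.
UPGMA is implemented directly because its conventions are part of the
contract: merge height = average inter-cluster distance / 2, so cophenetic
distance (2 × LCA height) equals the average-linkage merge distance; ties
are broken toward the pair of clusters containing the lowest leaf indices.
Average linkage is reducible, so merge heights are non-decreasing and the
tree is ultrametric by construction. Newick branch lengths are height
differences; re-reading the tree reproduces cophenetic distances exactly.
Cutting at a similarity level s applies all merges with cophenetic distance
≤ 1 − s (default cut 0.30). The cophenetic correlation is the Pearson
correlation between cophenetic and input distances over all pairs
(undefined for ≤ 2 leaves or constant distances).

PCA runs on the centred (not standardised) band matrix via SVD; eigenvalues
are SS/(n−1), percent variance is eigenvalue over the covariance trace
(summing to 100 over all axes), masked cells are mean-imputed per column
with a warning, and each axis's sign is fixed so its largest-magnitude
loading is positive. Geographic PCoA z-scores latitude, longitude and
altitude (so metres and degrees are commensurable), builds Euclidean
distances and delegates classical MDS (Gower double-centering) to
scikit-bio; samples with incomplete coordinates are dropped with a warning.

## Synthetic panels

The generator emulates the surveyed panel's structure: per population and
locus a japonica-allele frequency q ~ Beta(α, β); per sample-locus the call
is IJ with probability `het_rate` (default 0.03 — landraces are selfers and
observed per-sample heterozygosity spans roughly 0–17%), otherwise JJ with
probability q, else II. Overlays: `NN` at `null_rate` (default 0.005,
matching nulls in ~13 of 8,000 calls) and an X substitution at triallelic
loci at `x_allele_rate` (default 0.02, keeping the third allele rare).
Draws are keyed per (seed, population, sample), so panels are deterministic
and one sample's genotypes do not depend on how many others are drawn.

The study-scale preset is 192 samples × 42 loci (one triallelic): two
2-sample reference-like extremes (Beta(0.2, 30) and Beta(30, 0.2)), a
160-sample indica-like population with Beta(5, 17) locus frequencies
(mean q = 0.23, spanning the indica / close-to-indica classes as in the
surveyed panel) and a 28-sample japonica-leaning population with
Beta(12, 8) (mean 0.60, intermediate / close-to-japonica) — ~85% of the
panel on the indica side. The divergence-calibration preset uses
Beta(2, 18) vs Beta(18, 2) populations of 30, which the AMOVA stage must
detect at Phi_PT > 0.5.

Truth is recorded at parameter level (the Beta draws) and realization level
(allele proportions of the emitted calls), so noise-free recovery is tested
as an exact identity while noisy recovery is tested statistically.

What the simulation does **not** model: linkage between loci, locus-specific
null-allele propensity (nulls are i.i.d. across cells, while real nulls
concentrate in a few primer-binding-site mutants), admixed individuals with
locus-level mosaic ancestry, and genotyping error. Passing recovery and
calibration tests therefore shows the estimators and tests are correct
under idealised sampling, not that real panels meet those assumptions.

## Problem sizes and defaults

Verification computations use deliberately small instances: brute-force
AMOVA oracles on ≤ 8 samples, UPGMA oracles on 6 leaves, permutation
calibration with 200 replicate shufflings × 199 permutations on a
60-sample panmictic panel, power checks with 10,000 permutations on 60
samples, and the full pipeline at the 192 × 42 study scale with 999
permutations. These sizes give stable statistics while keeping a
verification run in seconds to a couple of minutes on one core.

## Known limitations

- The published per-marker PPA/EMR convention for multi-band markers is
  reproduced from the fixture, not derived; recomputed values use the
  documented NPA/total-bands convention and can differ for triallelic loci.
- With multiple non-reference bands at one locus, `XX` calls set all
  non-reference columns; only single-X catalogues (as here) are exact.
- The UPGMA implementation is O(n³) in samples; fine for marker panels
  (hundreds of samples), not intended for thousands.
- AMOVA on pairwise-complete masked distances loses the exact Euclidean
  embedding guarantee; components are clamped rather than re-projected.
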