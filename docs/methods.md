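# Methods

## Genotype conventions

Genotypes are additive dosages in {0, 1, 2} of a counted allele, with −1
as the missing sentinel.  All analysis assumes minor-allele counting:
`polarize_to_minor` flips any SNP whose counted-allele frequency (over
non-missing calls) exceeds 0.5, recoding x → 2 − x and swapping the
allele registry; an exact 0.5 tie keeps the input orientation, which makes
the operation idempotent and deterministic.  PLINK .bed input is decoded
from the SNP-major 2-bit layout with the A1 allele counted; polarization
then enforces the minor convention regardless of how the file was
oriented.  SNP positions are 1-based as in .bim; all internal indices are
0-based.  Missing calls are preserved at I/O and handled downstream.

## SNP-score (eMAF)

The score of sample s at SNP g is x_gs minus the SNP's mean dosage across
samples.  Missing entries are mean-imputed *before* centering, so they
contribute exactly 0 afterward — missingness is neutral for map training
rather than a source of invented signal.  Rows are centered only, never
variance-scaled: the ±2 dosage scale is what the portrait coloring refers
to (blue ≈ major-homozygous, green ≈ heterozygous, red ≈ minor-homozygous
relative to the SNP mean).  A SNP with no non-missing calls is an error.

## Self-organizing map

SNP rows (length-S score profiles) are clustered onto a rectangular,
non-toroidal W × H grid, default 45 × 45 = 2,025 units, row-major with
(0,0) top-left.  Training is the classic online Kohonen rule with a
Gaussian neighborhood:

* learning rate: linear decay 0.5 → 0.01 over all presentations;
* neighborhood radius: linear decay max(W, H)/2 → 1;
* epochs: 20 full passes in a per-epoch seeded shuffle;
* initialization: the grid spans the first two principal directions of
  the score matrix (SVD with a fixed sign convention), giving a
  deterministic start; a seeded random initialization is available;
* best-matching units by exhaustive Euclidean search, ties broken by
  lowest unit index.

These schedule choices are standard Kohonen practice and are exposed as
parameters; identical (data, parameters, seed) give bit-identical
codebooks.  The final SNP → unit assignment is recomputed by brute-force
BMU search after training.  Supporting maps summarize the fit: per-unit
codebook variance, mean Euclidean distance to the 8-neighborhood (D-map;
edge units average their existing neighbors), and SNP counts per unit.

A *portrait* is one sample's codebook column arranged on the grid — no
rescaling is applied to stored values; only rendering normalizes.  Mean
portraits are unit-wise means over a sample set.

## Admixture estimation

Q and P maximize the binomial admixture likelihood by EM: each allele
copy's component responsibility is computed from the current Q, P, and
the M-step re-estimates Q rows on the simplex and P entries clamped to
[1e-6, 1 − 1e-6] (numerical safety for the log-likelihood).  Missing
entries are skipped.  Convergence: log-likelihood gain < 1e-4 or 2,000
sweeps; the trace is non-decreasing by EM construction.  K = 1 has the
closed form Q ≡ 1, p_g = mean dosage / 2.  Initialization is a seeded
Dirichlet(1) draw for Q rows and seed-perturbed overall frequencies for P.
EM is slower than quasi-Newton acceleration but monotone and adequate at
the package's scale; estimates are identified up to label permutation, so
`align_components` matches components across runs or across K by greedy
maximum correlation, appending unmatched components of the larger run.

Cross-validation masks individual non-missing genotype *entries* (not
samples): entries are partitioned into folds by seed, each fold hidden,
the model refit, and hidden dosages predicted as 2·Σ_k q_sk p_kg; the CV
error is the mean squared prediction error averaged over folds.  This is
the quantity whose decay across K guides the choice of component count.

## Correlation maps and marker extraction

For each component k and unit m, the map value is the Spearman correlation
(mid-ranks for ties; Pearson on ranks) between the Q column k and codebook
row m across samples.  Constant vectors get coefficient 0 (logged) rather
than NaN.  Units with coefficient ≥ 0.7 (inclusive) form the component's
region; the SNPs assigned to those units are its marker list.  Selection
is by correlation magnitude, not p-value — no multiple-testing correction
is applied, and the threshold trades region separation against list size.
A generic (snp_id, gene_id) join with an unannotated-fraction report
stands in for external variant annotation.

## Spot modules

Spots are detected per portrait by marking units at or above the
portrait's own quantile (default 0.98) and keeping 8-connected components
with ≥ 3 units, labelled A, B, C… by decreasing peak value.  A zero-range
portrait yields no spots.  The quantile and minimum size are exposed; the
defaults reflect that spot modules are sparse, corner-localized features.
Summary maps give the fraction of portraits in which each unit lies inside
a spot, and segmenting that map (same rule) yields a shared spot atlas.
Spot profiles are per-sample means of member-unit codebook values; the
spot correlation network joins spot pairs with |Pearson r| ≥ 0.5 (signed),
and the co-occurrence network joins reference spots jointly present — a
spot is present in a portrait when ≥ 50% of its units are marked there —
in more than 50% of a group's portraits.

## Sample topology

Portrait similarity is the Pearson correlation of portrait vectors (a
rank variant is switchable); the pairwise correlation map is block-ordered
by group.  The silhouette uses distance d = 1 − r (monotone-equivalent to
the chordal distance and simpler): s_i = (b_i − a_i)/max(a_i, b_i) with
a_i the mean intra-group distance excluding self and b_i the smallest mean
distance to a foreign group, which also names the nearest foreign group;
singleton-group samples get 0.  The similarity network thresholds
correlations at 0.5 and lays the graph out with a seeded force-directed
embedding.

## Synthetic data

The generator draws exactly the structure the admixture likelihood
assumes: ancestral frequencies p0 ~ U(0.05, 0.5); component frequencies by
Balding–Nichols drift Beta(p0(1−F)/F, (1−p0)(1−F)/F) at divergence F_st;
admixture rows Q ~ Dirichlet(α·1_K); genotypes Binomial(2, Σ_k q_sk p_kg).
On top, each component k gets a planted block of module SNPs with
p_kg ~ U(0.6, 0.9) for its own component and U(0, 0.1) for the others —
strongly component-specific co-mutation modules, the map-space analogue of
the spot clusters the method is built to find.  Frequency contrast rather
than linkage blocks is used because array-style tag SNPs are effectively
unlinked; what the simulator does *not* emulate is LD structure, clonal
pedigrees, genotyping error or ascertainment bias, so passing tests
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to those real-data complications.

Presets: `recovery` (K=3, G=2,000, S=300, F_st=0.2, α=0.2, 100 module
SNPs per component — 5% of SNPs per module, a realistic size for a
structured panel), `laucou-like` (K=6, G=10,000, S=780, ~300 module SNPs
each, echoing a genotyping-array study of ~10k SNPs by ~780 accessions)
and `overlap` (recovery at F_st=0.05, for stress-testing cluster
diagnostics).

## Problem sizes used in the checks

End-to-end verification runs on the `recovery` preset with a 30 × 30 map
trained for 10 epochs (module structure is already stable there; the
45 × 45 default is exercised for geometry), CV at 3 folds over 3 seeds
with a 200-sweep EM budget per fold, the silhouette trend on
K=3/G=1,000/S=150 panels at F_st 0.3 vs 0.05 with a 15 × 15 map, and
pipeline determinism on a K=2/G=150/S=40 panel with a 6 × 6 map.  Score
invariants are checked at the full 10,000 × 780 array scale.

## Known limitations

* The EM estimator is unaccelerated; very large panels (10⁵+ SNPs) will
  want the external quasi-Newton tool, whose Q output ingests directly.
* Spot identity across portraits relies on the shared segmentation atlas;
  portraits with strongly shifted modules can alias spots.
* The SOM schedule is a design choice; no claim of equivalence with any
  specific published SOM implementation is made.
* Correlation-map selection has no significance control by design; treat
  marker lists as effect-size rankings.
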