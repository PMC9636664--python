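# Methods

## Coordinate model

All analyses run on a shared frame: one chromosome cut into `n_bins` bins
of `resolution` bp. Bin `i` covers bp `[i·resolution, (i+1)·resolution)`,
0-based and half-open. TADs are half-open bin intervals `[start_bin,
end_bin)` with `end_bin > start_bin`; a dataset (`TadSet`) is an ordered,
pairwise-disjoint collection of such intervals, with gaps allowed (real
callers leave unassigned regions). Boundaries are the union of all starts
and ends; the shared corner of two adjacent domains counts once (set
semantics). One chromosome per comparison; multi-chromosome inputs are
filtered to the requested chromosome at parse time.

When reading bp coordinates, `start_bin = floor(start/resolution)` and
`end_bin = ceil(end/resolution)`: a partially aligned interval keeps its
full bin coverage, and the conversion is deterministic. Caller outputs are
inconsistently scaled, so units can be auto-detected: coordinates are
treated as bins when the file's maximum coordinate is below `2·n_bins`,
else as bp; the decision is logged and overridable. Overlapping input
domains are a hard error rather than being silently clipped — the
concordance metrics assume disjoint domains, and silent repair would
corrupt them. Zero-length domains after conversion are likewise an error
(a size-0 domain breaks the MoC term's denominator).

## Sharing metrics

A boundary `x` of dataset A is *shared with* dataset B at tolerance `t`
(an integer bin count; `±t` bins = `±t·resolution` bp) when some boundary
`y` of B satisfies `|x − y| ≤ t`. A domain `[s, e)` is shared when one
single domain `[s', e')` of B has `|s − s'| ≤ t` and `|e − e'| ≤ t`.
Matching is existential, not bipartite: two A-elements may match the same
B-element. This is the simplest deterministic reading of a tolerance
window and needs no tie-breaking; the consequence — counts are relative to
the query set and asymmetric in general — is intended, and every table is
labelled with its query dataset. Counts are non-decreasing in `t` by
construction.

The one-vs-all tables report raw shared counts of a reference against each
other dataset over a tolerance range (default 0–3 bins, flag-overridable).
The all-vs-all sharing profiles count, for every element of every dataset,
how many of the other K−1 datasets contain a match, yielding per-dataset
histograms over k = 0..K−1 (reported as counts and as percentages of the
dataset's element total).

Size summaries use quartiles with linear interpolation between order
statistics (the inclusive method), so expected values in tests are exact.

## Measure of Concordance

For partitions A and B with N_A and N_B domains,

    MoC(A, B) = ( Σ_{i,j} |A_i ∩ B_j|² / (|A_i|·|B_j|) − 1 )
                / ( √(N_A·N_B) − 1 ),

with MoC = 1 when N_A = N_B = 1. Overlaps and sizes are measured in bins;
the term is scale-invariant, so any common unit gives the same value.
Identical partitions score exactly 1 (the double sum reduces to N); the
score is symmetric, and never exceeds 1. For datasets that fully tile the
region it is nonnegative (Cauchy–Schwarz); gapped datasets can produce
small negative values in pathological near-disjoint cases. These are
reported raw with a warning rather than clamped: a negative MoC flags a
data problem (e.g. two callers annotating disjoint regions), and clamping
would hide it.

The implementation sweeps the two sorted domain lists so each A-domain is
only compared against the contiguous run of B-domains it can overlap
(O(N_A + N_B + #overlapping pairs)); tests check it against a brute-force
all-pairs oracle to 1e-12. The all-vs-all output is the full symmetric K×K
matrix plus, per dataset, the mean over the other K−1 datasets.

## Matrix normalization

Five standard balancing methods are provided behind one `normalize()`
surface: VC (divide by the product of row marginals, then rescale to the
input total sum), SQRT-VC (same with the square root of the marginal
product), KR (Knight–Ruiz diagonal scaling to unit row sums, implemented
as the inner-outer inexact-Newton iteration with CG inner steps), ICE
(iterative marginal correction, result rescaled to unit mean over
unmasked entries), and SCN (alternating row/column L2 normalization,
then symmetrization). Bins with zero marginal sum are masked out before
balancing and restored as zero rows/columns afterwards — every method
would otherwise divide by zero. All methods preserve symmetry and
nonnegativity; outputs are re-symmetrized (`(M + Mᵀ)/2`) to remove
floating-point drift before validation against the container's 1e-9
relative symmetry tolerance.

Defaults: tolerance 1e-5 on marginal uniformity (KR/ICE) or iterate
change (SCN); iteration budgets 200 (ICE/SCN) and 3000 (KR inner
iterations). Non-convergence raises an error carrying the final residual;
the batch front end (`run_normalize`) logs the failure and continues with
the remaining methods.

Input formats: dense square whitespace-delimited text (bin count inferred
from the row count; asymmetry beyond 1e-9 relative is an error), sparse
`i j value` triplets (bin indices, or bp positions auto-detected when
coordinates exceed the bin range and are resolution-multiples; duplicate
cells are summed with a warning), and cool/h5 containers. The `.cool`
layout is plain HDF5, read directly via h5py: chromosome and resolution
come from the container's own metadata, multi-resolution (`.mcool`)
files require an explicit resolution choice, and a missing chromosome
error names the available ones.

## Embeddings

The feature representation feeding PCA/t-SNE is a per-bin binary vector
per dataset. Default mode is `boundary_dilated` with tolerance 1:
boundary indicator vectors dilated by ±1 bin, so boundaries within the
tolerance window overlap in feature space — the same notion of closeness
the sharing metrics use. Plain `boundary` and `occupancy` (bin covered by
any domain) modes are available.

PCA centers the rows and projects onto the top two principal axes; each
axis' sign is fixed so its largest-magnitude loading is positive, making
output deterministic. If all datasets are identical (zero variance) every
point is placed at the origin with a warning. With K = 2 datasets the
second component is identically zero.

t-SNE requires K ≥ 4 datasets; perplexity defaults to `min(30, (K−1)/3)`
and larger requests are clamped there with a warning. The exact (non
Barnes-Hut) gradient is used — K is tiny — with PCA initialization and a
fixed `random_state`, so identical inputs and seed give bit-identical
coordinates.

## Synthetic generator

The generator emulates the structural features the comparison metrics
respond to, not Hi-C physics. Partitions are laid left-to-right with
domain sizes ~ Uniform{min_size..max_size} bins and optional gaps
(probability `gap_prob`, size Uniform{1..gap_max}); generation stops when
the next domain would not fit, so a trailing remainder may stay
uncovered. The uniform size law was chosen over empirical TAD-size fits
because all downstream properties tested depend on orderings between
perturbation levels, not on the size distribution. Study conditions used
by the acceptance checks: 500 bins with sizes 5–25 for perturbation
sweeps, 200 bins for balancing fixtures, 300 bins for the clustering
design — sizes at which the full acceptance run completes in well under a
minute per section.

Perturbation operators model the observed disagreement modes between
callers. `jitter(magnitude)` moves each boundary by
Uniform{−magnitude..+magnitude} bins, processed left to right, each move
clamped to stop one bin short of its (unmoved) right neighbour so domain
order and ≥1-bin sizes are preserved; coincident start/end corners move
as one point, so adjacent domains stay adjacent. `merge_split` merges
each adjacent pair with probability `p_merge` (spanning any gap between
them) and then splits surviving domains of size ≥ 2 at a uniform interior
point with probability `p_split` — high `p_merge` emulates callers that
find fewer, larger domains; high `p_split` the many-small-domains mode.
Contact matrices are Poisson block models: intensity `intra_rate` inside
domain diagonal blocks, `inter_rate` elsewhere, upper triangle drawn and
mirrored. All four operations are deterministic given their seed.

Because the generator produces ideal block structure and uniform sizes,
passing tests demonstrate correctness of the comparison machinery and the
direction of its response to controlled perturbations — not performance
on real Hi-C data, which has distance decay, hierarchical sub-domains and
caller-specific artefacts the generator deliberately omits.

## Reports and determinism

A comparison run writes CSV/JSON files (no HTML): counts, size summaries,
one-vs-all tables, sharing profiles per tolerance, the MoC matrix and
averages, embedding coordinates, and a provenance block echoing the full
configuration, package version and seeds. All floats are formatted with a
fixed `%.10g`, and every random stage is seeded from the run
configuration, so identical configs produce byte-identical reports.
Errors in any input dataset abort the run before anything is written,
naming the offending dataset; partial reports are never left behind.

## Known limitations

- One chromosome per comparison; no BED fields beyond column 3, no BED12
  or GFF.
- No statistical significance for boundary overlap (permutation tests) and
  no alternative partition-similarity measures (Jaccard, VI).
- Normalization covers the cis matrix of one chromosome; no genome-wide
  trans balancing, no distance-decay (expected/observed) correction, no
  Juicer `.hic` binary format.
- The MoC of two single-domain datasets is 1 by convention regardless of
  their overlap; callers producing one domain each are degenerate inputs
  for this score.
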