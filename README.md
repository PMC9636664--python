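# tadconcord

Concordance and robustness analysis of topologically associating domain
(TAD) datasets.

TADs are contiguous genomic regions with elevated intra-region chromatin
contact frequency, visible as blocks along the diagonal of a Hi-C contact
matrix. Dozens of TAD-calling algorithms exist and they disagree — on the
number of domains, their sizes, and where the boundaries fall. Researchers
comparing callers (or the same caller across cells, chromosomes, or
normalizations) need quantitative answers to "how much do these TAD
datasets agree, and where?". `tadconcord` provides that comparison suite as
a library and CLI:

- **Counts and size distributions** of domains per dataset, in genomic bins.
- **Shared boundaries and shared domains** under a tolerance window: two
  boundaries are shared at tolerance *t* when they lie within *t* bins
  (±*t* × resolution bp) of each other; a domain is shared when both its
  rising and falling boundaries match a single domain of the other dataset.
  Reported one-vs-all (raw counts per tolerance) and all-vs-all
  (percentage sharing histograms).
- **Measure of Concordance (MoC)** between partitions *A* = {A₁…A_N_A} and
  *B* = {B₁…B_N_B}:

  MoC(A, B) = ( Σᵢⱼ |Aᵢ ∩ Bⱼ|² / (|Aᵢ|·|Bⱼ|) − 1 ) / ( √(N_A·N_B) − 1 )

  with MoC = 1 when N_A = N_B = 1. Identical partitions score exactly 1;
  the score is symmetric and scale-invariant. Emitted as a full all-vs-all
  matrix with per-dataset averages.
- **PCA and t-SNE embeddings** that place similar datasets close together,
  from per-bin boundary/occupancy feature vectors.
- **Hi-C matrix normalization** front end: VC, SQRT-VC, KR, ICE and SCN
  balancing for dense text, sparse triplet, and cool/h5 container inputs.
- **A synthetic generator** of TAD partitions, perturbations (boundary
  jitter, merge/split) and Poisson block-model contact matrices, so the
  whole suite is testable without external data.

## Worked example

```python
from tadconcord import (GenomicBinning, TadSet, boundaries_of, moc,
                        shared_boundaries, shared_domains, size_stats)

binning = GenomicBinning("chr10", resolution=40_000, n_bins=100)
topdom = TadSet.from_intervals("topdom", binning,
                               [(0, 10), (10, 22), (25, 40), (40, 60)])
hicseg = TadSet.from_intervals("hicseg", binning,
                               [(0, 11), (11, 22), (26, 40), (40, 61)])

s = size_stats(topdom)
print(f"topdom sizes (bins): median {s.median:.1f}, mean {s.mean:.2f}")
for t in (0, 1, 2):
    nb = shared_boundaries(boundaries_of(topdom), boundaries_of(hicseg), t)[0]
    nd = shared_domains(topdom, hicseg, t)[0]
    print(f"tolerance {t}: shared boundaries {nb}/{len(boundaries_of(topdom))}, "
          f"shared domains {nd}/{len(topdom)}")
print(f"MoC = {moc(topdom, hicseg):.4f}")
```

prints

```
topdom sizes (bins): median 13.5, mean 14.25
tolerance 0: shared boundaries 3/6, shared domains 0/4
tolerance 1: shared boundaries 6/6, shared domains 4/4
tolerance 2: shared boundaries 6/6, shared domains 4/4
MoC = 0.9063
```

The two datasets place every boundary within one bin of each other — at
tolerance 0 only 3 of 6 boundaries coincide exactly, at tolerance 1 all do,
and all four domains match end-to-end. The MoC of 0.9063 quantifies the
same near-agreement on the 0–1 concordance scale.

The same comparison from the shell, on files:

```sh
tadconcord simulate --n-bins 500 --n-sets 3 --seed 0 --out fixtures/
tadconcord compare --tads fixtures/synthetic0.bed --tads fixtures/synthetic1.bed \
    --tads fixtures/synthetic2.bed --chrom chrS --resolution 40000 --n-bins 500 \
    --tolerances 0,1,2,3 --out runs/demo
tadconcord normalize --matrix fixtures/matrix.txt --methods vc,kr,ice --out runs/norm
```

`runs/demo/` then holds `counts.csv`, `size_summaries.csv`, the per-dataset
`shared_boundaries_vs_*.csv` / `shared_domains_vs_*.csv` tables, the
sharing-profile histograms per tolerance, `moc_matrix.csv` +
`moc_averages.csv`, the embedding coordinates, and a `provenance.json`
sufficient to re-run the analysis bit-identically.

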