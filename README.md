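# saturascreen

Saturation screening of phylogenomic data partitions by phylogenetic
informativeness (PI) decay, with a desk-scale divergence-time experiment
showing why it matters.

## The problem

Molecular clock analyses of the same clades can disagree by 50–100 million
years depending on whether they use fast mitochondrial or slow nuclear
markers.  A major culprit is substitution saturation: at a site evolving at
rate λ, support for an internode at time T peaks at T* = 1/(4λ) and decays
beyond it, where accumulating hidden substitutions turn signal into
homoplasy.  Deep branches estimated from saturated sites are distorted, and
node ages inherit the distortion.

`saturascreen` implements the screen end-to-end for users with an
alignment, a dated tree, and a partition scheme:

1. estimate a maximum-likelihood substitution rate per alignment column on
   the fixed chronogram (Felsenstein pruning, rates in subs/site/Ma);
2. profile per-partition informativeness through time,
   PI(T) = mean over sites of 16 λᵢ² T e^(−4λᵢT);
3. flag partitions whose profile has decayed more than 5% from its peak
   before a user-set boundary (default 145.0 Ma, Jurassic–Cretaceous), and
   prune their sites;
4. (synthetic experiment) date trees from full vs pruned data with a
   least-squares strict clock and compare against known ages.

Partition schemes use the codon-position stride dialect of NEXUS charsets
(`charset name = 1-1145\3;` selects every third site), plus RAxML-style
lines.

## Worked example

Count the sites covered by the nine saturated subsets of the published
mitochondrial partition table, straight from the stride ranges:

```bash
$ saturascreen sites --scheme data/mtdna_partitions.charsets \
    --subsets subset1,subset3,subset4,subset5,subset6,subset8,subset11,subset12,subset14
subset1 1412
subset3 1000
subset4 1259
subset5 749
subset6 1151
subset8 748
subset11 324
subset12 352
subset14 359
total   7354
```

7354 of the 10061 aligned mitochondrial sites sit in saturated subsets;
2707 survive pruning.

Run the screen on simulated data with known structure:

```bash
$ python analysis/02_screening_demo.py
mito_like: flagged 12 of 13 partitions, removing 7200 of 7800 sites
  mtfast1    peak    8.7 Ma  decay  0.879  FLAGGED
  ...
  mtcons3    peak  132.0 Ma  decay  0.003  retained
nuclear_like: flagged 0 of 9 partitions, removing 0 of 5400 sites
  nuc1       peak  111.3 Ma  decay  0.026  retained
  ...
```

Every fast partition (mean 0.010 subs/site/Ma; profile peaks ~8–11 Ma,
decay ~0.85 by 145 Ma) is flagged; every slow partition (mean 0.0015;
peaks ~110 Ma, decay ~0.03) is retained.

The headline experiment (`python analysis/05_reconciliation.py`, ~10 min)
dates 20 replicate 44-taxon trees from full and pruned data and prints:

```json
{
  "mito_like":    {"median_rmse_full_minus_pruned": 28.5,
                   "fraction_pruned_better": 1.0,
                   "median_rmse_full": 40.7, "median_rmse_pruned": 13.7},
  "nuclear_like": {"median_rmse_full_minus_pruned": 0.0, ...}
}
```

Pruning saturated partitions cuts the fast dataset's node-age RMSE from
~41 to ~14 Ma (better in 20 of 20 replicates) and leaves the slow dataset
untouched — the synthetic analogue of fast/slow marker age reconciliation.

## Library surface

```python
import saturascreen as ss

aln    = ss.read_alignment("alignment.fasta")
tree   = ss.read_chronogram("chronogram.nwk")        # ultrametric, Ma
scheme = ss.parse_stride_ranges(open("parts.charsets").read())

rates    = ss.estimate_site_rates(aln, tree, ss.SubstitutionModel.gtr(...))
profiles = ss.profiles_for_scheme(rates, scheme, tree.root_age)
report   = ss.screen(profiles, scheme, boundary=145.0, threshold=0.05)
pruned, new_scheme, site_map = ss.prune(aln, scheme, report)
```

CLI subcommands: `simulate | rates | profile | screen | date | experiment |
sites | convert` (see `saturascreen --help`).

The numbered scripts under `analysis/` are thin drivers over the library:
site bookkeeping, the screening demo, rate recovery, the dating-shrinkage
mechanism, and the reconciliation experiment, each writing tables under
`results/`.

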