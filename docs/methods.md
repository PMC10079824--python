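# Methods

This note documents the models, parameters and numerical choices behind
`svwave`, and what the synthetic generators do and do not emulate.

## Coverage representation (BCOV)

Per-base read depth is stored as one little-endian unsigned 16-bit
integer per position, sequentially, with no header: a file is exactly
`2 × n_positions` bytes and any window is one O(1) seek. Depths above
65535 are clamped to 65535 — the largest value two bytes can represent.
Multi-contig files share one payload stream; a plain-text sidecar index
(`contig  byte_offset  n_positions` per line) locates each contig.
Endianness and the index layout are fixed here so files are portable.

Window convention: a window of half-width *w* centred on 1-based
breakpoint position *p* covers `[p − w, p + w − 1]` — `2w` values with
the breakpoint at 0-based offset *w*. With the default *w* = 256 every
profile has 512 values. Windows extending past a contig end are refused,
not padded; the extraction layer drops such loci.

## Variant filtering and breakpoint taxonomy

Records are kept when FILTER is exactly `PASS` and the interval length
`end − start + 1` is ≥ `min_sv_len` (20 bp); at exactly 20 bp the record
is retained. Insertions carry no reference length and are exempt. When a
per-sample `FT` field is present it must also be `PASS` for that
sample's profile to be used. Genotypes: `1/1` → hom-alt, `0/1`/`1/0` →
het, everything else (hom-ref, missing, multi-allelic) is excluded.

Loci: interval SVs ≥ 512 bp yield a left locus at `start` and a right
locus at `end`; insertions yield one breakpoint locus at `start`;
interval SVs of 20–511 bp are "special" (spSV) with a single window
anchored at the variant midpoint `⌊(start+end)/2⌋`, chosen so the whole
variant fits inside the window — copy-number calls never yield spSV
loci. Profiles that are entirely zero are dropped (this is the mechanism
that can unbalance left vs right counts at variant edges, where one side
of a deletion may carry no reads at all).

## Signal representation

* **Pooling**: arithmetic mean in fixed 8 bp windows; a ragged tail is
  averaged over its own length. 512 bp → 64 points.
* **Normalization**: `(x − μ)/σ` with population (ddof = 0) σ. Two
  modes: `sample` uses the sample's genome-wide coverage moments when
  available (the default, matching normalization "within a sequenced
  sample"); `profile` uses the profile's own moments. A constant profile
  in per-profile mode maps to all zeros. Note that sample-level moments
  are estimated on the raw per-base signal and applied to the pooled
  signal; pooling shrinks noise variance, so sample mode leaves pooled
  profiles with variance below 1 — harmless for clustering, which only
  compares profiles normalized the same way.
* **SAX**: with breakpoints `β_k = Φ⁻¹(k/a)`, `k = 1..a−1`, symbol *s*
  covers the left-closed cell `[β_s, β_{s+1})`; a value exactly on a
  boundary takes the upper cell, so a constant-zero series maps to
  symbol `a/2`. One symbol per pooled point (the pooling step already
  plays the piecewise-aggregate role), alphabet 24 by default.
* **MINDIST**: `√(n/w)·√Σ cell²` with cell distance zero for identical
  or adjacent symbols and otherwise the gap between the nearer cell
  edges. This lower-bounds the Euclidean distance of the underlying
  z-normalized series but is **not a metric** (adjacent cells are at
  distance zero), which matters for the pruned search below.
* **DTW**: classic endpoint-anchored dynamic programming over squared
  pointwise costs, square root at the end; no warping-window constraint
  by default, with an optional Sakoe–Chiba band in the config. The DP
  kernels are numba-jitted.

## DTW K-Means

Initialisation is k-means++-style seeding on DTW distances with 10
restarts (best inertia kept). The centroid update is DTW barycenter
averaging: each member is aligned to the current barycenter along its
optimal warping path and each barycenter point becomes the mean of the
values aligned to it. Both reassignment and the DBA update are
non-increasing in the within-cluster sum of squared DTW distances; the
implementation asserts monotonicity (tolerance 1e-8) every iteration and
stops on convergence or after 30 iterations. Runs are deterministic
given the seed.

The cluster count is estimated once per SV class by clustering bootstrap
subsamples (drawn without replacement) at each candidate k and averaging
the DTW-silhouette; the default study protocol uses 80 runs. On the
synthetic two-family pools this selects k = 2, which is then fixed for
discovery.

**Consistency experiment**: per repeat, a random subset of 100 raw
profiles is clustered three ways — compressed with seed A (C0),
compressed with seed B (C1), uncompressed with seed A (C2). The
uncompressed arm reuses C0's seed: re-running the identical compressed
clustering would compare a run with itself, so the informative contrast
is compression at matched seed. Agreement between two runs is the
maximum over label permutations of the co-assigned fraction (solved as
an assignment problem, so it generalises beyond k = 2). The two
agreement distributions (seed effect: C0 vs C1; compression effect: C0
vs C2) are compared with a one-sided two-sample Kolmogorov–Smirnov test,
alternative "compression-effect agreements stochastically larger".

## Motif discovery

Reference nodes are the SAX transforms of `sin` and `cos` sampled at
`seg_len` equispaced points on [0, π/2], each z-normalized before
discretisation; they are deterministic, and on symmetric sampling the
sine word is the reversed cosine word.

**Pruned neighbour search.** Each segment *i* gets two scalar
projections `S_i = MINDIST(seg_i, r_sin)` and `C_i = MINDIST(seg_i,
r_cos)`. Because MINDIST gives adjacent symbols distance zero it
violates the triangle inequality, so the naive candidate filter
`|S_i − S_j| ≤ ε` can miss true neighbours. The filter therefore uses
`ε + Δ` with the provable slack `Δ = √n · max_k(β_{k+1} − β_k)` (the
widest interior quantile cell): treating symbol cells as intervals on
the line, `|d(A,R) − d(B,R)| ≤ d(A,B) + min(diam A, diam B)`, and
positions pairing the two opposite extreme symbols — where both diameters
are infinite — are impossible in any pair within ε, provided ε is below
the MINDIST floor of such a pair; if ε exceeds that floor the filter is
disabled outright. Pairs passing both axis filters get an exact MINDIST
evaluation; pairs within ε are merged by single linkage (union-find).
The result is *identical* to brute-force all-pairs grouping — the
pruning only saves evaluations (counted and exposed for inspection).
Groups are ranked by size, ties by smaller mean intra-group distance;
the representative is the group medoid. For groups beyond 400 members
the medoid and mean distance are computed on a deterministic stride
subsample — this affects tie-breaking and the reported representative
only, never membership.

ε defaults to the 5th percentile of pairwise segment distances on a
calibration sample of ≤ 400 segments, computed once per discovery run;
`merge_eps` defaults to the same value.

**Bootstrapping and merging.** Per (SV class, side, genotype)
combination, each bootstrap subset (360 × 960 profiles at study scale;
sampling falls back to with-replacement when the pool is smaller) is
pooled, normalized, clustered at k = 2, scoped by the > 66% dominant-
cluster rule (at exactly 66% both clusters are searched), SAX-segmented
and grouped; the top group's representative becomes a candidate. K-Means
labels carry no identity across subsets, so clusters are canonicalised
by size (0 = larger) before merging. Candidates are merged
agglomeratively — while the closest pair of family representatives is
within `merge_eps`, merge it; the merged word is the per-position
support-weighted mean of symbol indices rounded half-to-even (alphabet-
closed and deterministic). The largest family's representative is the
predominant motif; its support is the family's candidate count. A motif
whose family absorbed < 10% of candidates is flagged unconvincing — the
expected verdict for insertion breakpoints, whose depth distortion is
too superficial to yield a reproducible waveform.

Each motif also records a breakpoint offset: the median, over the top
group's members, of the breakpoint position within the segment (pooled
units). Scan hits use it to convert a segment hit into a predicted
breakpoint coordinate.

## Scanning

Tiled 512 bp windows (configurable stride) are pooled, normalized and
SAX-transformed; every segment offset is scored by MINDIST against each
motif. Scores are invariant to uniform scaling of the raw depth. The
default threshold is motif-specific: the 1st percentile of scores on
motif-free Poisson coverage at 30x. By construction that percentile
admits ~1% of background offsets, so strict applications should tighten
it; on the synthetic fixtures true hits score ~1 against a background
≥ 10, leaving a wide margin. Overlapping same-motif hits collapse to the
minimum-score one.

## Synthetic data

The generator emulates ~30x short-read coverage: Poisson noise around a
flat rate (negative-binomial overdispersion behind a flag), with planted
events scaling the rate by genotype-dependent copy factors — DEL and
CNV-loss 0 (hom) / 0.5 (het), DUP and CNV-gain 2 / 1.5. Inversions keep
copy number 1 and receive a synthetic breakpoint dip (linear ramp to
0.5× over a 50 bp shoulder) standing in for alignment edge artifacts;
insertions keep 1× with a 20 bp half-depth dip at the breakpoint. The
planted-motif generator embeds a `seg_len`-point template (expanded ×8)
at the centre of a 512 bp profile, continuing the template's edge levels
outward, with Gaussian noise and optional shift/stretch jitter emulating
imprecise and elastically deformed breakpoints.

Not modelled: GC bias, mappability dropouts, read-level artifacts,
caller-specific breakpoint error distributions. Passing tests therefore
demonstrate the machinery recovers structure it can represent, not that
real HGDP-like data would yield the same motifs.

## Problem sizes

The package defaults carry the study-scale constants (360 × 960
bootstrap, 80 consistency repeats on subsets of 100, 10 K-Means
restarts). The test suite and worked examples run the same code at
desk scale as the package's own validation protocol: 6–12 bootstrap
subsets of 64–120 profiles over pools of 84–300, 8 consistency repeats
on subsets of 30, 2–3 K-Means restarts, and 100 randomized segment sets
of 30–200 segments for the pruning-equivalence property.

## Known limitations

* The DBA barycenter is a local optimiser; different seeds can yield
  different (equally valid) partitions on weakly separated data — the
  consistency experiment quantifies exactly this sensitivity.
* spSV windows are midpoint-anchored by convention; left-anchored
  windows would shift spSV motifs by up to half a window.
* The pruning slack is conservative (worst case over symbol
  configurations); on tightly clustered segment sets it may admit most
  pairs, degrading to near-brute-force cost while remaining exact.
* Motif `support` counts bootstrap subsets, not profiles; pools smaller
  than `bootstrap_size` are resampled with replacement, which inflates
  the effective weight of duplicated profiles.
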