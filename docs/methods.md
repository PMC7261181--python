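# Methods

## Generative model

**Replication.** Each nuclear chromosome starts as one unlabeled duplex per
cell. A labeling schedule is an ordered list of cell-cycle phases; each
phase replicates a region and splits every duplex semiconservatively into
two daughters, each keeping one parental strand, with the nascent strand
marked as BrdU-labeled over exactly the replicated region when BrdU is
present. For a complete phase the region is the whole chromosome; for the
final phase sampled at time *t* (minutes into S), the region is
{*x* : min<sub>o</sub>(*t*<sub>fire</sub>(*o*) + |*x* − pos(*o*)|/*v*) ≤ *t*}
for fork speed *v* — deterministic origin firing, bidirectional constant-speed
forks, no stochastic firing or fork stalling. Coordinates are 0-based
half-open; the replicated interval's exclusive end is the first
unreplicated base. An "asynchronous" final phase draws each cell's sampling
time uniformly over the S-phase duration.

This one-duplex-into-two rule applied to a *partial* region represents the
two arms of a replication bubble as separate molecules; the unreplicated
portion of a splitting duplex is carried as two single-parental-strand
molecules rather than one intact duplex. The approximation is exact for the
fragmentation read-out whenever the parental duplex is not itself
double-labeled mid-S — which holds in all packaged scenarios: the
fully-labeled control uses only complete cycles, and in the timing course
the parents entering the sampled S-phase carry label on at most one strand.

**Rereplication.** Designated rereplication domains re-fire within the
final phase: each parent duplex contributes one extra copy of each domain
interval, fully labeled on both strands — the net product of replicating an
already-labeled region a second time in label.

**Mitochondria.** The mitochondrial contig replicates continuously
regardless of cell-cycle arrest, so every copy is double-labeled in any
BrdU-containing schedule. It is emitted as `mito_copies` (default 50)
fully double-labeled molecules per cell and anchors normalization.

**Digest.** Labelable sites are Bernoulli per labeled bp at
`labelable_density` (default 0.3, approximating thymidine frequency without
shipping genome sequence); each site nicks with probability `p_nick`
(default 0.03), the single abstraction of UVA dose and digestion time.
Opposed nicks within `dsb_max_offset` (default 16 bp, a conventional
closely-opposed-nick scale) become a double-strand break at their floor
midpoint; nicks pair greedily left to right, each used at most once (a
deterministic, testable rule; alternatives change counts only at very high
nick density). Fragments between consecutive breaks are kept if internal
(both ends are breaks) and within the 100–3000 bp gel window. The defaults
give a mean retained fragment length near 400 bp, inside the 300–600 bp
range targeted for library construction. Single-strand-labeled molecules
can never acquire opposed nicks and yield nothing — the selectivity the
method rests on.

**Background.** `background_rate` (default 2×10⁻⁵ fragments/bp/cell) adds
uniformly placed nonspecific fragments independent of labeling, so
time-point-0 samples carry the low-complexity background against which the
blacklist and fold-enrichment measures are defined.

## Normalization chain

Order: fragments-per-million → mitochondrial scaling → binning → blacklist
(built from time-point-0, applied everywhere) → smoothing → replicate
averaging. The blacklist is constructed at bin resolution because a
"region of elevated signal" is only well defined on the common bin grid;
bins strictly above the grand mean plus one **population** SD of
non-mitochondrial bins (per-bin mean across T0 replicates) are excluded as
missing, never zero, so window means and averages are not dragged down at
blacklist edges. Mitochondrial bins are the normalizer and are never
blacklisted nor counted in the threshold. Mitochondrial scaling multiplies
each sample by (mean mito fraction)/(its mito fraction); since a global
per-sample factor cannot change a within-sample fraction, the quantity this
equalizes is the mitochondrial signal mass of depth-normalized samples —
the operational meaning of "same amount of mitochondrial control in every
sample". Replicate agreement is scored by Spearman rank correlation over
jointly non-missing bins.

Binning is the length-weighted mean per-bp signal (a density, invariant
under re-binning; mass is conserved exactly, including the truncated last
bin). Smoothing is a centered moving average over a window coerced up to an
odd number of bins; bins within half a window of a chromosome end are
passed through unsmoothed (downstream heatmaps still need values there),
missing bins are excluded from window means, and a missing bin stays
missing.

## Timing-domain analysis

Timing profiles use the published 0–2 scale (2 = replicated, 1 = not).
Early/late regions are maximal runs of bins at/above the 75th or at/below
the 25th percentile (linear-interpolation percentiles pooled over
chromosomes; inclusive thresholds). ERD/LRD domains extend to the midpoint
of each adjoining transition zone so TZ signal is counted once; a boundary
with no adjoining TZ keeps its coordinate. Scaled profiles resample each
extended domain to 101 relative positions (0–100 %) by linear interpolation
at bin centers. Domain "average signal" is the mean of non-missing bins
over the domain.

The enrichment statistic is the classic unweighted running sum: walking the
signal-ranked domain list, query members add 1/|query| and others subtract
1/(N−|query|); ES is the maximum-magnitude deviation, with exact magnitude
ties resolved toward the positive deviation. The p-value is the
add-one-smoothed fraction of label permutations with |ES| at least the
observed value. This deliberately replaces an external enrichment program:
weighting exponent and permutation settings of such programs are not
pinned down here, so exact numeric agreement with them is not claimed.

## Packaged study conditions

The desk-scale genome is two 500 kb chromosomes plus a 10 kb mitochondrial
contig; 20 origins at 50 kb spacing, fork speed 2 kb/min (yeast-like),
firing times a fixed interleaved permutation of a 0–10 min grid, giving a
~22 min S-phase. The timing course pre-labels one strand through a complete
BrdU cycle and samples the second S-phase at 0, 12, 18 min and completion;
12 min is the earliest time at which every origin has fired, so per-origin
signal in ±25 kb windows is strictly ordered by firing time. Three
replicates of 200 cells; 100 bp bins and a 10 kb smoothing window (the
yeast preset; the human preset is 1 kb/100 kb). The fully-labeled control
runs three complete BrdU cycles — sampling it mid-S would itself imprint
replication-timing copy-number structure, which is precisely what the
completed-cycle control must lack. The rereplication scenario re-fires two
100 kb domains (20 % of the nuclear genome), each spanning an early and a
late origin and several 40 kb TAD boundaries, from a G1 arrest.

What the generator does **not** emulate: sequence-dependent labelable-site
placement, GC/mappability bias, PCR duplicates, stochastic origin firing,
fork stalling, diploidy, and realistic chromosome counts. Passing tests
therefore demonstrate the internal consistency and selectivity of the
method's logic, not performance on real libraries.

## Per-origin quantification

Per-origin signal is the mean of non-missing smoothed bins in a ±25 kb
window around the origin, excluding bins within one maximal gel-window
fragment length (3 kb) of a chromosome end: segments abutting a molecule
terminus carry only one break end, are removed by size selection, and
systematically depress coverage there, which would otherwise imprint rank
structure on windows touching chromosome ends. The signal-vs-firing-time
Spearman coefficient is computed per replicate and averaged: correlating
the replicate-averaged track instead leaves a single rank correlation over
20 exchangeable origins, whose null SD (~0.23) would swamp the "no
structure" read-out of the fully-labeled control, while the replicate mean
shrinks that null variance threefold.

## Numerical choices

* All randomness flows through `numpy.random.Generator` seeded per sample
  from a `SeedSequence` of (experiment seed, time-point index, replicate);
  runs are bit-reproducible.
* Distinct nick sites are drawn as uniform integers with duplicate
  resampling (equivalent to per-bp Bernoulli given the binomial count).
* Ranked-list ties break lexicographically by domain id; heatmap row-sum
  ties likewise.
* Degenerate inputs raise named errors: zero-phase schedules, zero
  mitochondrial mass (naming the sample), all-identical timing profiles,
  empty or full query sets, fewer than 3 jointly non-missing bins for
  Spearman QC.
* The greedy nick-pairing inner loop is JIT-compiled when numba is
  available, with an identical pure-Python fallback.

## Known limitations

* `p_nick` is not calibrated to UVA minutes or digestion hours; no
  dose-response data exist to fit, so it is a free dial with a default
  chosen to hit the 300–600 bp fragment-length window.
* Gel extraction is a flat size window; no within-window recovery bias.
* The mid-S representation of partially replicated duplexes (above) slightly
  overcounts copies of unreplicated regions; it does not affect
  fragmentation in the packaged scenarios.
* The control's |Spearman ρ| between origin signal and firing time is pure
  noise on 20 origins (SD ≈ 0.23), so any single draw can exceed 0.2;
  packaged runs use fixed seeds.
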