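# Methods

## Poisson quantification

Each well partitions the reaction into `n` droplets (default 20,000 read;
nominal volume 1 nL, with 0.85 nL available as the common instrument
preset). Under random confinement the number of target molecules per
droplet is Poisson, so the negative fraction estimates `exp(-lambda)` and
`lambda = -ln(n_neg/n)`. Concentration in copies/µL is `1000·lambda /
volume_nL`; every downstream ratio statistic (%L, copy number) cancels the
volume.

The confidence interval on `lambda` is a symmetric normal (delta-method)
interval: with `p = n_neg/n`, `se(lambda) = sqrt((1-p)/(n·p))`, floored at
zero. This is standard digital-PCR practice; a parametric-bootstrap check
in the test suite reproduces the width within 5%, and Monte-Carlo coverage
sits in 93–97% for `lambda` between 0.05 and 1.5 at 20,000 droplets. Wells
with no negative droplets are returned as an explicit *saturated* state
(NaN concentration, flag set) rather than an infinity; wells under 8,000
accepted droplets are flagged by a configurable QC threshold.

## Linkage (%L)

For a duplex well, `gamma = lambda_a + lambda_b - lambda_union` (with
`lambda_union = -ln(p_nn)`) measures the mean occupancy of molecules
bearing both targets; it is exactly the chance correction for
co-encapsulation, since under independence `p_nn = p_aneg·p_bneg` and
`gamma = 0`. Because the four quadrant probabilities have three degrees of
freedom and the three-species loading model has three parameters, this
closed form is also the multinomial maximum-likelihood estimate (verified
numerically in the tests to 1e-6).

`%L = 100·gamma/denominator`. The default denominator is
`max(lambda_a, lambda_b)`: a sample with two copies of the shared gene and
one of the partner can then reach at most %L = 50, which is the quantitative
ceiling the score is designed to respect. Explicit `channel_a` /
`channel_b` modes divide by a named channel instead. Negative point
estimates (sampling noise around zero) are reported as-is, with a
zero-floored convenience field; the interval is a percentile bootstrap over
multinomial resamples of the quadrant counts (2,000 by default, seeded).

Motif calling contrasts an undigested and a digested aliquot of the same
sample: linkage is *abrogated* when the digested score falls to at most
half (configurable) of the undigested one, and a motif is *present* when
the undigested %L exceeds 1.0 (set below the weakest score the method
treats as evidence) **and** abrogation holds. Scores above the presence
threshold but under 5.0 carry a *weak* flag — low-but-abrogatable linkage
can reflect long-range arrangements on unusual extended haplotypes rather
than the canonical adjacent pair.

## Copy number

`raw_cn = 2·lambda_target/lambda_RPP30`; the factor 2 corrects for the
reference's one copy per haplotype. Its interval is a delta-method interval
on the log-ratio treating the channels as independent; the two channels
share droplets, so this is an approximation (documented; the dependence is
weak at typical loads and a multinomial bootstrap can be substituted).

Plates of raw estimates are clustered by a one-dimensional Gaussian
mixture, fitted by EM with quantile initialization (deterministic),
tolerance 1e-8, at most 1,000 iterations; both equal-variance and
free-variance parameterizations are fitted for k = 1…5 and the model with
the lowest BIC wins. Component standard deviations are floored at 0.02
copy-number units: integer copy states sit ~1 apart, so structure finer
than a few hundredths of a copy is measurement noise, and without the floor
the free-variance likelihood rewards spike components on near-tied
replicate values. Sorted component means map to integers by nearest
integer, with collisions pushed upward to keep the mapping strictly
increasing — this tolerates plates whose clusters sit systematically below
the integers (archival DNA often drifts low by ~15%) without scrambling the
ordering.

Each sample takes the integer of its maximum-posterior component (ties
break to the lower integer) and is flagged for review when the posterior
falls below 0.95 or when the sample's own confidence interval excludes the
called integer — the constellation where clustering and single-well
statistics disagree, e.g. a sample binned at zero copies whose interval
sits strictly above zero and likely carries one copy. Flags mark calls for
human inspection; they never silently change a call.

Concordance between two call sets uses Cohen's kappa over the union of
observed categories (unweighted; integers are treated as unordered labels),
with the asymptotic-variance normal interval clamped to [-1, 1]. A table
in which every pair falls in one identical category has expected agreement
1; kappa is undefined and returned as NaN with a degenerate flag.

## Pedigree checks

A family's integer calls are Mendelian-consistent when one split of each
parent's total across two haplotypes (each 0–2 copies for *KIR2DL5*,
configurable per gene) lets every child's total be written as one maternal
plus one paternal haplotype count. The same parental split must explain all
siblings jointly; de novo events are reported as violations, not explained.
Unknown parents quantify over all feasible totals. For inconsistent
families the reported child is the first one left unexplained by the
configuration that explains the most children — with joint constraints no
unique culprit exists, and this is the most useful single pointer.

The *KIR2DS3*/*KIR2DS5* co-segregation rules (both absent ⇒ no *KIR2DL5*;
both present ⇒ at least two copies) hold as near-perfect linkage
disequilibrium in most populations, so violations are emitted as warnings,
not errors.

## Simulator

The generator emulates the physical experiment stage by stage:

- **Genotypes** are assembled from a motif library placing the assayed loci:
  `cB01` carries *KIR2DL2*→*KIR2DL5* 21.8 kb apart (with *KIR2DS3*
  downstream), `tB01` carries *KIR3DS1*→*KIR2DL5* 19.9 kb apart (with
  *KIR2DS5*), `cB02` has *KIR2DL2* only, `cA01`/`tA01` none of the assayed
  loci. The library is an editable structure; centromeric and telomeric
  motifs join with a 40 kb default gap, which only matters for long-range
  cross-motif experiments.
- **Fragmentation** is Poisson random breakage: a pair of loci `d` kb apart
  stays joined with probability `exp(-d/mean_fragment_kb)`, times
  `(1 - p_cut)` for each restriction site between them. The default mean of
  50 kb matches a typical column-based genomic DNA preparation. Each target
  locus contributes exactly one molecule per genome copy — a surviving pair
  is one doubly-marked molecule, a severed pair one single of each kind —
  so molecule counts are conserved by construction. Within a haplotype,
  targets pair greedily by distance, which reproduces the canonical
  adjacent arrangements; a fragment-level model that merges co-resident
  copies of the *same* target into one molecule is deliberately not used,
  so channel occupancies stay proportional to copy number.
- **Confinement** drops each molecule into a uniformly random droplet;
  a droplet is channel-positive when it holds at least one molecule bearing
  that target. Occupancy is not capped at one molecule — positivity by
  occupancy reproduces Poisson statistics exactly. An optional per-channel
  misclassification rate ("rain") exists and defaults to 0.
- **Families** transmit one uniformly chosen haplotype per parent per
  child, emitting copy totals and *KIR2DS3*/*KIR2DS5* presence from the
  motif contents.

Default study conditions: 3,000 diploid genome copies per well (≈20 ng of
human DNA) in 20,000 droplets, giving per-copy occupancies of 0.15 — the
dilute regime the instrument targets. Identical seeds give identical wells.

What the simulator does **not** model: fluorescence amplitudes and gating
(the toolkit consumes quadrant counts), PCR efficiency and dropout,
inter-well pipetting variation, degradation chemistry (the systematic
copy-number underestimation of archival DNA is *tolerated* by the
integer-mapping rule, not generated), and realistic fragment-length
distributions beyond the one-parameter exponential. Passing recovery tests
therefore validate the estimators under idealized partitioning; they do not
certify performance on degraded or inhibited real specimens.

## Numerical and design choices

- EM is deterministic (quantile init), so model selection cannot be
  rescued by restarts; the BIC comparison spans both variance modes instead.
- The per-iteration log-likelihood trace is kept on the fitted model and
  asserted non-decreasing in the tests.
- Bootstrap and simulation seeds are explicit everywhere; CLI outputs embed
  the seed and parameters in a `#` metadata preamble sufficient to re-run.
- Saturated wells raise or flag explicitly at every entry point; no
  infinities propagate.
- The acceptance script uses 50 replicate wells of 20,000 droplets at 3,000
  genomes — enough that the Monte-Carlo error of the mean %L is well under
  0.5 — and derives both conditions from the same genotype object.

## Known limitations

- The %L interval ignores uncertainty in the digestion contrast; abrogation
  is a point-estimate comparison.
- The copy-number interval's channel-independence approximation slightly
  misstates coverage at very high loads.
- Mixture-based integer calling needs several samples per copy state; very
  small plates fall back to wide-posterior flags rather than refusing.
- The Mendelian checker assumes nuclear families and fixed parental
  haplotypes; it does not phase across generations or model genotyping
  error rates.
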