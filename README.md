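# kirlink

Droplet digital PCR (ddPCR) analysis of the Killer-cell Immunoglobulin-like
Receptor (KIR) gene complex: physical linkage between gene pairs for
haplotype-motif resolution, and gene copy-number enumeration against an
invariant reference.

## The problem

KIR haplotypes on chromosome 19q13.4 vary in gene content and structure. A
haplotype is one centromeric motif (cA01, cB01, cB02) joined to one
telomeric motif (tA01, tB01); *KIR2DL5* can sit next to *KIR2DL2* in the
centromeric motif, next to *KIR3DS1* in the telomeric motif, on both, or on
neither — so a diploid individual carries zero to four copies. Standard
genotyping reports presence/absence or total copy number but cannot say
*which* arrangement a sample carries. ddPCR can: molecules are partitioned
into ~20,000 nanoliter droplets, and two targets that remain on one DNA
fragment enter the *same* droplet, producing an excess of double-positive
droplets over the independence expectation.

## The statistics

For one fluorescence channel with `n_neg` negative droplets out of `n`,
Poisson partition statistics give the mean occupancy

```
lambda = -ln(n_neg / n)          concentration = lambda / droplet volume
```

For a duplex well with occupancies `lambda_a`, `lambda_b` and double-negative
fraction `p_nn`, the mean number of molecules carrying **both** targets is

```
gamma = lambda_a + lambda_b + ln(p_nn) = ln( p_nn / (p_a_neg * p_b_neg) )
```

which is zero in expectation when the targets load independently. The
normalized linkage score is `%L = 100 * gamma / max(lambda_a, lambda_b)`;
restriction digestion between the loci must abrogate it, and the
undigested/digested contrast calls the haplotype motif. Copy number uses the
invariant *RPP30* reference (two copies per diploid genome):
`raw_cn = 2 * lambda_target / lambda_RPP30`, with plates of raw estimates
clustered into integer bins by a 1-D Gaussian mixture (EM, model choice by
BIC). Family data are checked for Mendelian segregation of the integer
calls, and agreement with an orthogonal method is summarized by Cohen's
kappa.

A built-in simulator generates the whole experiment — motif-built genotypes,
random-breakage fragmentation with optional restriction cuts, stochastic
confinement into droplets — so every estimator is validated by parameter
recovery.

## Worked example

A diploid with haplotypes `cB01~tA01` and `cA01~tB01` carries two *KIR2DL5*
copies but only one *KIR2DL2* — only half of the larger channel can ever be
linked, so intact DNA should show `%L ≈ 50`:

```python
import numpy as np
from kirlink import (build_genotype, simulate_duplex_well, linked_concentration,
                     percent_linked_ci, INTACT_DNA, FragmentationModel,
                     digestion_cut_sites, call_motif)
from kirlink.simulate import ASSAY_2DL2_2DL5

g = build_genotype("cB01~tA01", "cA01~tB01")
q = simulate_duplex_well(g, ASSAY_2DL2_2DL5, n_genomes=3000, n_droplets=20000,
                         frag=INTACT_DNA, rng_seed=1)
res = linked_concentration(q)
lo, hi = percent_linked_ci(q, seed=1)
print(f"lambda_KIR2DL2 = {res.lambda_a:.4f}  lambda_KIR2DL5 = {res.lambda_b:.4f}")
print(f"linked molecules gamma = {res.gamma:.4f}  (~{res.linked_concentration:.0f} copies/uL)")
print(f"%L = {res.percent_linked:.1f}  (95% CI {lo:.1f} to {hi:.1f})")

frag = FragmentationModel(mean_fragment_kb=np.inf,
                          cut_sites=digestion_cut_sites(g, ASSAY_2DL2_2DL5))
res_d = linked_concentration(simulate_duplex_well(g, ASSAY_2DL2_2DL5, 3000, 20000,
                                                  frag, rng_seed=2))
print(f"after digestion: %L = {res_d.percent_linked:.1f}")
call = call_motif("KIR2DL2~KIR2DL5", res.percent_linked, res_d.percent_linked)
print("motif present:", call.present, " abrogated:", call.abrogated)
```

prints

```
lambda_KIR2DL2 = 0.1490  lambda_KIR2DL5 = 0.2992
linked molecules gamma = 0.1490  (~149 copies/uL)
%L = 49.8  (95% CI 48.4 to 51.1)
after digestion: %L = 0.6
motif present: True  abrogated: True
```

3,000 genome copies in 20,000 droplets load the single *KIR2DL2* at
`lambda = 0.15` and the two *KIR2DL5* copies at `0.30`; every *KIR2DL2*
molecule still carries its neighbouring *KIR2DL5*, so `gamma` equals the
*KIR2DL2* occupancy and `%L` sits at its theoretical maximum of 50. Cutting
between the loci severs every pair and the score collapses to noise around
zero — the signature of a genuine `KIR2DL2~KIR2DL5` motif.

The same machinery runs from the shell:

```
kirlink simulate config.yaml -o droplets.csv --seed 11
kirlink linkage droplets.csv -o linkage.csv --calls motifs.csv --seed 5
kirlink cnv droplets.csv -o cnv.csv
kirlink cluster cnv.csv -o calls.csv
kirlink ped-check families.tsv
```

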