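# tasscat

Analysis of **tandem alternative splice sites (TASS)** — alternative donor
or acceptor splice sites of the same type lying within 30 nt of each other.
Within a TASS cluster the most-supported site is the *major* splice site
(maSS) and the rest are *minor* sites (miSS); the relative usage of a miSS
is

```
phi = r_miSS / (r_miSS + r_maSS)
```

computed from split-read counts (one read end per junction). Most miSS are
thought to arise from splicing noise — the spliceosome failing to
discriminate between nearly identical signals — but a subset is expressed
above noise, regulated between tissues, and conserved in evolution. This
package implements the full statistical chain that separates those layers,
for bulk and single-cell transcriptomics practitioners working from
junction-level count tables. Everything runs on synthetic data shaped like
the real inputs, so the whole pipeline is testable without downloads.

## What it computes

- **Catalogue** (`tasscat.catalog`): merging annotated / expressed /
  cryptic site lists; the ≥3-reads-in-≥2-tissues expression call with a
  1.5-bit junction-entropy filter; removal of polymorphism-driven
  alignment artifacts; 30-nt single-linkage clustering into TASS clusters
  (size ≤ 5); read-support ranking; shift, frame and exonic/intronic
  classification; NMD response `phi_KD − phi_C`; Ribo-Seq support
  `RS = reads_miSS / (reads_miSS + reads_maSS)`; PWM log-odds site
  strength.
- **Significance** (`tasscat.zipsig`): per tissue, `r_miSS` is
  zero-inflated Poisson with `lambda = a0·r_maSS^a1` and
  `pi = logit⁻¹(b0 + b1·r_maSS)`; each count gets the upper-tail
  probability `P = 1 − (CDF_Poisson(r; lambda)(1−pi) + pi)`, Storey
  q-values over the miSS × tissue matrix, and a significance call at
  q < 0.05 with phi > 0.05.
- **Tissue specificity** (`tasscat.tissue`): per-tissue no-intercept
  regressions `r_miSS = a0·r_maSS + a_t·D_t·r_maSS`; the deviation
  `dphi_t = a_t / ((1+a0+a_t)(1+a0))`, identically `phi_t − phi_bar`;
  calls at q < 0.05 and |dphi_t| > 0.05; profile similarity across cell
  types and tissues of origin.
- **Regulation** (`tasscat.rbp`): miSS–RBP–tissue triples joining
  knockdown responses, RBP differential expression and tissue-specific
  miSS; co-directed iff the three delta signs multiply to −1; exact
  binomial excess test; eCLIP peak support within ±20 nt; overexpression
  vs knockdown contrasts split at |shift| < 5.
- **Selection** (`tasscat.evolution`): consensus (Cn) / non-consensus
  (Nc) classification from a constitutive-site PWM; parsimony ancestors
  over human/marmoset/galago; observed-over-expected (O/E) substitution
  ratios with score confidence intervals for a ratio of two binomial
  proportions; strength-matched control sampling; the bootstrap mixture
  model for the noisy-site fraction alpha; SNP max allele frequencies in
  site windows.
- **Synthetic data** (`tasscat.simulate`): seeded generators for every
  stage's inputs with truth tables.

## Worked example

```
$ python examples/02_zip_significance.py
fitted ZIP (true a0=0.05 a1=0.9 b0=-1.0 b1=0.0005):
  a0=0.0376  a1=1.0001  b0=-0.9992  b1=0.000270  converged=True

108 of 5000 miSS called significant (q < 0.05 and phi > 0.05); 99 of the 100 boosted ones
a significant miSS is expressed above the noise level predicted from its maSS read support alone.
miss_id  r_miss  r_mass      phi   p   q
   m148      59     232 0.202749 0.0 0.0
   m292      55     232 0.191638 0.0 0.0
   m456      67     230 0.225589 0.0 0.0
```

5,000 miSS/maSS count pairs are simulated from the conditional ZIP law,
100 of them boosted above it. The fit (on the contaminated data) still
tracks the generating parameters, and the significance call recovers 99
of the 100 boosted sites at a false-positive rate of ~0.2%. `phi ≈ 0.2`
means one in five split reads at the cluster chooses the minor site.

The other scripts in `examples/` walk through catalogue construction
(`01`), tissue-specific calls (`03`), regulatory triples with eCLIP
support (`04`), and the O/E selection statistic with the alpha mixture
model (`05`), each printing a short narrative of what its numbers mean.

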