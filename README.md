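# peptriact

Analysis toolkit for optimising enzymatic protein hydrolysis and screening
the resulting peptides for bioactivity. It covers the full computational
chain of a typical food-protein peptide study:

* **Assay statistics** — degree of hydrolysis (DH) by the pH-stat method
  (with the temperature-dependent α-amino pKa and dissociation degree),
  alcohol-dehydrogenase (ADH) activation from initial rates fitted to
  A340 progress curves, xanthine-oxidase (XOD) inhibition from a
  four-cuvette absorbance scheme, and DPPH radical scavenging with blank
  correction.
* **Response-surface methodology** — 3-factor Box–Behnken design
  construction, coded-unit second-order least-squares fitting, ANOVA with
  partial term sums of squares and a lack-of-fit split from replicated
  centre runs, and multi-response Derringer–Suich desirability
  optimization.
* **Peptide screening** — sequence-based average/monoisotopic mass,
  Henderson–Hasselbalch net charge, isoelectric point by bisection, and a
  staged virtual-screening funnel (mass < 1000 Da, ALC > 80 %, peak area
  > 10⁵, external bioactivity/toxicity/solubility predictions).
* **Synthetic data** — seeded generators for kinetic traces, design
  tables and peptide lists with known ground truth, so every stage is
  testable without external data.

A complete published optimization experiment — alkaline-protease
hydrolysis of corn germ meal, a 17-run Box–Behnken design with four
responses plus the three corn peptides that survived its screening
funnel — is bundled as the reference dataset
(`peptriact.datasets.load_corn_design()` / `load_corn_peptides()`).

## The model

Responses are fitted in coded units `x = (actual − center) / ((high −
low)/2)` with the full second-order model

```
Y = β0 + β1 A + β2 B + β3 C + β12 AB + β13 AC + β23 BC + β11 A² + β22 B² + β33 C²
```

by ordinary least squares. Per-term ANOVA sums of squares are partial
(drop-one-term refit), pure error comes from the replicated centre runs,
lack of fit is the residual remainder, and the coefficient of variation
is `100·√(residual MS)/ȳ`. Multi-response optimization maximises the
weighted geometric mean of per-response linear desirabilities over the
coded cube.

Degree of hydrolysis is `DH% = 100·C·V/(a·m·h_tot)` with `a =
10^(pH−pKa)/(1+10^(pH−pKa))` and `pKa(T) = 7.8 + 2400·(298−T)/(298·T)`;
net charge is the Henderson–Hasselbalch sum over the two termini and the
seven ionizable side chains, and the isoelectric point is its unique
root on pH ∈ [0, 14].

## Worked example

Fit and ANOVA of the degree-of-hydrolysis response on the bundled design:

```
$ peptriact rsm fit --response DH
DH = 46.21 + 2.12 A + 7.30 B + 6.25 C + 1.44 AB - 0.44 AC - 1.75 BC + 3.28 A^2 - 7.22 B^2 - 0.47 C^2

$ peptriact rsm anova --response DH
     Source          SS  Df         MS          F       p
      Model 1053.397933   9 117.044215  33.730293 <0.0001
          B  426.028050   1 426.028050 122.774553 <0.0001
        ...
Lack of fit   14.333700   3   4.777900   1.919545  0.2680
R2 = 0.9775  R2_adj = 0.9485  CV = 4.22%
```

The model is highly significant (F = 33.73) with a non-significant lack
of fit (F = 1.92, p = 0.27): the quadratic surface describes the runs
well, hydrolysis time (B) being the dominant linear effect. Peptide
properties from sequence alone:

```
$ peptriact pepstats --sequence QLPSYR --sequence FEGLFR
id,sequence,average_mass,monoisotopic_mass,net_charge,pI
QLPSYR,QLPSYR,762.85,762.4024,0.990,9.53
FEGLFR,FEGLFR,767.87,767.3966,-0.008,6.66
```

QLPSYR carries one net positive charge at pH 7 (the arginine) and an
isoelectric point of 9.53; FEGLFR is neutral (glutamate balancing the
arginine). The screening funnel (`peptriact screen`) retains all three
bundled corn peptides under the default thresholds.

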