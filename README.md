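# avgmodel

General linear models for **exhaustively combinatorial multi-gene phenotype
data**: quantitative traits measured over all 2^n genotypes of an n-gene
system in which every gene carries either its active (wild-type) or inactive
(null mutant) allele.

Such data arise wherever combinatorial knockouts of a gene network are
phenotyped — e.g. bacterial growth (log10 cfu/cm²) in plants mutated in all
16 combinations of four immune-signalling hub genes.  The classical way to
decompose the 2^n genotype means is ANOVA with interaction (the *additive*
model), but its high-order interaction terms become grossly inflated whenever
the phenotypic response is nonlinear (e.g. bounded), because the additive
definition requires the distributive law (A + B):C = A:C + B:C.  `avgmodel`
implements, side by side:

- **additive** — mean(G) = intercept + Σ_{T ⊆ active(G)} coef(T); every term
  enters with weight 1.
- **nr** (network reconstitution) — interaction terms of each order k ≥ 2 are
  averaged within the order (weight 1/C(m,k) in an m-gene genotype); 1-gene
  effects are summed.
- **averaging** — the averaging principle applied consistently to *all*
  orders: an order-k term of an m-gene genotype enters with weight 1/C(m,k).
  Equivalently every coefficient is the genotype's deviation from the average
  of the genotypes with one gene fewer, e.g.

  ```
  A;B;C = ABC − (AB + AC + BC) / 3
        = {(ABC − AB) + (ABC − AC) + (ABC − BC)} / 3
  ```

  — the *mean effect of adding the last gene*, defined purely from observed
  values, hence stable even for high orders and nonlinear systems.

All three are general linear models referenced to the **most disrupted**
(all-mutant) genotype, which is what makes wild-type allele effects
mechanistically interpretable; the conventional mutant-allele coding is
available by complement relabelling.  `:` joins additive/NR interaction
labels, `;` joins averaging ones.

## What the package provides

- genotype/term algebra over the subset lattice, with both genotype-string
  dialects (`"ABc"` full, `"AB"` omission, `"-"` all-mutant);
- exact design matrices and triangular solving between 2^n genotype means and
  coefficients for all three families, with independent oracles (Möbius
  inversion; the direct deviation-from-average definition);
- a mechanistic network evaluator and the built-in six-node example network;
- Monte-Carlo stability studies (uniform-random genotype means) and a
  synthetic replicated-data generator with nested random intercepts and
  optional treatment structure;
- statistical fitting in the statsmodels style: `MultiGeneModel(...).fit()`
  → `MultiGeneResults` with estimates, SEs, t-based 95% CIs, Holm-corrected
  p-values, `summary()` and a coefficient/CI plot; ordinary least squares or
  REML-fitted nested random intercepts (`random="replicate/flat/pot"`);
- gene-inclusion screening (BH-corrected background contrasts), bundling of
  an insignificant gene, model reduction (truncating interaction order);
- an `avgmodel` command line (`matrix`, `solve`, `simulate`, `screen`,
  `fit`, `fixtures`) over plain TSV/CSV files.

## Worked example

The built-in six-node network has inputs nA=5, nB=−3, nX=4, nY=2, additive
rules nC = nA + nB + nX and nZ = nC + nY, genes A, B, C tied to nA, nB, nC
(a knocked-out node outputs 0), and phenotype nZ:

```python
>>> import avgmodel as am
>>> means = am.network_means(am.fig1_fixture())
>>> print(means.to_series().to_string())
-       2.0
A       2.0
B       2.0
C       6.0
AB      2.0
AC     11.0
BC      3.0
ABC     8.0
>>> coef = am.solve_means(am.ModelSpec("averaging", means.universe), means)
>>> print(coef.to_series().to_string())
intercept    2.000000
A            0.000000
B            0.000000
C            4.000000
A;B          0.000000
A;C          7.000000
B;C         -1.000000
A;B;C        2.666667
```

The intercept 2 is the triple-mutant (basal) phenotype; C's own activity is
4; A;C = 7 says that adding A or C as the last gene to the other raises the
phenotype by 7 on average (11 − (2+6)/2); A;B;C = 8/3 is the mean effect of
adding the last of the three genes.  Solving the *additive* model on the same
means instead gives intercept 2, C = 4, A:C = 5, B:C = −3 and a zero
three-gene term — a direct readout of this (linear) network's wiring — while
the conventional mutant-allele coding (`am.recode_to_mutant`) yields the much
less interpretable b = 3, c = −6, b:c = −3.

Fitting replicated data works the same way from a long-format table:

```python
res = am.MultiGeneModel(df, genes="JEPS", family="averaging",
                        random="replicate/flat/pot").fit()
print(res.summary())
```

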