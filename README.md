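# workability

Bayesian estimation of genetic parameters for dairy **workability traits** —
milking speed (MS, scored 1–5) and milking temperament (MT, scored 1–3) —
in the style of national dairy-cattle evaluations: a two-trait animal model
fitted by Gibbs sampling of (co)variance components, under either a
pedigree relationship matrix (**BLUP**) or a single-step pedigree+genomic
matrix (**ssGBLUP**).

It is aimed at quantitative geneticists who want a transparent, tested,
pure-Python reference for this model class: every matrix (A, A⁻¹, G, H⁻¹)
is built from first principles, the sampler is a scikit-learn-style
estimator, and a synthetic-population module reproduces the statistical
structure of milk-recording data so the whole pipeline runs without any
proprietary data.

## The model

For traits t = MS, MT recorded once per first-lactation cow,

```
y_t = X b_t + Z a_t + e_t
```

* `b_t` — fixed effects: herd-year-season of calving (HYS; summer = Apr–Sep,
  winter = Oct–Mar), lactation stage (eight 10-day bins over days 21–100),
  and regressions on age at first calving and percent Holstein-Friesian
  genes;
* `a ~ N(0, G0 ⊗ K)` — additive genetic effects, with K the pedigree
  numerator matrix **A** (Henderson's sparse inverse, inbreeding included)
  or the single-step matrix **H** combining A with a VanRaden genomic
  matrix **G** built from SNP dosages of genotyped sires
  (`H⁻¹ = A⁻¹ + [0, 0; 0, Gw⁻¹ − A22⁻¹]`, `Gw = 0.95 G + 0.05 A22`);
* `e ~ N(0, R0 ⊗ I)` — residuals, both traits observed on every cow.

The 2×2 genetic (G0) and residual (R0) covariance matrices get
inverse-Wishart full conditionals; locations (b, a) are drawn jointly by
sampling-by-perturbation through one sparse LDL′ factorization per
transformed trait (the two-trait system is decoupled by the generalized
eigendecomposition of G0⁻¹ against R0⁻¹). From the chain the package
derives, per sample,

```
P0 = G0 + R0,   h²_t = G0[t,t] / P0[t,t],
r_g = G0[1,2] / √(G0[1,1] G0[2,2]),   r_p = P0[1,2] / √(P0[1,1] P0[2,2])
```

and reports posterior means, batch-means Monte Carlo errors, 95% highest
posterior density intervals, and Geweke convergence z-scores.

## Worked example: recovery of known heritabilities

Simulate 300 half-sib families of 15 daughters (unrelated dams) with true
components equal to the pedigree-analysis posterior means
(`G0 = [[0.02588, 0.00055], [0.00055, 0.00462]]`, residual = phenotypic −
genetic, so true h² = 0.120 / 0.080), then re-estimate with the
pedigree-mode sampler:

```python
from workability.recovery import run_recovery_experiment

result = run_recovery_experiment(seed=1)
print(f"h2_MS = {result['h2_MS']:.3f}  (true {result['true_h2_MS']:.3f})")
print(f"h2_MT = {result['h2_MT']:.3f}  (true {result['true_h2_MT']:.3f})")
print(f"cows = {result['n_cows']}, kept samples = {result['n_samples']}")
```

prints

```
h2_MS = 0.099  (true 0.120)
h2_MT = 0.054  (true 0.080)
cows = 4500, kept samples = 1600
```

Both posterior means land within the sampling noise of this design (the
realized-h² standard error of a 300×15 half-sib layout is ≈ 0.03 per
trait): the machinery recovers the truth at the precision the data allow.

## Command line

```bash
workability simulate --config cfg.yaml --out-dir data --seed 1
workability prep --in data/phenotypes.csv --out-dir prep --dataset-b
workability estimate --pheno prep/dataset_a.csv --ped data/pedigree.csv \
    --geno data/genotypes.tsv --seed 1 --out est
workability summarize --chain est/chain.csv --out summary
workability run-all --config cfg.yaml --out-dir run --seed 1
```

`run-all` executes both relationship matrices ("pedigree" and
"pedigree+genomic"), writes chains, posterior summaries, a side-by-side
comparison of h², r_g and r_p, the half-sib/HYS size-distribution tables,
per-birth-year descriptive statistics, and a provenance manifest with the
SHA-256 of every artifact.

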