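# hypoflow

A tested, reusable implementation of the computational chain used in
studies of drug cytotoxicity under hypoxia in blast-crisis chronic myeloid
leukaemia (CML) cells:

1. **Flow-cytometry quadrant quantification** — single-cell events
   (FSC, SSC; NAO/2-NBDG on FL1, TMRE on FL2, propidium iodide on FL3) are
   classified into four phenotypes: Q1 dead (PI⁺), Q2 live with high
   mitochondrial membrane potential, Q3 live apoptotic (NAO-dim, oxidized
   cardiolipin), Q4 live with collapsed MMP. The cytotoxic endpoint is the
   fraction affected, *Fa* = Q1 + Q3.
2. **Median-effect dose–response** — the quantal model
   log(*Fa*/*Fu*) = *m*·log *D* − *m*·log *Dm* (with *Fu* = 1 − *Fa*) is fit
   by OLS on the log–logit scale; *Dm* is the median-effect dose (≡ EC50)
   and *m* the sigmoidicity slope, so *D*(i) = *Dm*·(i/(1−i))^(1/m).
3. **Combination index / dose-reduction index** — for a fixed-ratio
   two-drug mixture, CI(i) = Dac(i)/Das(i) + Dbc(i)/Dbs(i) and
   DRIa(i) = Das(i)/Dac(i) (CI < 1 synergism, ≈ 1 additivity, > 1
   antagonism; CI = 1/DRIa + 1/DRIb identically).
4. **Signal-to-noise ranking and gene-set enrichment** — genes ranked by
   S2N = (x̄₁−x̄₂)/(s₁+s₂) between two groups (SDs floored at 0.2·|mean|),
   scored against gene sets with the weighted Kolmogorov–Smirnov running
   sum (ES ∈ [−1, 1]) and gene-set permutation significance.
5. **Metabolic-signature clustering** — patients clustered on a gene
   signature (Euclidean distance, complete linkage), the k-cut
   cross-tabulated against clinical staging (CP/AP/BC) with a chi-square
   test, and per-gene contrast vectors compared by Spearman correlation
   with a Fisher-z confidence interval.

Because raw cytometry and expression data of such studies are rarely
deposited, a **synthetic-data module** generates every input with known
ground truth: four-population log-normal event mixtures whose weights follow
a median-effect curve, negative-binomial count matrices with planted fold
changes, and a three-class patient cohort with a planted signature and a
calibrated inverse correlation between the class contrast and the
environment contrast. Every downstream stage is therefore testable against
planted truth.

The package is a library first: import `hypoflow` from Python, or start from
the narrative scripts in `examples/`. A thin `hypoflow` CLI wraps each stage
for shell use.

## Worked example

`python examples/02_median_effect_synergy.py` simulates dose series for two
drugs (true *Dm* 10 and 100, slope 2) and their 1:1 combination (*Dm* 5),
quantifies 20,000 events per dose, fits each series, and prints:

```
     A: m=2.021  Dm(EC50)=10.08  r=0.99995
     B: m=2.004  Dm(EC50)=100.18  r=0.99999
   A+B: m=1.994  Dm(EC50)=4.97  r=0.99997
 level    CI  DRIa   DRIb interaction
 0.250 0.269 4.087 40.424   synergism
 0.500 0.271 4.056 40.312   synergism
 0.750 0.273 4.027 40.201   synergism
 0.900 0.275 3.997 40.089   synergism
```

The fits recover the planted parameters to within sampling error and the
combination is synergistic across the effect range: at 50% effect the
mixture needs about a quarter of the additive dose (CI50 ≈ 0.27, planted
0.275), with 4-fold and 40-fold dose reductions for the two drugs.

`python examples/04_signature_clustering.py` runs the cohort stage (62 CP /
17 AP / 32 BC patients on a 25-gene signature) and prints the cluster ×
clinical-category contingency table (BC concentrated in one metabolic
group, CP in the other, AP split), its chi-square, and the planted inverse
reprogramming/plasticity correlation (Spearman ρ ≈ −0.41).

## Pipeline runs

`hypoflow run --config run.yaml --outdir out/` executes a config-driven
end-to-end run (simulate → quantify → fit → synergy/enrichment/cohort
stages as requested), writing every artifact with a manifest and a
byte-identical config snapshot; identical configs reproduce identical
outputs. Unknown config keys are rejected rather than ignored.
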