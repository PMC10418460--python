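# ddgbench

Stratified benchmarking of predicted free-energy changes (ΔΔG) of
single amino-acid substitutions on protein stability and binding.

Experimental ΔΔG databases (ProTherm/S2648, SKEMPI-2.0, ProNAB) are
dominated by investigator-chosen mutations — above all alanine
scanning — rather than by the substitutions that single nucleotide
variants (SNVs) can actually produce. A predictor's headline accuracy
on such a database therefore says little about its accuracy on human
missense variants. `ddgbench` gives researchers who develop or apply
ΔΔG predictors the machinery to measure that gap:

- **SNV reachability.** A substitution wt→mut is SNV-reachable iff some
  sense codon of wt can be turned into a sense codon of mut by a single
  nucleotide change (stop codons are never traversed). The package
  computes the full 380-pair lookup from any codon table, and accepts an
  externally curated lookup file instead.
- **Chemical typing.** Substitutions are categorized along four axes —
  hydropathy (hydrophobic/polar), size (small/large), ring
  (aliphatic/aromatic/neither) and charge (positive/negative/neutral) —
  with ordered categories (large–small ≠ small–large).
- **Curation.** The standard funnels that turn raw database exports into
  benchmark sets: exact affinity + temperature, single-point mutations
  only, dimers only, duplicate collapse at SD ≤ 1 kcal/mol, minimum
  partner-chain length, intact −5…+5 residue window at the mutation
  site, nonstandard-residue normalisation. Every step is logged with
  input/output counts.
- **Assessment.** For experimental values *x* and predictions *y*, the
  Pearson correlation r(x, y), the mean squared error
  MSE = ⟨(x − y)²⟩, and the OLS slope of y on x are averaged over 100
  random subsamples of size N = ⌊0.5 · min(|SNV|, |non-SNV|)⌋ drawn
  without replacement (chemical categories use K = ⌊0.5 · |category|⌋
  and are assessed only if they hold ≥ ⌈f · |dataset|⌉ records,
  f = 0.10 by default). Sign conventions differ by dataset kind —
  folding ΔΔG = ΔG_wt − ΔG_mut (stabilizing-positive), binding
  ΔΔG = ΔG_mut − ΔG_wt (destabilizing-positive) — and predictions are
  aligned to the dataset's convention before scoring.
- **Synthetic data.** A seeded generator emulates the statistical
  structure of the real databases (≈50 % SNV composition,
  destabilization enrichment of roughly 8–16:1 at the 2 kcal/mol
  cutoff, duplicated measurements) and pseudo-predictors
  pred = β·ΔΔG + ε with known β and σ, so the whole pipeline can be
  validated against closed-form expectations without downloads.

## Worked example

```python
import ddgbench as d

lookup = d.build_snv_lookup()
print(len(lookup.true_pairs()))          # 150 of 380 ordered pairs
print(lookup.is_snv("V", "A"))           # True  (GTT -> GCT)
print(lookup.is_snv("W", "K"))           # False (needs two base changes)

data = d.generate_dataset(d.SyntheticSpec(n_records=2000, seed=42,
    mixture=d.DdgMixture(destab_weight=1.0, destab_mean=1.0, destab_sd=1.5)))
preds = d.generate_predictions(data.dataset, beta=0.5, sigma=0.8, seed=43)
results = d.assess_snv_vs_nonsnv(data.dataset, preds, lookup,
                                 d.SamplingPlan(n_draws=100, seed=7))
for label, r in results.items():
    print(f"{label:8s} PCC {r.pcc_mean:.3f}±{r.pcc_sd:.3f} "
          f"slope {r.slope_mean:.3f}±{r.slope_sd:.3f}")
```

prints

```
whole    PCC 0.690±0.019 slope 0.498±0.021
SNV      PCC 0.697±0.015 slope 0.500±0.017
non-SNV  PCC 0.692±0.018 slope 0.507±0.018
```

The recovered slope matches the generator's attenuation β = 0.5 (a
predictor with slope ≈ 0.5 underestimates energy changes by a factor of
two), and the PCC matches the closed form
β·σ_true / √(β²σ_true² + σ²) = 0.684 within sampling error.

The same workflow is available from the shell:

```sh
ddgbench snvtable --out lookup.txt
ddgbench simulate --n-records 1000 --beta 0.5 --sigma 0.8 --outdir sim/
ddgbench assess sim/dataset.csv sim/predictions.csv --outdir out/
ddgbench curate skempi-seq export.csv --format skempi2 --outdir curated/
```

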