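# Methods

## SNV reachability model

A missense substitution wt→mut is *single-nucleotide-variant (SNV)
reachable* when some sense codon c of wt and some sense codon c′ of mut
differ at exactly one position. Two modelling choices follow from the
fact that the quantity of interest is missense variation:

- **Stop codons are never traversed.** A path through a nonsense codon
  is not a missense event, so reachability is defined over sense→sense
  single-base changes only. Reassigning a stop codon to an amino acid
  (as in variant genetic codes) can therefore only add reachable pairs,
  never remove them — a property the test suite checks exhaustively.
- **Coding-strand DNA alphabet {A, C, G, T}.** Strand is irrelevant
  because codons are defined on the coding strand.

Under the standard code, 150 of the 380 ordered missense pairs are
reachable, and the relation is symmetric (a single-base change is
invertible). The lookup computed this way is a statement about the
genetic code, not about any published supplementary table; published
SNV classifications of database mutations do not always coincide with
pure codon reachability (for example, Leu→Ala is sometimes described as
an SNV although every Leu codon differs from every Ala codon at two
positions, while Ile→Val and Ala→Gly are single-base reachable yet
sometimes listed as non-SNVs). For this reason every assessment accepts
a user-supplied lookup file; the computed table is only the default.

## Chemical typing

The literature that motivates category-stratified benchmarking rarely
states class memberships explicitly, so the default scheme is a
documented choice (a Taylor-style taxonomy), overridable via a YAML
scheme file validated for coverage and exclusivity:

- hydropathy: hydrophobic {A,C,F,I,L,M,V,W,Y}, polar
  {D,E,G,H,K,N,P,Q,R,S,T}. Proline is placed polar, consistent with its
  negative Kyte–Doolittle hydropathy; schemes differ on P, G, H and Y,
  which is precisely why the scheme is pluggable.
- size: small {A,C,D,G,N,P,S,T,V}, large (complement).
- ring: aliphatic {A,G,I,L,P,V}, aromatic {F,H,W,Y}, neither (rest).
- charge: positive {H,K,R}, negative {D,E}, neutral (rest).

Categories are ordered pairs — large–small is a different stratum from
small–large — because the direction of a substitution (e.g. cavity
creation versus steric clash) matters energetically.

## Sign conventions and classification

Folding: ΔΔG = ΔG_wt − ΔG_mut, positive stabilizes. Binding
(protein–protein and protein–DNA): ΔΔG = ΔG_mut − ΔG_wt, positive
weakens the interaction. Affinities convert via ΔG = RT ln Kd with
R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹, so
ΔΔG_binding = RT ln(Kd_mut/Kd_wt).

Stabilizing/destabilizing counting applies the cutoff strictly
(|ΔΔG| must *exceed* 1 or 2 kcal/mol; ties are neutral). Whether the
boundary is open or closed is unstated in the sources this mirrors; the
strict reading was chosen and applied consistently, and changes nothing
for continuous data.

## Curation pipelines

- Exact-affinity filter: a Kd survives parsing only if it is a plain
  number — inequality or approximate values (">1e-4", "~2e-6") are
  treated as missing and purged together with records lacking a numeric
  temperature. A temperature with an annotation ("298(assumed)") counts
  as present; only a field with no numeric token at all is missing.
- Dimer rule: exactly one chain in each of the two partner groups of
  the complex identifier. Records without chain-group information are
  dropped.
- Duplicate collapse: replicate measurements of the same
  (complex, chain, position, wt, mut) group are purged wholesale when
  their ΔΔG standard deviation exceeds 1 kcal/mol, otherwise replaced
  by a single record at the group mean. The *sample* (n−1) estimator is
  used (configurable); for the canonical {0.0, 3.0} example either
  estimator purges. The operation is idempotent and order-insensitive
  (output sorted by record id). ΔΔG values are averaged directly even
  when replicate temperatures differ.
- Chain length: every partner chain needs ≥ 20 residues, measured from
  SEQRES when available, else from resolved residues; a chain of
  exactly 20 is kept.
- Residue window: the mutation site and all author-numbered positions
  within ±5 must be present with coordinates. Positions beyond the
  chain's numbering range are not required, so windows truncate at the
  termini rather than failing.
- Nonstandard residues: common analogs are renamed to their parents
  (MSE→MET, SEP→SER, TPO→THR, PTR→TYR, …); structures containing the
  purge-list chemical ids {CGU, LLP} are excluded entirely.
- Protein–DNA pipeline: single-point → DNA only (RNA/hybrid excluded)
  → PDB id required → duplicate collapse → the mutated residue must
  exist in the structure with coordinates and match the listed
  wild-type amino acid.

Pipeline correctness is asserted on engineered fixtures with known
counts, not on live database releases, which grow over time.

## Subsampling assessment

Metrics per draw: Pearson product-moment correlation, mean squared
error, and the OLS slope of predicted on experimental ΔΔG with
intercept (slope < 1 ⇒ systematic underestimation of energy changes).
The protocol:

- SNV contrast: one shared subsample size
  N = ⌊0.5 · min(|SNV|, |non-SNV|)⌋ for the whole dataset and both
  strata; 100 draws without replacement per stratum; report across-draw
  mean ± sample SD. (With strata of 1493 and 1154 this gives N = 577;
  floor is the only rounding consistent with the documented gate sizes
  below.)
- Category contrast: a category qualifies if its size reaches
  ⌈f · |dataset|⌉ — f = 0.10 by default (265 of 2648), f = 0.50 for
  small protein–DNA sets (210 of 419) — and is then subsampled at
  K = ⌊0.5 · |category|⌋.
- A single master seed spawns independent per-stratum substreams
  (numpy `SeedSequence.spawn`), so strata are comparable across runs
  and results are bitwise reproducible.
- Records lacking a prediction abort the assessment with the missing
  ids; silent dropping would bias strata differently.
- Predictions are first expressed in the dataset's native sign
  convention; an undeclared convention is an error, never guessed.

## Synthetic data generator

The generator defines the study conditions for all closed-loop tests:

- ΔΔG magnitudes are drawn from a two-component Gaussian mixture in the
  destabilizing direction — a destabilization-shifted component
  N(1.6, 2.0²) with weight 0.7 plus a near-neutral component
  N(0.2, 0.6²) — then signed per dataset kind. This is the simplest
  shape producing the right-skewed, destabilization-enriched
  distributions of the experimental databases; the defaults give a
  destabilizing:stabilizing ratio of ≈ 12:1 at the 2 kcal/mol cutoff
  (inside the empirical 8–16 band) and ≈ 6:1 at 1 kcal/mol, slightly
  below the empirical 7.7–13.7 band — a limitation of the two-component
  shape accepted in favour of simplicity.
- SNV-stratum substitutions are drawn by picking a random sense codon
  and a random missense single-base neighbor (reachable by
  construction, with codon-multiplicity weighting as a side effect);
  non-SNV substitutions are sampled uniformly from the lookup's false
  pairs. The target SNV fraction defaults to 0.5.
- Pseudo-predictors are pred = β·ΔΔG_true + ε, ε ~ N(0, σ²), with
  per-stratum (β, σ) overrides. Closed forms used as oracles:
  slope = β and PCC = β·σ_true/√(β²σ_true² + σ²).
- Duplicated measurements (configurable rate, replicate noise SD
  0.3 kcal/mol) exercise the SD collapse; ground truth (stratum and
  pre-noise ΔΔG) is emitted alongside so tests never re-derive it from
  outputs.
- Structure fixtures are minimal CA-only PDB files with configurable
  chain lengths, numbering gaps and nonstandard-residue insertions —
  enough to drive the window, chain-length and analog checks, with no
  pretense of geometric realism.

What passing closed-loop tests shows — and does not. The generator
reproduces the statistical structure the assessment machinery assumes
(stratum composition, skewed ΔΔG, attenuated noisy predictors); it does
not model real predictors' structured errors (shared training data,
alanine bias, homology leakage), so recovery of (β, σ) here validates
the *evaluation machinery*, not any claim about real predictors.

## Problem sizes and numerics

Closed-loop checks run at pool size 2000 with 100 draws of 500 (whole
pool) or N = ⌊0.5·min strata⌋, chosen so the standard error of the
recovered slope, σ/(σ_true√n) ≈ 0.012, makes the 3-SE acceptance band
tight while the full suite stays fast. Tallies of mixture ratios use
10 000 draws. Metrics are computed in plain double precision from
centered sums; the Pearson denominator uses the standard
product-moment form. Degenerate inputs (zero variance, strata below the
minimum subsample size of 3, empty strata) raise explicit errors rather
than returning NaN.

## Known limitations

- ProNAB/SKEMPI replication is fixture-based; live exports differ by
  release and the published funnel counts are not asserted.
- The dimer criterion (one chain per partner group in the complex
  identifier) is a documented reading; biological-assembly-based
  definitions would classify some complexes differently.
- The default chemical scheme is one defensible taxonomy among several;
  conclusions about category-stratified performance depend on it, which
  is why it is overridable and serialized with every run manifest.
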