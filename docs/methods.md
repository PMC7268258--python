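# Methods

This note documents the models implemented in `catchn`, their assumptions,
the defaults, and the known limitations. It states nothing the tests or
`scripts/acceptance.py` do not themselves compute.

## Symbiosis impairment score

**Model.** An in-planta TnSeq screen passes a saturated transposon library
through a severe population bottleneck (plant infection and nodule
recovery). Neutral insertions survive the bottleneck independently with
probability `1/l`; `l` is the *neutral loss rate*, estimated as
`Σn / Σi` over a neutral reference set (all genes, intergenic sites, or a
user-supplied set — the pooled all-gene fallback is biased upward by
whatever truly depleted minority is present, about 10% under the default
synthetic conditions). For each gene the score multiplies two tail
probabilities:

* `p1 = P(X ≤ i)`, `X ~ Poisson(λ = n/l)` — evaluated through the
  regularised incomplete gamma function (`scipy.stats.poisson`), accurate
  to ≤1e-12 against direct series summation over the tested range
  (λ ≤ 50, i ≤ 200).
* `p2 = P(longest run of lost sites ≥ k)` under uniform random retention
  of `i` among the `n` coordinate-ordered sites. Lost sites partition
  into the `i+1` gaps between retained ones — a weak composition of
  `n−i` — and inclusion–exclusion over which gaps contain a run of `k`
  gives an exact expression valid in every regime. The historical
  single-run closed form `(i+1)C(n−k,i)/C(n,i)` (its first term, valid
  for `k > (n−i)/2`), exhaustive enumeration (n ≤ 22) and Monte-Carlo
  sampling are retained as selectable cross-checks. Integer arithmetic is
  exact up to n = 2000; beyond that, log-gamma with compensated summation
  is used (alternating-sum cancellation limits it to ~1e-7 relative,
  ample for a p-value).

**Interpretation note.** A published verbal definition of the composition
count reads "each part does not exceed k", which contradicts the
definition of the probability itself ("a consecutive loss … equals or
exceeding k"); the closed form only matches the latter, so `p2` is
implemented as `P(max run ≥ k)`.

**Calibration caveat.** `score = p1·p2` is a product of two nearly
independent, approximately uniform p-values and is therefore *not* itself
a calibrated p-value: for independent uniforms
`P(U1·U2 ≤ α) = α(1 − ln α)`, i.e. ≈0.20 at α = 0.05. Discreteness and
the binomial underdispersion of `i` make each factor conservative, but
direct simulation of the null (independent retention at the true `l`)
still yields 12–16% of neutral genes below 0.05, worsening with `n`
(0.875/0.854/0.842 above 0.05 at n = 30/100/300). The score is a ranking
statistic, excellent at ordering depleted before neutral genes
(AUROC ≈ 0.997 under the default synthetic screen) but anti-conservative
as an absolute threshold; treat `alpha` as a tunable cut, not a false
positive rate, or apply the Benjamini–Hochberg option and validate hits.

**Essentiality calls.** A CDS is essential when its insertion density is
below 1/6 of the genome-wide average *and* it has a single insertion-free
gap > 60% of its length or two internal gaps jointly > 80%; below 1/4 of
the average without a gap hit it is a fitness gene. The density factors
are configurable because the thresholds admit a literal multiplicative
reading (6× and 4×) that would be nearly vacuous for essential genes;
the reduced-density reading is the default. Boundary gaps are eligible
for the single-gap rule; a site occupies one base, so the gap between
sites at p and q is `q−p−1` bp. Genes shorter than 100 bp are flagged
low-confidence but still classified.

## Synthetic-data generator

The generator emulates the screen the statistics were designed for, at
desk scale: a multi-replicon annotated genome (default three replicons,
660 CDS of 300–1500 bp placed disjointly), a saturated input library
(0.11 sites/bp, independent per-base Bernoulli, strand recorded but
statistically ignored, geometric read counts with mean 10), and an output
library produced by independent per-site retention at `1/l` (`l = 6.84`)
for neutral sites and `1/(l·f)` for a 10% minority of genes depleted
`f = 20`-fold. With `contiguity_weight` (default 1) the losses inside a
depleted gene are taken as one contiguous run whose length is binomially
matched to the marginal loss probability and whose start is uniform —
the run statistic `k` presumes biologically contiguous depletion but no
generative model is established, so the simplest one is used. A single
integer seed drives all draws through derived `numpy` SeedSequences;
identical config + seed gives byte-identical files.

What the generator does **not** emulate: per-plant multinomial structure
of the bottleneck (losses in real screens are correlated within plants),
read-count noise affecting site detection, insertion hot/cold spots, and
operon polarity. Passing tests therefore demonstrate correctness of the
statistics under the independence null, not robustness to those real-data
features.

## Bioenergetic accounting

Per N2 reduced: 8 low-potential electrons and 16 ATP at the nitrogenase
(2 ATP per flavodoxin hydroquinone). Each catabolic NADH is bifurcated —
one electron to flavodoxin, one to the quinone pool; each electron passing
quinol → oxygen translocates 3 H+; direct quinol (succinate
dehydrogenase) contributes both electrons. Oxidase electron flux is
`nadh_bifurcated + 2·qh2 + extra`, O2 consumed is that /4 (reported
negative), and

```
atp_net = (3·e_oxidase + h_enzymatic) / (10/3) + substrate_level_atp − 16
```

All arithmetic is exact rational (`fractions.Fraction`); the H+/ATP ratio
is stored as 10/3 (using the printed 3.33 would give 2.82 instead of 2.80
for CATCH-N1), and rounding (two decimals, half-up) happens only at
report time. Two fixture fields are back-solved rather than copied:
`substrate_level_atp` (2 for the CATCH-N cycles, 1.6 for TCA) from the
published summary rows under the identity above, and
`extra_electrons_to_oxidase` for the malate-fed CATCH-N cycles (the
printed quinol column alone does not close the electron balance implied
by the bracketed translocation terms; the bracket-derived flux is taken
as authoritative). The succinate-fed TCA row cannot be reconciled with
these rules at all (the model yields +0.24 ATP and −3.63 O2 against
printed 0.12 and −3.6); its fixture ships flagged `non_reconciled` and is
excluded from exact checks.

Nitrogen bookkeeping is per arginine: 4 organic N in, plus the cycle's
fixation share (1 N per arginine when 8 bifurcated electrons serve 2
arginines); each of the two transamination events per arginine secretes
one N as alanine (or aspartate) and the conservation remainder leaves as
ammonium — 2 + 3 = 5 N per arginine, +25% over the classical 4-N route.
The summary table's product column lists net cycle products (2 alanine
per 2 arginine); the per-arginine amino-acid count is carried separately
(`transaminations_per_arginine`) because the transamination network turns
over two pyruvates per arginine.

## Reaction network

Twelve core metabolites, 17 irreversible edges, each edge classed
(aminotransferase / decarboxylase / ureohydrolase / dehydrogenase, plus
optional deiminase, urease and classical ORN→PRO→GLU branches) with the
class fixing its co-species: pyruvate→alanine, +CO2, +urea, NAD+→NADH,
+NH4. Carbon and nitrogen balance is validated per edge including
co-species; the drawn network is reconstructed from the published arrow
key and enzyme-profiling text and shipped as data, easily amended. Every
directed arginine→succinate path has exactly 6 steps and exactly 2
aminotransferase edges (hence net pyruvate consumption 2).

Kinetics are mass-action with order-of-magnitude defaults — no rate
constants are established for the reconstituted system, so all assertions
are structural or ordinal, never fitted. First-order steps default to
0.5/min; aminotransferases are bimolecular at 0.025/(mM·min) so their
pseudo-first-order rate at the assay's 20 mM pyruvate matches the other
steps (without this the transaminase branch outruns everything and the
intermediate tiers collapse). NAD+ is clamped (2 mM excess in the assay).
Integration is `solve_ivp`/LSODA at rtol 1e-8; concentrations are clipped
to zero only in the returned table; total carbon is conserved to ~1e-10
relative. Redundant isozymes (e.g. the three 4-aminobutyraldehyde
dehydrogenases) collapse to one edge.

Label propagation duplicates each backbone pool into labeled/unlabeled
species sharing rate constants; transamination keeps the backbone, so the
label moves substrate→product on every edge while the alanine carbon
(from unlabeled pyruvate) stays out of the labeled fraction. Sources are
clamped; non-source pools are pre-filled with a small unlabeled amount
(0.05 mM) so dilution along chains is visible. Fractions are reported as
labeled/(labeled+unlabeled) with empty pools reported as 0.

## Problem sizes and defaults

The shipped synthetic screen uses 500 genes over three replicons
(~530 kb, ~58k input sites) — large enough that the neutral loss-rate
estimate converges within 1% and gene-level `n` stays ≥ 20, small enough
to run in seconds; benchmark properties are averaged over 5 seeds. ODE
scenarios run 120–600 simulated minutes at 0.1–2 min resolution.

## Limitations

* The impairment score's absolute calibration (see caveat above).
* The generator's independence assumptions (see above).
* The bioenergetics engine is a stoichiometric ledger, not a
  thermodynamic model: no ΔG for bifurcation, no flux-balance analysis.
* The network's rate constants are placeholders; time courses are
  qualitative.
* The essentiality rules reproduce a classification procedure, not any
  specific organism's essential-gene list — that would require the
  original sequencing libraries.
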