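# Methods

## Model and assumptions

Droplet occupancy is modelled as Poisson with mean λ cells per droplet:
cell-droplet formation is assumed random and sparse, so the number of cells
a droplet captures is independent of which cells they are. Each captured
cell is an independent draw from the pooled suspension: sample `i` with
probability `r_i` (`Σ r_i = 1`), and, conditionally, labelled with
probability `a_i`. Under these assumptions the per-(sample, label-status)
cell counts in a droplet are independent Poissons with rates `λ r_i a_i`
and `λ r_i (1 − a_i)` (Poisson thinning), which is both how the closed
forms are derived and how the simulator draws droplets.

A droplet with ≥2 cells is classified by what a demultiplexer could see:
the multiset of detected sample barcodes. Two or more barcode species →
multilabelled (detectable); no barcode → unlabelled multiplet (detectable
as label-negative); exactly one barcode species → stealth, split into
homogeneous (every cell labelled, one sample) and partial (≥1 unlabelled
cell). A deliberate consequence, forced by the derivation of `p_PS` vs
`p_HS`: a droplet holding labelled cells of sample `i` plus an unlabelled
cell *that also originated from sample `i`* is partial stealth, not
homogeneous — classification never sees the unlabelled cell's origin, and
the closed forms only balance under this convention. The simulator records
origin internally but ignores it when classifying.

Model assumptions that real data can violate: cell clumping (non-random
co-encapsulation), very high loading (negative-binomial rather than Poisson
occupancy), and bead dropout all distort the multiplet mass. None of these
are modelled.

## Probability conventions

The closed forms are per droplet, empty droplets included — verifiable
because at `ā = 0` the unlabelled-multiplet probability reduces to the full
multiplet mass `1 − e^{-λ} − λe^{-λ}`. Observable tables, however, count
only cell-droplets, and audits count only monolabelled droplets, so
`MultipletProbabilities` carries an explicit convention tag with
conversions: `per_cell_droplet` divides by `1 − e^{-λ}`, `per_monolabelled`
by the monolabelled mass `P(1)ā + p_HS + p_PS`. Sweep tables additionally
report the four classes as fractions among multiplets (the area-chart
convention). Per-droplet is the canonical storage form; conversions are
defined only from it.

## Numerical choices

* `S − s = Σ(e^{r_i a_i λ} − 1)` is evaluated with `expm1`, and
  `e^{-āλ} − e^{-λ}` as `e^{-λ}·expm1((1−ā)λ)`, avoiding cancellation at
  small λ.
* `1 − ā` is computed directly as `Σ r_i (1 − a_i)`, which is exactly zero
  for perfectly labelled designs (so `p_PS` and `p_Un` are literal zeros
  there, not ~1e-17 round-off).
* Root-finding (Brent) with `xtol = 1e-12`: λ on the bracket `[1e-9, 10]`
  where the multilabelled fraction is monotone increasing, so the root is
  unique; ā on `[0, 1]` with boundary returns (flagged in diagnostics)
  when the observed ratio exceeds what the model can produce.
* Pooling fractions must sum to 1 within 1e-9; design vectors are validated
  at construction.

## Parameters and defaults

| parameter | meaning | typical range | notes |
|---|---|---|---|
| `s` | samples multiplexed | 2–24 | 8 and 7 in the two worked datasets |
| `r_i` | pooling fraction | 1/s ± pipetting error | equal pooling is the default design |
| `a_i` | labelling efficiency | 0.8–1.0 in practice | *apparent* efficiency — the demultiplexer's threshold is part of it |
| `λ` | mean cells/droplet | 0.1–0.8 | instrument loading charts give ~0.3–0.6 at common loadings |

## Estimators

The default ā estimator is the simple ratio
`n_mono / (n_mono + n_unlabelled)`; it reproduces the published 99.5% for
the hashing dataset and is exact as λ → 0, but carries an upward bias of
order `λ(1 − ā)` because stealth multiplets inflate the monolabelled tally
(at `s = 4, ā = 0.9, λ = 0.4` its exact expectation is 0.9057). The
`model_consistent` option removes this bias by solving the full class-ratio
equation; `estimate_parameters` alternates it with the λ solve and
converges in ~6 iterations. λ is always inferred from the per-cell-droplet
multilabelled fraction `p_Mu/(1 − e^{-λ})` — that equation reproduces both
published loading rates (0.369, 0.608) from the published count tables.
No joint likelihood over all class counts is attempted; counts are treated
as exact, and uncertainty is assessed only by Monte-Carlo in the tests.
Estimates are reported to three decimals.

## Simulator

`simulate_pool` draws the thinned Poisson channel matrix per droplet
(distributionally identical to drawing `k ~ Poisson(λ)` then assigning
cells; numpy PCG64, explicit seed, identical tallies per seed).
`degrade_calls` turns a simulated pool into a (truth, degraded) call-table
pair: the truth table shows each droplet's *apparent* call (stealth
multiplets surface as their sample name, with the latent class kept in a
side column), and the degraded table independently unassigns or misassigns
calls at given rates. This emulates the one property of real
demultiplexers the audit needs — imperfect, independent per-droplet calls —
and nothing else: no UMI counts, no ambient contamination, no
transcriptomes, and no correlation between a droplet's content and its
error probability. Passing tests therefore validate the probability model
and audit logic, not any specific demultiplexing algorithm.

## Concordance audit

Five-way classification of droplets called by both of two demultiplexers,
with the reference (`ref`) treated as ground truth and the other (`test`)
under audit: identical sample calls → Singlet; test singlet where ref says
multiplet → Partial stealth; both multiplet → Multiplet; test unassigned →
Unassigned; everything else → Discordant/Others (with a per-subtype
breakdown retained, since "others" mixes sample mismatches and
ref-unlabelled droplets). `partial_stealth / (singlet + partial_stealth)`
is the observable stealth burden among monolabelled droplets; note its
complement is *not* the TSR — homogeneous stealth multiplets are invisible
to any audit of this kind and still hide among the Singlets. Dialect call
tokens (`Doublet`, `Negative`, `A+B`, …) are normalised by the reader via a
user-extensible map.

## Two-Gaussian marker thresholds

Marker-score distributions are modelled as a two-component 1-d Gaussian
mixture fitted by EM (scikit-learn, 10 restarts, tolerance 1e-8); the
lower-mean component is the null. The threshold is the smallest score with
null upper-tail probability ≤ p (default p = 1e-4): analytically
`μ₀ + z₁₋ₚσ₀` in the unadjusted default, or the smallest observed score
whose Benjamini–Yekutieli-adjusted tail probability clears p when
`adjust="BY"`. Both modes are exposed because published pipelines differ in
whether and how they adjust; no claim is made that either matches any
particular R implementation bit-for-bit. Degenerate inputs (all scores
equal, zero-variance null) and EM non-convergence raise with diagnostics.
Droplets above threshold in ≥2 lineages are double-positive multiplets;
those the demultiplexer called monolabelled are partial-stealth candidates.

## Problem sizes

The test suite checks the simulator against the closed forms on 300 random
designs at 1e5 droplets (≥99% of class frequencies within 3 binomial SE)
plus 20 designs at 1e6 droplets (all within 3 SE), and parameter recovery
on one 1e6-droplet pool; these sizes give standard errors well below every
tolerance asserted. The acceptance script's estimates are deterministic
root solves on the published count tables; its only stochastic element is
a 2e5-droplet diagnostic cross-check.

## Known limitations

* Equal pooling is assumed wherever only (`ā`, `s`) are known; unequal
  designs are supported throughout but must be given explicitly.
* The ā ratio estimator is biased upward by stealth multiplets (see above);
  prefer `model_consistent` when λ(1−ā) is not small.
* λ is unidentifiable without multilabelled droplets (`s = 1`, or none
  observed) and the solver refuses observed fractions above the model's
  supremum on the bracket.
* The audit conflates demultiplexer disagreement with true stealth content;
  it is a measurement of the *pair* of call sets, not of either alone.
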