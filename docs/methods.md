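# Methods

## Codon-run statistics

A *maximal lysine run* is a block of consecutive AAA/AAG codons flanked by
non-lysine codons or ORF boundaries. Counting is exact-length: a run of
three lysines contributes one length-3 occurrence and nothing to the
dilysine table. This matches within-length normalization — the observed
fractions of each length then sum to 1 — and treats boundary-truncated runs
as maximal (no boundary information is available from a CDS FASTA alone).

The null model is independence: each lysine codon of a run is an
independent draw at the corpus-wide single-codon usage
p(AAA) = #AAA / (#AAA + #AAG), counted over all in-frame codons with
terminal stop codons excluded (a stop cannot encode lysine). Usage and
expected fractions are kept as exact `fractions.Fraction` values until
display, so enrichment columns are reproducible bit-for-bit; published
tables that print usage at two decimals can disagree with the unrounded
arithmetic by up to ~0.01 in expected fractions and a few percent in
enrichment ratios, and comparisons should carry that slack. When the
expected fraction is zero (degenerate usage) enrichment is reported as
undefined (`None`), not infinity. No multiple-testing machinery is
attached: the quantities are descriptive ratios.

## Sequential incorporation kinetics

The chain M → MK → MK₂ → … → MKₙ with rate constants k₁…kₙ (s⁻¹) is linear
and irreversible with an absorbing terminal species; each kᵢ is an
*observed* per-step aggregate folding together tRNA binding, peptidyl
transfer and translocation. Species fractions use the Bateman closed form.
Its coefficients divide by pairwise rate differences, so whenever two rates
are within 1e-6 relative of each other the evaluation is routed to
uniformization: p(t) = Σₘ Pois(m; Λt) · p₀Pᵐ with Λ the largest rate and
P = I + Q/Λ. All uniformization terms are non-negative (no cancellation)
and the Poisson tail is truncated at Λt + 12√Λt + 35 terms, bounding the
error near 1e-12. The threshold 1e-6 is deliberately wider than where the
closed form first misbehaves; the two routes agree to ~1e-12 at the
crossover. (A matrix-exponential fallback was rejected: on this stiff
non-normal generator scipy's `expm` loses up to ~5e-4 absolute accuracy.)

Fitting is unweighted least squares on fractions with rates
log-parameterized (positivity without constraints), bounded to
[1e-13, 1.6e5] s⁻¹, and a small multi-start (×0.1, ×1, ×10 around a
half-life/peak-time heuristic) per step. The *iterative* fitter mirrors
manual practice: k₁ from the M column alone, each later kᵢ from the
previous species' column with earlier rates frozen (column i depends only
on k₁…kᵢ₊₁). The *global* fitter floats all rates against all columns,
seeded by the iterative result. R² is 1 − SSR/SST per column; a constant
column with zero residual reports R² = 1. Non-convergence returns
`converged=False` with the best estimate rather than raising. Lumping
terminal co-migrating species (e.g. unresolvable MK₄/MK₅ bands) produces an
equivalent shorter chain, so lumped time courses are fitted with the same
code path. Equal or near-equal slow steps (e.g. 5×10⁻⁴ vs 3×10⁻⁴ s⁻¹) are
weakly identifiable from a single time course; the fitters report, and do
not resolve, this. Peptidyl-tRNA drop-off is not modeled: an exit rate per
step degrades fits of chain-like data and is unnecessary for the regimes
simulated here.

## Pause/slide/elongate simulator

State is the A-site codon's 0-based nucleotide index `a`; frame offset is
(a − start) mod 3. Events compete as independent exponentials (Gillespie):

* **ELONGATE** — append the amino acid of the A-site codon (standard
  genetic code), advance 3 nt. Rate k_fast = 12 s⁻¹, except *slow*
  (k_slow_AAA = 5×10⁻⁴, k_slow_AAG = 9×10⁻³ s⁻¹) when the previous
  incorporation was a lysine **and** the in-reading maximal run of
  consecutive lysine codons containing the A-site codon has at least
  `min_lys_run_slow = 4` members. The gate reflects the observation that
  di-lysine contexts do not show the dramatic slowdown measured on
  five-lysine messages, and that 3-codon poly(A) contexts (9–11 A) largely
  complete translation while longer ones pause; it is the single most
  behavior-determining constant in the model and is user-settable.
  `k_next` (default unset) overrides the rate of the first codon beyond a
  qualifying A-run *in any reading* — 0 models withheld downstream tRNA, as
  in lysine-only reconstituted reactions where no out-of-frame codon has a
  decoding tRNA either.
* **SLIDE** — reposition the A-site codon, without peptide-bond formation,
  onto a uniformly chosen alternative all-A placement inside a maximal
  A-run of ≥ `min_A_run = 5` nt, both directions, |d| ≥ 1. Sliding is
  available whenever the A-site **or the P-site** codon touches such a run:
  the paused state observed experimentally has the peptidyl-tRNA on the
  A-stretch with the A-site already on the following (stop or sense) codon,
  and backward sliding from exactly that state is what regenerates lysine
  codons in the A site. Total rate is k_slide_unit × (number of accessible
  placements), so longer runs slide more; k_slide_unit has no measured
  value and defaults to 2×10⁻³ s⁻¹ — slow against elongation and release
  (12 s⁻¹), fast against the slow lysine additions. With this value the
  simulator reproduces, at the default 30-min window: a majority-extended
  peptide population on AUG-AAA-AAA-UAA under lysine-only conditions, its
  collapse when release factors or the downstream tRNA are supplied at
  normal rates, and truncated-product fractions that rise with poly(A)
  insert length (9→10→11→13).
* **TERMINATE** — release at a stop codon in the current reading at
  k_term (0 = no release factors).

The peptide state does not constrain sliding (no codon–anticodon
re-pairing energetics); displacement choice is uniform because no
displacement distribution has been measured. Termination happens only at
stop codons — there is no sense-codon release pathway. A trajectory ends on
release, at t_max = 1800 s (the experimental observation window) as
*stalled*, or — guard only — if the A site runs past the template 3′ end,
which is unreachable on templates with stops in all frames. Classification:
released at the annotated stop in frame 0 → full-length; released anywhere
else or out of frame → truncated/out-of-frame; otherwise stalled. A
trajectory is additionally *extended* if its lysine tally exceeds the
in-frame encoded count (this flag may overlap any category).

Ensembles draw trajectory i from `SeedSequence(seed, spawn_key=(i,))`, so
results are independent of execution order. The exact companion
(`exact_distribution`) enumerates reachable states
(position × last-residue-lysine × capped lysine tally × status), builds the
sparse generator with per-placement slide rates, and integrates
dp/dt = Qp with LSODA at rtol 1e-10 (dense Jacobian below 600 states);
the lysine-tally cap (default 12) only labels states and never alters
dynamics, so capping is exact for category probabilities as long as the
cap exceeds the encoded count.

## Synthetic data

Time courses add band-quantification noise to the exact chain solution:
Gaussian σ = 0.02 per entry with clipping and row renormalization (typical
densitometry spread; the true quantification error structure is unreported,
so this is a stand-in and a Dirichlet alternative with precision 500 is
provided), replicate r using seed substream (r,). Null corpora draw codons
i.i.d.: lysine with p_lysine = 0.044 (a typical genomic lysine codon
frequency), then AAA with p_AAA|lys (default 0.72, the bacterial split),
else uniform over the 59 non-lysine sense codons — internal stops cannot be
drawn, so generated ORFs pass strict validation without rejection
resampling. `inject_run` overwrites non-lysine windows (flanks included) so
exactly the requested number of new maximal runs appears and no existing
run is altered. Reporters are ATG + optional upstream Gly-Ser flank +
insert + downstream flank + in-frame stop; the `mcherry_like` downstream
flank contains, by construction and verified by a scanner at build time, a
stop codon in each shifted frame within a few codons of the insert
(sequence CTAAGTAGACCG: TAA at shift +1, TAG at shift +2, no frame-0 stop).
It is a synthetic stand-in for a real reporter vector — only the property
"out-of-frame stops nearby" is preserved. Non-multiple-of-3 poly(A)
inserts are padded to the codon boundary with non-A bases so the A-run
length is exact and the annotated stop stays in frame.

What the generators do *not* emulate: real genomes' codon-context
correlations and amino-acid composition, gel artifacts, transcription
heterogeneity, ribosome collisions or drop-off. Passing null-recovery tests
therefore shows correctness of the counting and fitting machinery under the
stated models, not that real data obey those models.

## Problem sizes and tolerances

The test suite and the acceptance script use: 100 random rate sets
(1–4 steps, rates 10⁻³·⁵–10¹·³ s⁻¹, a quarter with near-degenerate pairs)
against a Radau ODE oracle at 1e-8; 100 noise seeds × 25 log-spaced time
points for noisy recovery (median relative error, threshold 20%);
10⁴ Gillespie trajectories against the exact chain distribution (3 Monte
Carlo standard errors); 2–3×10³ trajectories per reporter for the sliding
phenotypes; and null corpora of ≥5×10⁴ lysine codons for enrichment
recovery (4-sd binomial bounds). These sizes keep the full run in tens of
seconds while leaving comfortable statistical margins.

## Known limitations

* The slow-step gate is a hard threshold on run length; reality is surely
  graded. The threshold location (4) places the robust-truncation onset
  between 11 and 13 consecutive A, one step later than the sharpest
  published estimate (11).
* k_slide_unit and the uniform displacement law are free modeling choices;
  only their qualitative consequences are constrained.
* The independence null ignores codon-pair and amino-acid-level selection;
  enrichment departures from 1 on real genomes conflate several forces.
* Iterative fitting propagates errors in k₁ into later rates; the global
  fit mitigates but shares the unweighted-least-squares assumption.
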