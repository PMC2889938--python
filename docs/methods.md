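# Methods

## Scope and data model

The package links a signaling cascade to its transcriptional output in
three stages: (i) Network Component Analysis (NCA) reconstructs
transcription-factor activities from time-series expression under a
known TF→gene support; (ii) a mass-action kinetic model simulates
nuclear NF-κB from a candidate IKK input; (iii) Pearson matching of the
two NF-κB profiles selects the IKK input that explains the data.

Expression values are log2 ratios of stimulated over resting signal
(microarray convention).  Internally all logarithms in the
simulation-to-activity mapping are natural; the distinction only moves
a constant factor, which the max-1 normalization removes and the
Pearson score is blind to.  Multi-dose experiments are represented as
one merged matrix whose column blocks are the per-dose time grids
(default {0, 0.5, 2, 4, 6, 12} h × 3 doses = 18 columns).  Missing
values fail validation by default; an `allow_nan` flag plus
`drop_nan_genes` enables explicit gene-wise removal.  Gene and TF
identifiers are matched as exact case-sensitive strings.

Pre-filtering removes target genes whose maximum |log2 ratio| never
reaches a threshold (default 1.0, i.e. two-fold change) together with
their edges, and then TFs left without targets.  The default is a
conventional fold-change cutoff, not an attempt to reproduce any
specific study's significance rule.

## NCA: support-constrained alternating least squares

The model is `E = S A` with `S` zero outside the network support.
Identifiability is tested on the support pattern with the standard
three criteria: (1) generic full column rank K of `S`; (2) for every
TF, deleting its column and regulon rows leaves generic rank K−1;
(3) at least K data columns.  "Generic" rank is computed by filling the
support with standard-normal draws (5 trials, fixed internal seed) and
counting singular values above a scaled-epsilon tolerance; a pattern
passes if any trial reaches the required rank.  The test-suite oracle
recomputes the same criteria in exact rational arithmetic on
integer-filled supports.

The solver alternates `A ← argmin ‖E − S A‖_F` (dense least squares,
columns independent) with per-gene restricted least squares for the
supported entries of each row of `S`; rank-deficient subproblems fall
back to a tiny ridge (λ = 1e−10).  Defaults: relative-residual
tolerance 1e−8, max 1000 iterations, 5 random restarts (standard-normal
initialization of the supported entries, seeded; lowest residual kept).
The per-iteration residual path is recorded and is non-increasing by
construction of the exact subproblem minimizations.

The diagonal scale/sign ambiguity `S A = (S D)(D⁻¹ A)` is resolved by
the positive-peak, max-1 convention: each activity row is sign-flipped
(with its strength column) so its largest-magnitude entry is positive,
then rescaled so its maximum is 1.  The three dose blocks are fitted
jointly with one shared `S` and normalized by a single global row
maximum, so relative activation amplitudes across doses survive
normalization.  Edge signs in network files are carried as annotation
(and used by the generator) but are not enforced as constraints in the
fit.

Influence ranking orders a TF's regulon by |s_ik| descending, ties
broken lexicographically.  Gene–TF correlation reports the Pearson r
between each regulon gene's expression row and the TF's activity row
across all merged columns; a zero-variance row yields NaN with a
warning rather than an exception, since a single flat gene should not
abort a report.

## Kinetic model

The bundled configuration (`src/nfkblink/models/nfkb_ikk.yaml`) is a
two-compartment (cytoplasm/nucleus, volume ratio kv = 3.3) mass-action
module in the Hoffmann/Lipniacki lineage with 24 species and 72
reactions: free NF-κB in both compartments; IκBα/β/ε each as
cytoplasmic protein, nuclear protein and mRNA; IκB·NF-κB complexes in
both compartments; clamped IKK; and IKK·IκB and IKK·IκB·NF-κB
complexes per isoform.  Each isoform carries 23 reactions
(association/dissociation with NF-κB in both compartments, complex
shuttling, IκB shuttling, IKK binding to free and complexed IκB,
IKK-catalyzed IκB destruction from both IKK complexes, constitutive
IκB turnover inside complexes, constitutive transcription, mRNA decay,
translation, free-IκB decay in both compartments); IκBα additionally
has NF-κB-inducible transcription — the negative-feedback loop — and
free NF-κB has nuclear import and export: 3 × 23 + 1 + 2 = 72.

Reaction types are association (2→1), dissociation (1→2), transport
(1→1 across compartments), synthesis (0→1, optionally template-
modulated, e.g. translation driven by mRNA level) and degradation.
Degradation consumes its substrate and may list up to two products:
these are binding partners that survive the destruction of the
degraded moiety (IKK·IκB → IKK; IKK·IκB·NF-κB → IKK + NF-κB;
IκB·NF-κB → NF-κB).  This widening of the degradation arity is what
lets the network destroy IκB inside complexes without violating NF-κB
conservation; the released-partner semantics is stated in the reaction
labels and enforced structurally by the moiety check.

Transport fluxes are expressed per source-compartment volume; the
receiving side is scaled by the volume ratio, so volume-weighted totals
are conserved.  At load time every declared moiety's weight vector is
verified to lie in the left null space of the volume-weighted
stoichiometry (clamped species excluded); the default model declares
the total NF-κB moiety.  IKK is a clamped boundary species: its value
is dictated by the input profile and its derivative forced to zero.

Rate constants are literature-inspired order-of-magnitude values in
1/h and 1/(conc·h) with μM-like arbitrary concentration units; no claim
of a fitted parameterization is made, and all quantitative pipeline
checks are structural (counts, conservation), qualitative (pulse shape,
monotone amplitude response) or self-consistent (the same model is
used forward and inverse).  Total NF-κB is 0.1 units; basal IKK 1e−4;
stimulated IKK peaks around 0.1.  With these values a step or pulse of
IKK releases NF-κB into the nucleus within ~0.5–1 h and IκBα feedback
pulls it back down — the classic rise-and-fall.

Integration uses stiff BDF (scipy `solve_ivp`), segment-by-segment
between input knots so the piecewise-linear input's kinks are exact
boundaries; dense output on ≥ 241 points plus all knots; defaults
rtol 1e−7, atol 1e−10.  Pre-equilibration (default on) integrates at
basal IKK in 200 h chunks until max |dy/dt| < 1e−9.  Small negative
overshoots are clipped at rate evaluation; a final state more negative
than 10·atol aborts with an error.  The nuclear free NF-κB readout is
linearly interpolated from the dense output at the requested grid.

SBML Level 3 export (mass-action kinetic laws, clamped species as
boundary conditions) is provided for interoperability; import is not.

## IKK profiles and the inverse search

Candidate inputs are continuous piecewise-linear curves on the knots
{0, 0.5, 1, 2, 4, 6, 12} h (basal outside).  The 1 h knot is included
even though the expression grid skips it, giving the search resolution
at early times.  The candidate family is a pulse-decay grid: linear
rise from basal to a peak height at a chosen knot, geometric decay by a
chosen fraction at each later knot, optionally plus a second wave
(added height at a late knot, e.g. 6 h).  A free per-knot enumeration
would explode combinatorially; arbitrary profiles remain available by
direct construction.  The default acceptance/example grid is
3 peak times × 3 heights × 3 decays = 27 candidates.

For matching, a simulated concentration series `c_j` becomes a relative
activity `r_j = ln(max(c_j, ε)/max(c_0, ε))` with ε = 1e−6 × total
NF-κB (guarding the log near zero), then both series are scaled to
max 1.  Because the Pearson correlation is invariant under positive
affine maps, the candidate ranking is provably independent of these
normalization conventions (asserted as a test property); the
normalization exists to make the reported series and plots comparable,
not to influence selection.  Ties break toward the smaller IKK time
integral — the most parsimonious stimulus — then candidate order.  The
comparison grid includes t = 0 by default; `drop_t0` reproduces the
variant that correlates only the five post-stimulus points.  An
optional Nelder-Mead refinement of the winner's knot heights is off by
default.

## Synthetic data

The generator emulates a three-dose stimulus-response microarray
layout: 54 genes, 3 TFs, 77 edges, grid {0, 0.5, 2, 4, 6, 12} h,
log2-ratio scale.  Supports are drawn with exact edge count, full gene
coverage, and are resampled until identifiable.  Strengths are
log-normal magnitudes (μ = 0, σ = 0.5 on the ln scale) with Bernoulli
signs (80% activating).  Activities are gamma-shaped pulses
`(t/tp)^α e^{α(1−t/tp)}` (unit peak at tp, smooth rise/decay), with
the NF-κB pulse peaking at 2 h by default and later TFs staggered in
peak time and width; per-dose amplitudes (0.6, 0.8, 1.0) encode a
sub-proportional response to a 100-fold dose range.  Noise is additive
Gaussian, default σ = 0.1 log2 units.  The end-to-end generator
replaces the NF-κB pulse with the simulated, log-transformed,
normalized response to a known IKK profile, closing the loop.

What the generator does **not** emulate: probe-level noise models,
platform/batch effects, mRNA-delay between TF activity and target
transcription, unknown or wrong network edges, and TF activities
outside the planted family.  Passing tests therefore demonstrate the
pipeline's internal consistency and numerical correctness, not
robustness to network misspecification on real arrays.

## Problem sizes and numerical choices

Test and acceptance runs use the 54 × 18 instance with 27-candidate
searches (~10² ODE simulations of the 24-state system over 12 model
hours), chosen to exercise the full pipeline at the study's native
scale.  The noise-monotonicity property is checked on NCA activity
recovery over 3 seeds × 3 noise levels.  Convergence properties are
asserted by tolerance halving (sampled NF-κB changes < 1e−4 relative)
and by refinement against a high-accuracy re-integration.

## Known limitations

- The kinetic parameter set is plausible, not fitted; absolute
  concentrations and timescales should not be read quantitatively.
- No A20 feedback or other extensions beyond the 24-species inventory;
  no stochastic or spatial simulation.
- NCA assumes the support is correct and identifiable; no confidence
  intervals on `S` or `A`.
- The inverse search is a finite grid; profiles between grid points are
  only reachable via the optional local refinement.
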