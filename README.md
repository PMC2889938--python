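# nfkblink

Linking signal-transduction dynamics to genomic responses for the
NF-κB pathway: reconstruct transcription-factor activity from
time-series gene expression, simulate the IKK–IκB–NF-κB signaling
module, and infer the time-varying upstream IKK kinase activity that
explains the observed transcriptional program.

The package is aimed at systems biologists analyzing stimulus-response
time courses (the motivating setting is LPS-stimulated monocytes
profiled at 0, 0.5, 2, 4, 6 and 12 h under three stimulus doses) who
want to connect an expression matrix to the unobserved signaling input
upstream of a transcription factor.

## Method

Three coupled stages:

1. **Reverse engineering (NCA).** Log-ratio expression is modeled as a
   log-linear mixture, `[E] = [S][A]`, where `E` is the I × J matrix of
   log2 expression ratios, `S` (I × K) holds influence strengths `s_ik`
   that are nonzero only where the known regulatory network has a
   TF→gene edge, and `A` (K × J) holds TF activities over time.  With
   an identifiable support pattern (full-rank criteria on the zero
   structure, tested generically), alternating least squares recovers
   `S` and `A` up to a per-TF scale, fixed by normalizing each activity
   row to a positive peak of 1.  Matrices from several doses are merged
   column-wise and fitted jointly with one shared `S`, so the relative
   activation strength across doses is preserved.
2. **Forward engineering (kinetics).** A two-compartment mass-action
   ODE model of the IKK–IκB–NF-κB module (24 species, 72 reactions:
   IκBα/β/ε isoforms, nuclear-cytoplasmic shuttling with volume ratio
   `kv`, NF-κB-inducible IκBα transcription, and a clamped time-varying
   IKK input) maps a candidate IKK activity profile to a nuclear
   free-NF-κB time course.  NF-κB is conserved as a moiety; the resting
   state is obtained by pre-equilibration at basal IKK.
3. **The link.** Candidate IKK inputs are piecewise-linear profiles on
   the knots {0, 0.5, 1, 2, 4, 6, 12} h.  Each candidate's simulated
   nuclear NF-κB is log-transformed relative to its resting value,
   scaled to max 1, and scored by the Pearson correlation against the
   (max-1 normalized) NCA-derived NF-κB activity on the shared grid.
   The best-scoring candidate is the inferred IKK profile; ties break
   toward the smaller IKK time integral.

A synthetic-data generator closes the loop for validation: a known IKK
profile drives the kinetic model, the simulated NF-κB activity
generates a noisy 54-gene / 77-edge / 3-dose expression matrix through
the NCA forward model, and the pipeline must recover both the 2 h
NF-κB activity peak and the 0.5 h IKK peak.

## Worked example

`python examples/03_infer_ikk_profile.py` runs the closed loop:

```
ground-truth IKK: peak 0.1 at 0.5 h
NCA residual on the synthetic bundle: 0.1454
searching 27 candidate IKK profiles (peak time x height x decay grid)
  lps0.01: winner 'peak0.5h_h0.1_d0.3', Pearson r = 0.9971, IKK peak at 0.5 h
  lps0.1: winner 'peak0.5h_h0.1_d0.3', Pearson r = 0.9972, IKK peak at 0.5 h
  lps1: winner 'peak0.5h_h0.1_d0.3', Pearson r = 0.9995, IKK peak at 0.5 h
```

The residual 0.145 is the relative reconstruction error of the NCA fit
and reflects the injected measurement noise (σ = 0.1 log2 units).  For
every dose the matcher selects the candidate whose knot values equal
the ground-truth IKK pulse: the simulated and reconstructed NF-κB
profiles correlate at r ≈ 0.997–0.9995, and the inferred kinase
activity peaks at 0.5 h, as constructed.  Examples 01 and 02
demonstrate the NCA stage (activity peaks, influence-strength ranking,
gene–activity correlations) and the kinetic simulator (pulse response,
moiety conservation, SBML export) separately.

Every stage is also exposed on the command line:

```sh
nfkblink synth nca --out data/
nfkblink nca --expr data/expression.tsv --net data/network.tsv --out fit
nfkblink gen-ikk --spec ikk_grid.yaml --out candidates/
nfkblink simulate --ikk candidates/ikk_0000.tsv --t-end 12 --out traj.tsv
nfkblink link --target fit.A.tsv --candidates candidates/ --out match.json
nfkblink run --config run.yaml     # full pipeline
```

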