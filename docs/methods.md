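# Methods

## The model

`elonsim` simulates translation elongation in an *E. coli*-like reaction
compartment as a stochastic diffusion–collision process.  The only
mobile species are ternary complexes (EFTu·GTP·aminoacyl-tRNA); each of
the `N_EFTu` complexes performs a continuous-time random walk on a
periodic cubic lattice that discretises the reaction volume.  Ribosomes
sit at fixed, uniformly random lattice sites (their diffusion is orders
of magnitude slower and is neglected), each translating its own mRNA
copy of the target coding sequence, starting from a uniformly random
codon.  Initiation and termination are outside the model: a ribosome
that reaches the last codon wraps to the first.

Events are drawn with the Gillespie direct method.  Because every
complex shares one travel propensity and one dissociation rate, the
channel selection factorises into (travel | dissociation) followed by a
uniform choice of molecule and direction — mathematically identical to
scanning the cumulative propensity vector, but O(1) per event.  The
three event types are:

* **Jump.**  A complex moves to one of its six neighbour sites.  If the
  destination holds a ribosome whose current codon is served by the
  complex's tRNA species and whose catalytic idle window has expired,
  the collision reacts instantly: the elongation counter advances, the
  ribosome moves one codon and becomes refractory for
  `t_cat = 1/24 s` (the reciprocal of the 24 aa/s maximum specific
  rate), and the complex is recycled — the delivered tRNA joins the
  free pool, EFTu instantly binds a uniformly chosen free tRNA
  *molecule* (species weighted by free counts) and the new complex is
  placed at a uniformly random site.  If several eligible ribosomes
  share the site, one is chosen uniformly.
* **Dissociation.**  Each complex decays with first-order rate
  `k_diss = 1/s`; recycling is identical to the post-reaction path.
* Waiting times are exponential with rate
  `alpha_0 = N_complex (a_travel + k_diss)`.

Per-species tRNA number (bound + free) is conserved exactly; the
complex count equals `min(N_EFTu, total tRNA)`.  When every tRNA is
complex-bound (possible in extreme ATP-allocation corners) a released
tRNA re-binds immediately, which the implementation realises by adding
the released molecule to the pool before drawing.

## Parameters

| parameter | default | meaning |
|---|---|---|
| D | 2.567e-12 m²/s | ternary-complex diffusion coefficient |
| k_diss | 1 s⁻¹ | complex dissociation rate |
| t_cat | 1/24 s | ribosome refractory time per elongation |
| volume | 0.064 µm³ | reaction compartment (preliminary-study size) |
| h | 10 nm | lattice spacing = effective capture distance |
| ribosomes / EFTu | 1044 / 9122 | counts at growth rate 1.1 h⁻¹ |
| tRNA table | 36 species, Σ = 12 727.8 | per-species counts, same growth rate |
| stop / burn-in | 5000 / 1000 events | run length and discarded transient |

### The jump-propensity convention

Discretising the diffusion equation gives a per-direction jump rate
`d = D/h²` (total `6D/h²`), and with that convention the simulator's
tracer mean-squared displacement is `6Dt` (verified by an oracle test).
The published update rule, however, assigns `D/h²` as the *total* move
propensity and then draws the direction uniformly from six — the same
walk with an effective coefficient `D/6`.  Only the latter reproduces
the reported elongation rates and encounter times; with the
per-direction convention all sequences saturate near the 24 aa/s
catalytic cap and lose codon-usage discrimination.  Both are available
via `KineticParams.jump_convention`; the default is `"published"`.
The MSD oracle pins each convention to its own closed form.

### Grid spacing h

`h` is the collision (capture) distance — physically the sum of the
ribosome and ternary-complex radii, which are not independently fixed
by the published parameter set.  Absolute rates scale roughly with the
capture rate ∝ `D·h/V`, so `h` calibrates the overall time scale:

| h (nm) | native in vivo rate (aa/rib/s) | whole-volume encounter time |
|---|---|---|
| 20 | 20.8 | 46 µs |
| 12.5 | 18.9 | 48 µs |
| 10 | 18.0 | 51 µs |
| 8 | 16.8 | 55 µs |

The default is 10 nm: it places the native-sequence encounter time
inside the reported 50–60 µs band, gives 17–18 aa/rib/s, and keeps an
even number of grid points at 0.064, 0.008 and 1.0 µm³ (40, 20, 100 per
side).  It was fixed once from this table and not revisited; all other
results follow with no further adjustment.

## Estimators

* **Specific elongation rate** — OLS slope of cumulative elongation
  count against event time over events 1001…5000, divided by the total
  ribosome count.  Replicate errors are standard errors over ten
  independently seeded runs.
* **Encounter times** — successive event-time differences after the
  same burn-in (whole-volume waiting times, not per-ribosome).
* **Slope comparison** — z = (b₁−b₂)/√(SE₁²+SE₂²) from the two OLS
  fits over events 1001…3000 each, two-sided Student-t p with
  df = n₁+n₂−4 = 3996.
* **Elasticity / FCC** — central finite differences of ln(rate) against
  ln(concentration), scaling EFTu + total tRNA jointly (elasticity, at
  fixed ribosomes) or ribosomes alone (FCC, on the volume-total flux),
  with ±10% perturbations and SEs propagated from replicate errors.
  The joint substrate scaling treats the ternary-complex pool as one
  entity; an EFTu-only variant exists but is not the default.  The two
  arms share replicate seeds (common random numbers); the propagated SE
  assumes independent arms and is therefore conservative.  The
  elasticity estimate has a replicate sd of ≈0.12 at ten seeds — the
  default for quick analyses — and the reproduction script uses 32
  seeds to bring its standard error to ≈0.07.
* **ATP allocation** — `floor(share × budget / unit cost)` molecules of
  each machine species added to the baseline; added tRNAs split across
  species proportionally to their baseline abundance (largest-remainder
  rounding; a uniform-per-species alternative is available).  The
  response is the volume-total rate normalised to the unaltered
  scenario with identical seeds.

### Relaxation and measurement windows

The initial state (random placement, all ribosomes simultaneously
reactive) relaxes over several `t_cat` periods plus, for poorly adapted
sequences, the free-pool composition time of order seconds.  An
event-count window therefore covers 8× less simulated time in an 8×
larger volume, and scenarios with different volume rates are unequally
relaxed at the same event index.  Consequently:

* Headline rate and encounter-time reproductions use the published
  protocol verbatim (5000 events, burn-in 1000, 0.064 µm³) — these
  printed values are themselves protocol-coupled quantities.  For the
  non-adapted sequence the protocol rate (≈13) exceeds the fully
  relaxed rate (≈10.5); the native sequence is nearly insensitive.
* Physics checks that compare volumes (intensivity of the per-ribosome
  rate) use a fixed simulated-time window, 0.45–0.9 s.
* Control coefficients are estimated in the 0.008 µm³ compartment,
  where the 5000-event window spans ≈2 s and is well relaxed.
* ATP-allocation sweeps also run at 0.008 µm³ with the budget scaled to
  the same ATP concentration (10⁸ per 0.064 µm³ → 1.25×10⁷), using the
  shared time window 0.45–0.9 s for every simplex cell, because
  augmented cells differ several-fold in event rate.  Scans use one
  seed per cell; the ranking of the leading cells is re-checked at full
  volume.

## Synthetic sequences

No coding sequences ship with the parameter tables, so the package
generates them.  `synth_codon_sequence` draws codons i.i.d. from a
mixture: with probability `adaptation` a tRNA species is chosen
proportionally to its abundance and a codon uniformly within that
species; otherwise a codon is chosen uniformly from the 61 sense
codons.  `adaptation = 1` therefore makes codon demand exactly
proportional to supply — the idealisation of a native, codon-optimised
gene — and `adaptation = 0` ignores the pool entirely.

Two frozen stand-ins emulate the study's target genes and are labelled
synthetic throughout: `tufa_like` (394 codons, adaptation 1.0, the
length of EF-Tu) and `gfp_like` (239 codons, adaptation 0.0, the length
of GFP).  What the generator does **not** emulate: real codon
autocorrelation and rare-codon clustering, wobble competition between
isoacceptors, amino-acid composition constraints.  Tests passing on
these stand-ins validate the simulator and estimators, not predictions
for the real tufA/GFP sequences; the rates of a non-adapted stand-in in
particular are sensitive to its sampled rare-codon count.

## tRNA table transcription

The 36-species abundance table was transcribed from a flattened,
ambiguously concatenated rendering of the original; the species naming
follows Dong et al. and the column-major alphabetical order fixes every
split (e.g. "Asn 235.1", "Thr1 21.6", "Tyr1 2378.9").  The transcription
is pinned by tests.  Two species (Thr1 21.6, Ser2 52.8) fall below the
"at least 80 tRNAs in the reaction volume" remark that accompanies the
original table; the coherent transcription was kept and the remark read
as loose prose.  The codon→species map collapses wobble so each sense
codon is served by exactly one bundled species; codons of isoacceptors
absent from the table (Gly1/2, Ile2, Pro2, Val2) are assigned to the
bundled family member.

## Known limitations and deviations

* The in vitro (all pools × 0.05) per-ribosome rate is 16–17% of the
  in vivo rate, vs the published 21.5%.  With rate = 1/(t_cat + W) and
  a diffusion wait `W` scaling at least linearly with dilution, a
  ratio of 21.5% is arithmetically incompatible with the published
  17.3 aa/rib/s in vivo (it would require W ≈ 10 ms, i.e. ≈19 aa/rib/s);
  the model here reproduces the in vivo rate and yields the smaller
  ratio.  The published encounter-time bands (50–60 µs vs 270–360 µs,
  a ×5–6 step) are consistent with diluting only the diffusing
  substrates while the ribosome count stays at its in vivo value, and
  the cell-free encounter scenario here does exactly that.
* The ATP-allocation optimum for the non-adapted stand-in falls at
  ribosome-heavy shares (≈0.875/0/0.125, ≈2.4-fold) rather than the
  published (0.375/0.125/0.5, 1.9-fold); the published split evaluates
  to ≈1.8–1.9-fold here as well, and the ranking is stable between the
  0.008 and 0.064 µm³ volumes and across measurement protocols.  The
  preference is driven by the relatively low ribosome baseline cost
  share; it may also reflect the stand-in's uniform rare-codon usage.
  For the adapted stand-in the published optimum (0.9/0/0.1) is
  recovered exactly, with a larger fold (≈2.0 vs 1.6).
* Ribosome–ribosome interference, initiation/termination kinetics,
  aminoacylation (recharging is instantaneous by construction), mRNA
  secondary structure and excluded volume are all outside the model.
* Event times use IEEE accumulation of ~10⁷–10⁸ exponential increments
  per run; the relative error is ≪ any reported digit.  Runs are
  bit-reproducible for a given seed and platform (one seeded generator
  for initialisation, one for the compiled event loop, both derived
  from the user seed).
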