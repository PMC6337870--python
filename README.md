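# elonsim

Stochastic diffusion–collision simulation of translation elongation in
*Escherichia coli*, with elongation-rate statistics, translational
control analysis, and ATP-cost accounting for the translation machinery.

## The problem

During fast growth, an *E. coli* cell needs more than 170,000 amino
acids per second of protein synthesis.  Every elongation step requires a
ternary complex (EFTu·GTP·aminoacyl-tRNA) to find, by diffusion alone, a
ribosome whose current codon matches its tRNA — and the relevant tRNA
species may be present in only tens of copies per reaction volume.
`elonsim` asks how far diffusion and substrate scarcity limit
elongation, how that limit depends on the codon usage of the translated
gene relative to the tRNA pool, and where a cell (or a cell-free
reaction) should spend ATP — on ribosomes (~108,461 ATP equivalents
each), tRNA (~700) or EFTu (~3,565) — to buy the most translation rate.

It is a library for systems/synthetic biologists: import it from Python
(see `examples/`), or use the thin `elonsim` command-line wrapper.

## The model

Ternary complexes perform a continuous-time random walk on a periodic
cubic lattice (spacing *h*, the capture distance) discretising a
0.064 µm³ compartment; ribosomes sit at fixed random sites, each
cycling its own copy of the target coding sequence.  Events follow the
Gillespie direct method with per-complex travel propensity derived from
*d = D/h²* and first-order dissociation *k*<sub>diss</sub>.  A jump onto
a site with a cognate, non-refractory ribosome elongates one codon; the
ribosome then idles for *t*<sub>cat</sub> = 1/24 s and the complex is
recycled through the free tRNA pool.  The specific elongation rate is
the OLS slope of elongation count over time (events 1001–5000),
normalised by ribosome count.  On top of the simulator:

* **ε<sub>T3</sub> = (∂v<sub>TL</sub>/∂c<sub>T3</sub>)(c<sub>T3</sub>/v<sub>TL</sub>)** — substrate elasticity, and
  **FCC = (∂v<sub>TL</sub>/∂c<sub>R</sub>)(c<sub>R</sub>/v<sub>TL</sub>)** — ribosome flux control
  coefficient, by central finite differences over simulated rates;
* ATP-budget allocation across (ribosomes, tRNA, EFTu) on a share
  simplex, maximising the volume-total rate per ATP spent.

Parameter tables (1044 ribosomes, 9122 EFTu, 36 tRNA species at growth
rate 1.1 h⁻¹; D = 2.567×10⁻¹² m²/s) ship with the package.  Coding
sequences are read from FASTA or generated synthetically with a tunable
`adaptation` of codon demand to tRNA supply; the bundled `tufa_like`
(adaptation 1) and `gfp_like` (adaptation 0) fixtures are synthetic
stand-ins for the study's native and heterologous target genes.  See
`docs/methods.md` for conventions, calibration of *h*, measurement
windows and known limitations.

## Worked example

```bash
python examples/01_elongation_rates.py
```

prints (exact numbers are seed- and platform-deterministic):

```
tufa_like : 17.98 +/- 0.05 aa/ribosome/s (one elongation somewhere in the volume every 51 us)
gfp_like  : 13.08 +/- 0.05 aa/ribosome/s (one elongation somewhere in the volume every 73 us)
Rates are OLS slopes of elongation count vs time over events 1001-5000,
normalised by the 1044 ribosomes in the reaction volume.
```

The pool-adapted sequence elongates ~37% faster than the non-adapted
one at identical concentrations: with supply-matched codon demand no
single tRNA species is ever the bottleneck.  Under 20-fold dilution to
cell-free concentrations (`examples/02_dilution_sweep.py`) the rate
drops only ~6-fold, because the 1/24 s catalytic time is concentration
independent.  `examples/03_control_coefficients.py` shows who controls
the flux (FCC ≈ 1.0 for the adapted gene, substrate elasticity ≈ 0.7
for the non-adapted one), and `examples/04_atp_allocation.py` finds the
most economical ATP split for boosting translation.

## Layout

```
src/elonsim/     params, sequences, ssa (+ JIT kernel), rates,
                 control, atp, config, cli
src/elonsim/data bundled parameter tables and the codon->tRNA map
examples/        one short narrative script per capability
tests/           pytest suite; test_acceptance.py holds the end-to-end
                 scientific checks
docs/methods.md  model, estimators, calibration, limitations
```
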