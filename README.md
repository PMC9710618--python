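# blinkmix

Calibration-free molecular counting for single-molecule localization
microscopy (SMLM).

## The problem

SMLM techniques (dSTORM, PALM, DNA-PAINT) image fluorescently labeled
macromolecular complexes one stochastic blink at a time. The number of
blinks a complex emits before photobleaching carries information about
how many labeled subunits it has — so a field of view full of complexes
yields a histogram of per-complex blink counts from which the
monomer/dimer/trimer composition of the population can, in principle, be
read off. The catch is that the conversion depends on the fluorophore's
blinking propensity, which is environment-sensitive and tedious to
calibrate sample by sample.

`blinkmix` removes the calibration step. Most photoswitchable
fluorophores emit a geometrically distributed number of blinks, so a
single fluorophore with characteristic blink number λ has

    Pr(B = b) = (1 − e^(−1/λ)) e^(−(b−1)/λ),   b ≥ 1,

and a complex carrying N fluorophores emits a negative-binomial total

    p(B | N) = C(B−1, N−1) (e^(1/λ) − 1)^N e^(−B/λ),   B ≥ N.

A population with fractions π₁…π_h of 1…h-subunit complexes then
produces the finite mixture p(B) = Σ_k π_k p(B|k). Both the fractions
**and λ itself** are estimated jointly from the observed blink counts by
an expectation–maximization (EM) algorithm with a closed-form λ update,
so no separate single-fluorophore calibration experiment is needed.

The package also provides:

* **Labeling-efficiency correction** — with per-subunit labeling
  probability θ, detected-label classes are a binomially thinned,
  renormalized version of the true species; closed-form inversions (h ≤ 3)
  and a generic triangular solve map fitted "apparent" fractions back to
  true protomer fractions.
* **Model selection** — AIC scoring of candidate maximum orders
  (monomer vs monomer/dimer vs monomer/dimer/trimer), with near-tie
  diagnostics.
* **A simulator** — parametric geometric blinking or bootstrap assembly
  of protomers from a pool of single-dye blink counts, with binomial
  label dropout, plus replicate benchmarking with mean/CV summaries.

Intended users: microscopists and image analysts doing quantitative
SMLM stoichiometry, and method developers who need a reproducible
benchmark harness.

## Worked example

Simulate a 40/40/20 monomer/dimer/trimer population of 1000 complexes
with λ = 3.6 and 90% labeling efficiency, then fit it blind:

```sh
$ blinkmix simulate --lambda 3.6 --weights 0.4,0.4,0.2 --theta 0.9 \
      --n 1000 --seed 7 --out demo.csv
wrote 951 blink counts to demo.csv (49 complexes discarded as unlabeled)

$ blinkmix fit --input demo.csv --h 3 --theta 0.9 --seed 7 --restarts 2
h = 3   N_T = 951   converged = True (35 iterations)
lambda = 3.441
apparent fractions: pi1 = 0.4852, pi2 = 0.3755, pi3 = 0.1393
corrected fractions (theta = 0.9): pi'1 = 0.4309, pi'2 = 0.3871, pi'3 = 0.182
log-likelihood = -2650.99   AIC = 2656.99
```

Reading the output: 49 of the 1000 simulated complexes carried no
active label and are invisible, so 951 blink counts were fitted. The EM
fit recovers λ ≈ 3.44 (truth 3.6) without any calibration input. The
*apparent* fractions describe detected-label classes — labeling dropout
makes the population look more monomeric than it is (π̂₁ = 0.49 vs the
true 0.40). Supplying θ = 0.9 inverts the thinning model: the
*corrected* fractions (0.43/0.39/0.18) estimate the true 0.4/0.4/0.2
composition. Single-dataset trimer estimates carry substantial
statistical spread (see `docs/methods.md`); replicate benchmarks
(`blinkmix benchmark`) quantify it.

When the oligomer order is unknown, rank candidate models:

```sh
$ blinkmix select --input demo.csv --h-max 3 --seed 7
```

prints a per-h AIC table and flags near-ties (ΔAIC < 2), which are
common exactly where small minority fractions make orders hard to
distinguish.

The same workflow is available as a library:

```python
import blinkmix as bm

data = bm.read_blink_counts("demo.csv")          # or bm.BlinkDataset(counts)
fit = bm.fit_em(data, h=3, config=bm.EMConfig(seed=7))
corrected = bm.correct(fit.params.weights, theta=0.9)
```

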