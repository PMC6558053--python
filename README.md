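# diverse-induction

Bayesian models of the **diversity effect** in category-based induction,
and of how it depends on **sampling assumptions**.

People judge an argument like "dogs, rats and whales have enzyme X,
therefore all mammals do" as stronger than one built from similar
premises ("rabbits, raccoons and squirrels …").  On a Bayesian account
this diversity effect hinges on how the reasoner believes the premises
were selected.  The reasoner entertains hypotheses *h* about the
property's true extension, each with a prior *P(h)*, and updates on the
premise categories **x** by Bayes' rule

```
P(h | x) = P(x | h) P(h) / Σ_h' P(x | h') P(h')
```

The likelihood encodes the sampling assumption:

* **weak sampling** — items were observed at random, so
  *P(x | h) ∝ 1* for every hypothesis consistent with the evidence;
* **strong sampling** — items were drawn from among property bearers,
  so each of *m* positive premises contributes *1/(|h| − k)* for
  *k = 0..m−1* (sequential draws without replacement), where *|h|* is
  the extension size.  Smaller consistent hypotheses get more
  likelihood: the *size principle*.

Under strong sampling, nondiverse evidence (two canines) concentrates
the posterior on the narrow hypothesis, so generalization to a
superordinate collapses; under weak sampling it merely shrinks.  With
diverse evidence (a dog and a koala) only the superordinate survives
under either model — hence a larger diversity effect under strong
sampling.  The package implements this account end to end for
researchers in inductive reasoning and computational cognitive science:

* `hypotheses` — hypothesis spaces with sized extensions, explicit
  membership, priors; the six-hypothesis mammal taxonomy.
* `induction` — weak/strong likelihoods, posteriors, likelihood ratios,
  argument strength (all probability arithmetic in log space).
* `simulation` — a 1-D interval hypothesis space, a sweep of
  generalization over a continuous diversity axis, and a
  latent-diversity SSE fit mapping model curves onto rating-cell means.
* `experiment` — a seeded generator for a synthetic two-group
  (strong/weak instructions) 7-point rating experiment, 184
  participants, 12 trials each, with a configurable
  diversity-insensitive minority in the strong group.
* `analysis` — participant-level cell summaries, diversity effects and
  their interaction, per-argument ECDFs, per-subject effect scatter
  summaries, and a JZS paired-samples Bayes factor computed by
  numerical quadrature.
* `cli` — a `diverse-induction` command with `toy`, `posterior`,
  `sweep`, `fit`, `generate`, `analyze` and `pipeline` subcommands.

## Worked example

```bash
diverse-induction toy
```

```
Evidence wolf+, dog+ (nondiverse)
  weak sampling posterior:
    canines      0.333333
    ursines      0
    placentals   0.333333
    macropods    0
    marsupials   0
    mammals      0.333333
  strong sampling posterior:
    canines      0.999871
    ursines      0
    placentals   7.87595e-05
    macropods    0
    marsupials   0
    mammals      5.04036e-05
  strong likelihood ratios:
    canines : mammals    19,837 : 1
    canines : placentals 12,695 : 1
Evidence dog+, koala+ (diverse)
  weak sampling: P(mammals | dog, koala) = 1
  strong sampling: P(mammals | dog, koala) = 1
```

Reading: with two canines as evidence, a weak-sampling reasoner spreads
belief evenly over the three consistent hypotheses (1/3 each), while a
strong-sampling reasoner all but rules out the superordinates
(P(mammals | wolf, dog) ≈ 5.0×10⁻⁵) because drawing two canines at
random from 5,000 mammal species would be a huge coincidence.  With a
dog and a koala, only "mammals" is consistent, so both reasoners are
certain — the diversity effect, larger under strong sampling.

The same logic as a continuous sweep, plus the latent-diversity fit:

```python
from diverse_induction import SimulationConfig, diversity_sweep, fit_latent_diversity

curve = diversity_sweep(SimulationConfig())           # m=101 interval space
fit = fit_latent_diversity(curve, (5.38, 5.08, 4.78, 3.88))
print(fit.d_hat, fit.n_hat, fit.sse)                  # 0.227 0.076 ~2e-13
```

The four cell means (weak/strong × diverse/nondiverse) are reproduced
exactly by perceived diversities d̂ ≈ 0.23 for the diverse and
n̂ ≈ 0.08 for the nondiverse premise sets with an affine rating map —
with the strong-condition diversity gap (0.90) three times the weak
one (0.30).

A full synthetic experiment and analysis:

```bash
diverse-induction pipeline --seed 0 --out runs/demo
```

writes the generalization curve, a 2,208-row ratings CSV, cell
summaries, ECDF tables, the latent-diversity fit, and a run manifest.

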