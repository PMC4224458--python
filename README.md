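# emdetwin

Expectation–maximization resolution of the merohedral indexing ambiguity
that arises when merging snapshot ("still") diffraction data from many
randomly oriented crystals, as in serial femtosecond crystallography
(SFX) at X-ray free-electron lasers.

## The problem

When a crystal's Bravais lattice has higher symmetry than its space
group (e.g. space group *P*6₃ on a hexagonal lattice), auto-indexing
from Bragg spot positions alone cannot distinguish twin-related
settings such as (*h*, *k*, *l*) and (*k*, *h*, −*l*).  Merging
thousands of independently indexed snapshots then mixes the two
settings at random, and the merged intensities look like data from a
physically twinned crystal: the model–truth correlation is capped near
1/√2 ≈ 0.71.  Worse, each still records only *partial* reflections — a
fraction *p* ∈ (0, 1] of every full intensity — so single patterns are
too noisy to classify reliably against each other.

## The method

`emdetwin` assigns every pattern *i* an indexing mode *t* (one of the
candidate reindexing operators) by expectation maximization:

1. start from a model {*I*<sub>full</sub>} of random positive numbers
   on the observed reciprocal lattice;
2. **E-step** — compute Pearson correlations *r*<sub>*i*</sub><sup>*t*</sup>
   between each pattern's partial intensities and the model's means
   over their common reflections, for every mode *t*; assign each
   pattern its argmax mode;
3. **M-step** — Monte Carlo merge: reindex each pattern by its assigned
   operator, map to the asymmetric unit, and average all observations
   of each unique reflection;
4. iterate until assignments stop changing (typically < 10 iterations).

Progress is monitored by the target score (1/*N*) Σ<sub>*i*</sub>
max<sub>*t*</sub> *r*<sub>*i*</sub><sup>*t*</sup>.  Because the random
start carries no mode information, the first iteration splits the
patterns roughly 50/50; a small stochastic imbalance then amplifies
until the ambiguity breaks.  The result is defined up to a global
gauge: relabeling all modes by the twin law gives an equally valid
solution, so evaluation labels the mode that best matches a reference
the *consistent indexing mode* (CIM) and the others *alternative
indexing modes* (AIM).

The package also ships a synthetic-data generator (Wilson/exponential
true intensities, uniform or resolution-dependent partialities, Poisson
shot noise, random per-pattern modes) and an evaluation suite
(CIM/AIM gauging, ground-truth consistency, multi-start consistency
matrices, dataset-size sweeps, pairwise-vs-model separability).

## Worked example

```sh
python examples/01_detwin_synthetic_dataset.py
```

```
simulated 1000 patterns, 1713 unique reflections
  iteration 1: target score 0.0468, 536 assignments changed, mode populations [464, 536]
  iteration 2: target score 0.6413, 386 assignments changed, mode populations [492, 508]
  iteration 3: target score 0.7702, 25 assignments changed, mode populations [487, 513]
  iteration 4: target score 0.7715, 0 assignments changed, mode populations [487, 513]
model-truth correlation: CIM 0.9941, AIM 0.1183
patterns matching ground-truth modes: 100.00%
```

The near-zero score at iteration 1 reflects the random starting model;
it rises as consistently indexed patterns sharpen the merged model.  At
convergence the merged model correlates 0.994 with the true full
intensities in the consistent gauge (the alternative gauge scores only
0.118), and every pattern's mode matches the ground truth up to the
global gauge flip.  The other examples measure the 1/√2 twinned-merge
ceiling, multi-start self-consistency in a 3–5 Å shell, and why
pattern-vs-model correlations separate the modes better than
pattern-vs-pattern ones.

A thin CLI wraps the same library calls for shell pipelines:

```sh
emdetwin simulate -c config.yaml -o sim/
emdetwin detwin   -c config.yaml -i sim/dataset.txt -o run/
emdetwin evaluate -c config.yaml -m run/model.txt -r sim/true_model.txt \
                  -i sim/dataset.txt -a run/assignments.tsv \
                  --truth sim/truth_modes.tsv -o eval/
```

Input is either a native whitespace table (`h k l I [sigma]`, one
pattern per `# pattern_id:` block) or a tolerant subset of the CrystFEL
stream format.

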