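"""Simulate a twinned still-shot dataset and resolve it with EM.

Generates 1,000 snapshot patterns whose indexing modes are scrambled
between the two twin-related settings of point group 6, runs the EM
detwinner from a random starting model, and compares the result with
the (known) ground truth.
"""

from emdetwin import (AmbiguityGroup, EMConfig, PointGroup,
                      SimulationConfig, label_and_score, run_em,
                      simulate_dataset)

pg = PointGroup.hexagonal_6()
group = AmbiguityGroup.p63()

cfg = SimulationConfig(n_patterns=1000, seed=3)
dataset, truth = simulate_dataset(cfg, group, pg)
print(f"simulated {dataset.n_patterns} patterns, "
      f"{len(truth.true_model)} unique reflections")

state = run_em(dataset, group, pg, EMConfig(seed=7), cell=cfg.cell)
for rec in state.history:
    print(f"  iteration {rec.iteration}: target score {rec.score:.4f}, "
          f"{rec.n_changed} assignments changed, "
          f"mode populations {rec.mode_populations.tolist()}")

report = label_and_score(state, truth.true_model, group, pg, dataset,
                         truth=truth, cell=cfg.cell)
print(f"model-truth correlation: CIM {report.r_cim:.4f}, "
      f"AIM {report.r_aim:.4f}")
print(f"patterns matching ground-truth modes: "
      f"{100 * report.fraction_truth:.2f}%")

# The CIM (consistent indexing mode) correlation near 1 says the merged
# model reproduces the true full intensities; the much lower AIM value
# is what the twin-related alternative setting would give.  A truth
# fraction near 100% means the ambiguity was resolved pattern by
# pattern, up to an irrelevant global gauge flip.
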