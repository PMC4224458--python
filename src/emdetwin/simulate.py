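"""Synthetic still-shot datasets with a known ground truth.

The generator emulates the statistical structure that the detwinner
exploits, with no external data:

* true full intensities are i.i.d. exponential draws on the canonical
  reciprocal lattice (Wilson statistics for acentric reflections), so
  twin-related index pairs carry independent intensities except for the
  twin-invariant reflections, which are single lattice entries;
* each pattern observes a random subset of the lattice; its true
  indexing mode is drawn from the configured mode probabilities;
* every observation is the true intensity of the mode-reindexed index
  scaled by a per-reflection partiality — either Uniform(0,1)
  independent of resolution, or a resolution-dependent family whose
  lower bound rises with scattering vector q (the Ewald shell is thicker
  at higher resolution, so high-q partials are better measured);
* optional Poisson shot noise replaces each intensity with a Poisson
  draw of that mean (intensities are in photons).

What it does not emulate: patterns as curved Ewald-slice samples of the
lattice (subsets are uniform), beam-profile and crystal-size variation,
and structure-factor amplitudes from an atomic model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .reflection_io import Dataset, MergedModel, Pattern, UnitCell, resolution_d
from .symmetry import AmbiguityGroup, PointGroup, apply_operator, asu_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "canonical_lattice",
    "wilson_intensities",
    "draw_partiality",
    "simulate_dataset",
]

#: smallest admissible per-pattern reflection count (matches the EM
#: default for a defined correlation)
_MIN_REFLECTIONS = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    The default lattice is a small hexagonal cell (a = b = 60 Å,
    c = 40 Å) truncated at d_min = 3 Å, giving roughly 1.5k unique
    reflections — enough multiplicity for Monte Carlo merging at desk
    scale while keeping the 3–5 Å shell populated.  ``psi_preset``
    switches to Photosystem-I-like cell dimensions.
    """

    n_patterns: int = 1000
    reflections_per_pattern: int = 100   # Poisson mean per pattern
    cell: UnitCell = field(
        default_factory=lambda: UnitCell.hexagonal(60.0, 40.0))
    d_min: float = 3.0
    intensity_scale: float = 1000.0      # mean full intensity, photons
    partiality_model: Literal["uniform", "resolution_dependent"] = "uniform"
    p_floor: float = 0.1                 # low-q asymptote of the lower bound
    noise: Literal["poisson", "none"] = "poisson"
    mode_probabilities: tuple[float, ...] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_patterns <= 0 or self.reflections_per_pattern <= 0:
            raise ValueError("counts must be positive")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not 0 < self.p_floor <= 1:
            raise ValueError("p_floor must be in (0, 1]")
        if abs(sum(self.mode_probabilities) - 1.0) > 1e-9:
            raise ValueError("mode probabilities must sum to 1")

    @classmethod
    def psi_preset(cls, **overrides) -> "SimulationConfig":
        """Photosystem-I-like hexagonal cell (a = b = 281 Å, c = 165.2 Å).

        The resolution truncation defaults to 10 Å here: at this cell
        volume the 3 Å lattice would hold ~10⁵ unique reflections, far
        beyond what desk-scale multiplicities can merge meaningfully.
        """
        defaults = dict(cell=UnitCell.hexagonal(281.0, 165.2), d_min=10.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the detwinner must not see.

    ``true_partialities[pid]`` is aligned row-for-row with the pattern's
    reflection arrays.
    """

    true_model: MergedModel
    true_modes: dict[str, int]
    true_partialities: dict[str, np.ndarray]

    def mode_vector(self, ds: Dataset) -> np.ndarray:
        return np.array([self.true_modes[p.id] for p in ds], dtype=np.int64)


def canonical_lattice(cell: UnitCell, d_min: float,
                      pg: PointGroup) -> np.ndarray:
    """All ASU-canonical Miller indices with d >= d_min, sorted."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    g = cell.reciprocal_metric()
    # conservative per-axis bounds from the diagonal metric entries
    hmax = int(math.ceil(1.0 / (d_min * math.sqrt(g[0, 0]))))
    kmax = int(math.ceil(1.0 / (d_min * math.sqrt(g[1, 1]))))
    lmax = int(math.ceil(1.0 / (d_min * math.sqrt(g[2, 2]))))
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    block = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    block = block[block.any(axis=1)]
    d = resolution_d(block, cell)
    block = block[d >= d_min]
    if len(block) == 0:
        raise ValueError("lattice is empty at this d_min")
    canon = np.unique(asu_map(block, pg), axis=0)
    return canon


def wilson_intensities(lattice: np.ndarray, intensity_scale: float,
                       seed: int) -> MergedModel:
    """Exponential (acentric Wilson) full intensities on a lattice.

    Each canonical index gets an i.i.d. Exponential(mean=intensity_scale)
    draw; twin-related pairs are therefore independent unless the twin
    maps an index onto its own orbit.
    """
    lattice = np.asarray(lattice, dtype=np.int64).reshape(-1, 3)
    if len(lattice) == 0:
        raise ValueError("empty lattice")
    rng = np.random.default_rng(seed)
    return MergedModel.from_means(
        lattice, rng.exponential(intensity_scale, size=len(lattice)))


def draw_partiality(hkl, cell: UnitCell,
                    model: Literal["uniform", "resolution_dependent"],
                    p_floor: float, d_min: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-reflection partialities in (0, 1].

    uniform: Uniform(0, 1) independent of resolution.
    resolution_dependent: Uniform(lo(q), 1] with
    lo(q) = p_floor + (1 - p_floor) * q / q_max, q = 1/d, q_max = 1/d_min
    — the expected partiality rises strictly with q, mimicking the
    thicker Ewald shell at higher scattering angles.
    """
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    n = len(hkl)
    if model == "uniform":
        u = rng.uniform(size=n)
        return np.nextafter(u, 1.0)          # open at 0, closed at 1
    if model != "resolution_dependent":
        raise ValueError(f"unknown partiality model {model!r}")
    q = 1.0 / resolution_d(hkl, cell)
    q_max = 1.0 / d_min
    lo = p_floor + (1.0 - p_floor) * np.minimum(q / q_max, 1.0)
    u = rng.uniform(size=n)
    return lo + (1.0 - lo) * np.nextafter(u, 1.0)


def simulate_dataset(cfg: SimulationConfig,
                     g: AmbiguityGroup | None = None,
                     pg: PointGroup | None = None
                     ) -> tuple[Dataset, GroundTruth]:
    """Generate one dataset plus its complete ground truth.

    For each pattern: a Poisson-sized subset of the canonical lattice is
    drawn without replacement (count truncated to at least 5), a true
    mode is drawn from ``mode_probabilities``, and each observed index h
    records partiality × true intensity of the mode-reindexed index,
    Poisson-resampled when shot noise is on.  Fully reproducible from
    ``cfg.seed``.
    """
    g = g or AmbiguityGroup.p63()
    pg = pg or PointGroup.hexagonal_6()
    if len(cfg.mode_probabilities) != g.n_modes:
        raise ValueError("mode_probabilities length must equal n_modes")
    lattice = canonical_lattice(cfg.cell, cfg.d_min, pg)
    if cfg.reflections_per_pattern > len(lattice):
        raise ValueError(
            f"reflections_per_pattern={cfg.reflections_per_pattern} exceeds "
            f"lattice size {len(lattice)}")
    rng = np.random.default_rng(cfg.seed)
    true_model = wilson_intensities(
        lattice, cfg.intensity_scale,
        seed=int(rng.integers(0, 2**31 - 1)))
    true_means = true_model.mean_intensity

    # fast canonical-index -> lattice-row lookup for each mode
    base = int(np.abs(lattice).max()) + 1
    span = 2 * base + 1

    def encode(a):
        return ((a[:, 0] + base) * span + (a[:, 1] + base)) * span \
            + (a[:, 2] + base)

    lattice_keys = encode(lattice)
    order = np.argsort(lattice_keys)
    sorted_keys = lattice_keys[order]
    mode_row_of = []
    for op in g.operators:
        mapped = asu_map(apply_operator(op, lattice), pg)
        pos = np.searchsorted(sorted_keys, encode(mapped))
        mode_row_of.append(order[pos])
    mode_row_of = np.stack(mode_row_of)     # (n_modes, n_lattice)

    n_digits = len(str(cfg.n_patterns - 1))
    patterns: list[Pattern] = []
    true_modes: dict[str, int] = {}
    true_partialities: dict[str, np.ndarray] = {}
    probs = np.asarray(cfg.mode_probabilities)
    for i in range(cfg.n_patterns):
        count = int(rng.poisson(cfg.reflections_per_pattern))
        count = max(_MIN_REFLECTIONS, min(count, len(lattice)))
        subset = rng.choice(len(lattice), size=count, replace=False)
        mode = int(rng.choice(g.n_modes, p=probs))
        hkl = lattice[subset]
        true_rows = mode_row_of[mode][subset]
        part = draw_partiality(hkl, cfg.cell, cfg.partiality_model,
                               cfg.p_floor, cfg.d_min, rng)
        expected = part * true_means[true_rows]
        if cfg.noise == "poisson":
            observed = rng.poisson(expected).astype(np.float64)
            sigma = np.sqrt(np.maximum(observed, 1.0))
        elif cfg.noise == "none":
            observed = expected
            sigma = None
        else:
            raise ValueError(f"unknown noise model {cfg.noise!r}")
        pid = f"sim_{i:0{n_digits}d}"
        patterns.append(Pattern(pid, hkl, observed, sigma, source="simulate"))
        true_modes[pid] = mode
        true_partialities[pid] = part
    return Dataset(patterns), GroundTruth(true_model, true_modes,
                                          true_partialities)
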