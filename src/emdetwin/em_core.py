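"""The EM detwinning algorithm.

Each snapshot records only partial reflection intensities, and when the
Bravais lattice outranks the space group every pattern may arrive in any
of the twin-related indexing settings.  The algorithm here resolves the
ambiguity without a reference structure:

1. start from a model of random positive intensities on the observed
   reciprocal lattice;
2. E-step: correlate every pattern with the model under every candidate
   reindexing operator (Pearson, over the reflections they share) and
   assign each pattern the mode with the highest correlation;
3. M-step: merge all patterns under their assigned modes by plain Monte
   Carlo averaging of every observation of each canonical index;
4. repeat until the assignments stop changing.

The objective being ascended is the mean over patterns of the best
per-pattern correlation with the merged model (the target score), which
is also the quantity used to monitor convergence.  Correlations ignore
very low-resolution reflections (huge intensities there dominate the
sums and carry no mode information) and are declared undefined below a
minimum number of shared reflections.

Everything is computed on flat arrays: a dataset is "compiled" once into
concatenated observation vectors plus, for every candidate mode, the
model-row index of each observation after reindexing and ASU mapping.
One EM iteration is then a handful of ``np.bincount`` passes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reflection_io import Dataset, MergedModel, Pattern, UnitCell, resolution_d
from .symmetry import AmbiguityGroup, PointGroup, ReindexOperator, apply_operator, asu_map, validate_group

__all__ = [
    "EMConfig",
    "ModeCorrelations",
    "Assignment",
    "EMState",
    "IterationRecord",
    "pearson",
    "pattern_pair_correlation",
    "pattern_model_correlation",
    "assign_modes",
    "merge",
    "random_model",
    "target_score",
    "run_em",
]

log = logging.getLogger(__name__)

#: default minimum number of shared reflections for a defined correlation
MIN_COMMON = 5

#: default low-resolution cutoff: reflections with d > 20 Å are ignored
#: in correlation sums (their extreme intensities swamp the statistic)
LOW_RES_CUTOFF_D = 20.0


@dataclass
class EMConfig:
    """Tunable parameters of the EM loop.

    max_iterations: hard iteration cap (convergence is typically reached
        well within ten iterations).
    min_common: minimum shared reflections for a defined correlation.
    low_res_cutoff_d: reflections with d-spacing above this (Å) are
        excluded from correlations; requires a unit cell.  ``None``
        disables the cutoff.
    convergence_fraction: stop once the fraction of patterns changing
        mode drops below this (or exactly zero change).
    seed: governs the random starting model and any random assignment of
        patterns with no defined correlation.
    winsorize_percentile: if set (e.g. 99.9), intensities above this
        percentile are clipped for correlation purposes only, a guard
        against saturated measurements; merging always uses raw values.
    """

    max_iterations: int = 20
    min_common: int = MIN_COMMON
    low_res_cutoff_d: float | None = LOW_RES_CUTOFF_D
    convergence_fraction: float = 0.001
    seed: int = 0
    winsorize_percentile: float | None = None


@dataclass
class ModeCorrelations:
    """Per-pattern correlations with the model under each mode."""

    pattern_id: str
    r_per_mode: np.ndarray          # NaN marks an undefined correlation
    n_common_per_mode: np.ndarray


@dataclass
class Assignment:
    """The chosen indexing mode for one pattern."""

    pattern_id: str
    mode: int
    best_r: float                   # NaN if assignment was random


@dataclass
class IterationRecord:
    iteration: int
    score: float
    n_changed: int
    mode_populations: np.ndarray


@dataclass
class EMState:
    """Final state of a run plus the per-iteration trajectory."""

    iteration: int
    model: MergedModel
    assignments: list[Assignment]
    correlations: list[ModeCorrelations]
    score_history: list[float]
    n_changed: int
    rng_seed: int
    converged: bool
    history: list[IterationRecord] = field(default_factory=list)

    @property
    def assignment_vector(self) -> np.ndarray:
        return np.array([a.mode for a in self.assignments], dtype=np.int64)


# ---------------------------------------------------------------------------
# scalar statistics

def pearson(x, y) -> float:
    """Pearson product-moment correlation; NaN when undefined.

    Means are taken over the supplied (common) entries only.  Zero
    variance in either vector yields NaN — "no information", which
    callers must treat as distinct from a low correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-d vectors")
    if len(x) < 2:
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx <= 0.0 or vy <= 0.0:
        return float("nan")
    return float((dx @ dy) / math.sqrt(vx * vy))


def _encode(hkl: np.ndarray, base: int) -> np.ndarray:
    span = 2 * base + 1
    return ((hkl[:, 0] + base) * span + (hkl[:, 1] + base)) * span \
        + (hkl[:, 2] + base)


def pattern_pair_correlation(p: Pattern, q: Pattern, op: ReindexOperator,
                             pg: PointGroup,
                             min_common: int = MIN_COMMON):
    """Correlation between two patterns with q reindexed by ``op``.

    Returns ``(r, n_common)``; r is NaN when fewer than ``min_common``
    reflections are shared or either side has zero variance.
    """
    q_hkl = asu_map(apply_operator(op, q.hkl), pg)
    base = int(max(np.abs(p.hkl).max(initial=0),
                   np.abs(q_hkl).max(initial=0))) + 1
    kp = _encode(p.hkl, base)
    kq = _encode(q_hkl, base)
    common, ip, iq = np.intersect1d(kp, kq, return_indices=True)
    n_common = len(common)
    if n_common < min_common:
        return float("nan"), n_common
    return pearson(p.intensity[ip], q.intensity[iq]), n_common


def pattern_model_correlation(p: Pattern, model: MergedModel,
                              op: ReindexOperator, pg: PointGroup,
                              cell: UnitCell | None = None,
                              low_res_cutoff_d: float | None = LOW_RES_CUTOFF_D,
                              min_common: int = MIN_COMMON):
    """Correlation between a pattern's partials and the model's means.

    The pattern's indices are reindexed by ``op``, ASU-canonicalized and
    matched against model entries with at least one observation.  When a
    cell is given, reflections with d-spacing above ``low_res_cutoff_d``
    are excluded.  Returns ``(r, n_common)``.
    """
    p_hkl = asu_map(apply_operator(op, p.hkl), pg)
    keep = np.ones(len(p_hkl), dtype=bool)
    if cell is not None and low_res_cutoff_d is not None:
        keep &= resolution_d(p.hkl, cell) <= low_res_cutoff_d
    base = int(max(np.abs(p_hkl).max(initial=0),
                   np.abs(model.hkl).max(initial=0))) + 1
    kp = _encode(p_hkl, base)
    km = _encode(model.hkl, base)
    order = np.argsort(km)
    pos = np.searchsorted(km[order], kp)
    pos = np.clip(pos, 0, len(km) - 1)
    hit = keep & (km[order][pos] == kp)
    rows = order[pos[hit]]
    visible = model.n_obs[rows] > 0
    rows = rows[visible]
    x = p.intensity[hit][visible]
    n_common = len(rows)
    if n_common < min_common:
        return float("nan"), n_common
    return pearson(x, model.mean_intensity[rows]), n_common


# ---------------------------------------------------------------------------
# compiled dataset: flat arrays for the vectorized EM loop

@dataclass
class _Compiled:
    pattern_ids: list[str]
    obs_pattern: np.ndarray      # (T,) ordinal of the owning pattern
    obs_intensity: np.ndarray    # (T,) raw intensities (used for merging)
    obs_corr_value: np.ndarray   # (T,) possibly winsorized (correlations)
    rows_per_mode: np.ndarray    # (n_modes, T) model row per observation
    lowres_ok: np.ndarray        # (T,) passes the low-resolution cutoff
    model_hkl: np.ndarray        # (M, 3) canonical union over all modes

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_ids)

    @property
    def n_modes(self) -> int:
        return self.rows_per_mode.shape[0]

    @property
    def n_model(self) -> int:
        return len(self.model_hkl)


def _compile(ds: Dataset, g: AmbiguityGroup, pg: PointGroup,
             cell: UnitCell | None, cfg: EMConfig) -> _Compiled:
    if ds.n_patterns == 0:
        raise ValueError("empty dataset")
    all_hkl = np.concatenate([p.hkl for p in ds])
    intensity = np.concatenate([p.intensity for p in ds])
    obs_pattern = np.concatenate([
        np.full(len(p), i, dtype=np.int64) for i, p in enumerate(ds)])

    canon_per_mode = [asu_map(apply_operator(op, all_hkl), pg)
                      for op in g.operators]
    base = int(max(np.abs(c).max() for c in canon_per_mode)) + 1
    keys_per_mode = [_encode(c, base) for c in canon_per_mode]
    union_keys = np.unique(np.concatenate(keys_per_mode))
    rows_per_mode = np.stack([
        np.searchsorted(union_keys, k) for k in keys_per_mode])

    # recover the union's hkl triples from the first occurrence of each key
    stacked_keys = np.concatenate(keys_per_mode)
    stacked_hkl = np.concatenate(canon_per_mode)
    first = np.full(len(union_keys), -1, dtype=np.int64)
    pos = np.searchsorted(union_keys, stacked_keys)
    first[pos[::-1]] = np.arange(len(stacked_keys) - 1, -1, -1)
    model_hkl = stacked_hkl[first]

    if cell is not None and cfg.low_res_cutoff_d is not None:
        lowres_ok = resolution_d(all_hkl, cell) <= cfg.low_res_cutoff_d
    else:
        lowres_ok = np.ones(len(all_hkl), dtype=bool)

    corr_value = intensity
    if cfg.winsorize_percentile is not None:
        cap = np.percentile(intensity, cfg.winsorize_percentile)
        corr_value = np.minimum(intensity, cap)

    return _Compiled([p.id for p in ds], obs_pattern, intensity, corr_value,
                     rows_per_mode, lowres_ok, model_hkl)


def _mode_correlations(comp: _Compiled, model_means: np.ndarray,
                       model_visible: np.ndarray, min_common: int):
    """(P, n_modes) correlation matrix + matching n_common counts."""
    P = comp.n_patterns
    r = np.full((P, comp.n_modes), np.nan)
    n_common = np.zeros((P, comp.n_modes), dtype=np.int64)
    for t in range(comp.n_modes):
        rows = comp.rows_per_mode[t]
        valid = comp.lowres_ok & model_visible[rows]
        pid = comp.obs_pattern[valid]
        x = comp.obs_corr_value[valid]
        y = model_means[rows[valid]]
        n = np.bincount(pid, minlength=P).astype(np.float64)
        sx = np.bincount(pid, weights=x, minlength=P)
        sy = np.bincount(pid, weights=y, minlength=P)
        sxx = np.bincount(pid, weights=x * x, minlength=P)
        syy = np.bincount(pid, weights=y * y, minlength=P)
        sxy = np.bincount(pid, weights=x * y, minlength=P)
        n_common[:, t] = n.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / np.where(n > 0, n, 1)
            vx = sxx - sx * sx / np.where(n > 0, n, 1)
            vy = syy - sy * sy / np.where(n > 0, n, 1)
            rt = cov / np.sqrt(vx * vy)
        rt[(n < min_common) | (vx <= 0) | (vy <= 0)] = np.nan
        r[:, t] = rt
    return r, n_common


def _assign_from_r(r: np.ndarray, prev: np.ndarray | None,
                   rng: np.random.Generator):
    """Argmax assignment with hysteresis tie-breaking.

    Ties keep the previous iteration's mode when it attains the maximum;
    otherwise the lowest mode index wins.  Patterns whose correlations
    are undefined in every mode get a uniformly random (seeded) mode and
    a NaN best_r.
    """
    P, n_modes = r.shape
    defined = np.isfinite(r)
    any_defined = defined.any(axis=1)
    filled = np.where(defined, r, -np.inf)
    mode = np.argmax(filled, axis=1)
    best_r = filled[np.arange(P), mode]
    if prev is not None:
        prev_ok = defined[np.arange(P), prev]
        prev_r = np.where(prev_ok, r[np.arange(P), prev], -np.inf)
        keep_prev = any_defined & prev_ok & (prev_r == best_r)
        mode[keep_prev] = prev[keep_prev]
    n_undef = int((~any_defined).sum())
    if n_undef:
        mode[~any_defined] = rng.integers(0, n_modes, size=n_undef)
        best_r[~any_defined] = np.nan
    return mode, best_r, n_undef


def _merge_compiled(comp: _Compiled, mode_vec: np.ndarray) -> MergedModel:
    rows = comp.rows_per_mode[mode_vec[comp.obs_pattern],
                              np.arange(len(comp.obs_pattern))]
    sums = np.bincount(rows, weights=comp.obs_intensity,
                       minlength=comp.n_model)
    counts = np.bincount(rows, minlength=comp.n_model)
    return MergedModel(comp.model_hkl, sums, counts.astype(np.int64))


# ---------------------------------------------------------------------------
# public per-spec operations (thin wrappers over the compiled path)

def assign_modes(ds: Dataset, model: MergedModel, g: AmbiguityGroup,
                 pg: PointGroup, cfg: EMConfig | None = None,
                 cell: UnitCell | None = None,
                 rng: np.random.Generator | None = None,
                 prev: np.ndarray | None = None):
    """E-step: best indexing mode per pattern against a fixed model.

    Returns ``(correlations, assignments)``; patterns with no defined
    correlation in any mode are assigned a seeded random mode.
    """
    cfg = cfg or EMConfig()
    if not validate_group(g):
        raise ValueError("invalid ambiguity group")
    rng = rng or np.random.default_rng(cfg.seed)
    comp = _compile(ds, g, pg, cell, cfg)
    means, visible = _project_model(comp, model)
    r, n_common = _mode_correlations(comp, means, visible, cfg.min_common)
    mode, best_r, n_undef = _assign_from_r(r, prev, rng)
    if n_undef:
        log.info("assign_modes: %d pattern(s) had no defined correlation; "
                 "assigned randomly", n_undef)
    correlations = [ModeCorrelations(pid, r[i], n_common[i])
                    for i, pid in enumerate(comp.pattern_ids)]
    assignments = [Assignment(pid, int(mode[i]), float(best_r[i]))
                   for i, pid in enumerate(comp.pattern_ids)]
    return correlations, assignments


def _project_model(comp: _Compiled, model: MergedModel):
    """Align an arbitrary model onto the compiled lattice rows."""
    base = int(max(np.abs(comp.model_hkl).max(initial=0),
                   np.abs(model.hkl).max(initial=0))) + 1
    ck = _encode(comp.model_hkl, base)
    mk = _encode(model.hkl, base)
    order = np.argsort(mk)
    pos = np.searchsorted(mk[order], ck)
    pos = np.clip(pos, 0, len(mk) - 1)
    hit = mk[order][pos] == ck
    means = np.zeros(comp.n_model)
    visible = np.zeros(comp.n_model, dtype=bool)
    src = order[pos[hit]]
    visible[hit] = model.n_obs[src] > 0
    model_means = model.mean_intensity
    means[hit] = np.where(model.n_obs[src] > 0, model_means[src], 0.0)
    return means, visible


def merge(ds: Dataset, assignments: Sequence[Assignment], g: AmbiguityGroup,
          pg: PointGroup) -> MergedModel:
    """M-step: Monte Carlo merge under the given per-pattern modes.

    Every observation is reindexed by its pattern's assigned operator,
    ASU-canonicalized, and averaged into its canonical entry (plain
    unweighted mean; partiality and the other stochastic factors average
    out as more patterns contribute).
    """
    if ds.n_patterns == 0:
        raise ValueError("empty dataset")
    if len(assignments) != ds.n_patterns:
        raise ValueError("need exactly one assignment per pattern")
    by_id = {a.pattern_id: a.mode for a in assignments}
    comp = _compile(ds, g, pg, None, EMConfig(low_res_cutoff_d=None))
    mode_vec = np.array([by_id[p.id] for p in ds], dtype=np.int64)
    return _merge_compiled(comp, mode_vec)


def random_model(indices, seed: int) -> MergedModel:
    """The iteration-zero model: random positive intensities.

    Every canonical index receives an independent Uniform(0, 1) draw with
    ``n_obs = 1`` so the entry is visible to correlations.  Starting from
    noise guarantees the first E-step carries no mode information, which
    is why the first iteration splits the patterns roughly evenly.
    """
    hkl = np.asarray(indices, dtype=np.int64).reshape(-1, 3)
    if len(hkl) == 0:
        raise ValueError("random_model needs at least one index")
    rng = np.random.default_rng(seed)
    means = rng.uniform(0.0, 1.0, size=len(hkl))
    return MergedModel.from_means(hkl, means)


def target_score(correlations: Sequence[ModeCorrelations]) -> float:
    """Mean over patterns of the best per-mode correlation.

    Patterns whose correlations are undefined in every mode are excluded
    from both numerator and count.  This is the monitored EM objective:
    it rises as the merged model absorbs consistently indexed patterns
    and saturates when every pattern is indexed as well as its partial
    reflections allow.
    """
    best = []
    for c in correlations:
        finite = c.r_per_mode[np.isfinite(c.r_per_mode)]
        if len(finite):
            best.append(finite.max())
    if not best:
        raise ValueError("no pattern has a defined correlation")
    return float(np.mean(best))


def run_em(ds: Dataset, g: AmbiguityGroup, pg: PointGroup,
           config: EMConfig | None = None,
           cell: UnitCell | None = None) -> EMState:
    """Full EM loop: random model → (assign, merge) until stable.

    Returns the final :class:`EMState`; ``state.history`` holds one
    record per iteration (target score, number of assignment changes,
    mode populations).  Non-convergence at ``max_iterations`` is flagged
    via ``state.converged`` rather than raised.
    """
    cfg = config or EMConfig()
    if ds.n_patterns == 0:
        raise ValueError("empty dataset")
    problems = [p for p in [g] if not validate_group(p)]
    if problems:
        raise ValueError("invalid ambiguity group")
    comp = _compile(ds, g, pg, cell, cfg)
    rng = np.random.default_rng(cfg.seed)
    model = random_model(comp.model_hkl, seed=cfg.seed)
    means, visible = model.mean_intensity, model.n_obs > 0

    prev = np.zeros(comp.n_patterns, dtype=np.int64)
    score_history: list[float] = []
    history: list[IterationRecord] = []
    r = n_common = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        r, n_common = _mode_correlations(comp, means, visible, cfg.min_common)
        mode_vec, best_r, n_undef = _assign_from_r(
            r, prev if it > 1 else None, rng)
        n_changed = int((mode_vec != prev).sum())
        model = _merge_compiled(comp, mode_vec)
        means, visible = model.mean_intensity, model.n_obs > 0
        means = np.nan_to_num(means)
        finite = best_r[np.isfinite(best_r)]
        score = float(finite.mean()) if len(finite) else float("nan")
        score_history.append(score)
        pops = np.bincount(mode_vec, minlength=g.n_modes)
        history.append(IterationRecord(it, score, n_changed, pops))
        log.info("iteration %d: score=%.4f n_changed=%d populations=%s%s",
                 it, score, n_changed, pops.tolist(),
                 f" ({n_undef} random)" if n_undef else "")
        prev = mode_vec
        if n_changed == 0 or n_changed / comp.n_patterns < cfg.convergence_fraction:
            converged = True
            break

    assignments = [Assignment(pid, int(prev[i]),
                              float(r[i][prev[i]]) if np.isfinite(
                                  r[i][prev[i]]) else float("nan"))
                   for i, pid in enumerate(comp.pattern_ids)]
    correlations = [ModeCorrelations(pid, r[i], n_common[i])
                    for i, pid in enumerate(comp.pattern_ids)]
    if not converged:
        log.warning("EM did not converge within %d iterations",
                    cfg.max_iterations)
    return EMState(iteration=it, model=model, assignments=assignments,
                   correlations=correlations, score_history=score_history,
                   n_changed=history[-1].n_changed, rng_seed=cfg.seed,
                   converged=converged, history=history)
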