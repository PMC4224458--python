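"""Reflection-list data model, text readers/writers, resolution bookkeeping.

Per-pattern partial reflection intensities are held as flat numpy arrays
(an (N, 3) integer index block plus an intensity vector), which is the
layout every downstream correlation is computed on.  Two on-disk formats
are supported, both plain text:

* a native whitespace table ``h k l I [sigma]`` with ``#`` comments, one
  pattern per file or several patterns concatenated under
  ``# pattern_id: <id>`` header lines;
* a tolerant subset of the CrystFEL stream format (chunk delimiters and
  the reflection table only; geometry, cell and peak blocks are ignored).

Indices are mapped to their asymmetric-unit representative at load time;
duplicate observations of one canonical index within a pattern (e.g.
Friedel mates) are averaged, with a count kept in the load log.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .symmetry import MillerIndex, PointGroup, asu_map

__all__ = [
    "Reflection",
    "Pattern",
    "Dataset",
    "UnitCell",
    "MergedModel",
    "read_reflection_table",
    "read_patterns",
    "write_pattern",
    "write_dataset",
    "read_stream_subset",
    "write_model",
    "read_model",
    "resolution_d",
    "shell_filter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reflection:
    """One observed partial reflection (scalar convenience view)."""

    hkl: MillerIndex
    intensity: float
    sigma: float | None = None


def _merge_duplicates(hkl: np.ndarray, intensity: np.ndarray,
                      sigma: np.ndarray | None):
    """Average duplicate canonical indices; returns arrays + n merged."""
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    hkl, intensity = hkl[order], intensity[order]
    if sigma is not None:
        sigma = sigma[order]
    uniq, inverse, counts = np.unique(hkl, axis=0, return_inverse=True,
                                      return_counts=True)
    if len(uniq) == len(hkl):
        return hkl, intensity, sigma, 0
    mean_i = np.bincount(inverse, weights=intensity) / counts
    mean_s = None
    if sigma is not None:
        # combined sigma of an average of independent observations
        mean_s = np.sqrt(np.bincount(inverse, weights=sigma ** 2)) / counts
    return uniq, mean_i, mean_s, int(len(hkl) - len(uniq))


@dataclass
class Pattern:
    """One snapshot's set of partial reflection intensities.

    ``hkl`` is an (N, 3) integer array of ASU-canonical indices (unique
    within the pattern), ``intensity`` the matching partial intensities.
    """

    id: str
    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    source: str = ""

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if len(self.hkl) != len(self.intensity):
            raise ValueError("hkl and intensity length mismatch")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError(f"pattern {self.id}: non-finite intensity")

    def __len__(self) -> int:
        return len(self.hkl)

    @classmethod
    def from_observations(cls, pid: str, hkl, intensity, pg: PointGroup,
                          sigma=None, source: str = "") -> "Pattern":
        """Canonicalize indices and average duplicates (Friedel mates etc.)."""
        hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        intensity = np.asarray(intensity, dtype=np.float64)
        if len(hkl) == 0:
            raise ValueError(f"pattern {pid}: no reflections")
        if np.any(~hkl.any(axis=1)):
            raise ValueError(f"pattern {pid}: (0,0,0) reflection")
        sig = None if sigma is None else np.asarray(sigma, dtype=np.float64)
        canon = asu_map(hkl, pg)
        canon, intensity, sig, n_merged = _merge_duplicates(
            canon, intensity, sig)
        if n_merged:
            log.debug("pattern %s: averaged %d duplicate observations",
                      pid, n_merged)
        return cls(pid, canon, intensity, sig, source=source)

    def reflections(self) -> Iterator[Reflection]:
        for i in range(len(self)):
            s = None if self.sigma is None else float(self.sigma[i])
            yield Reflection(MillerIndex(*map(int, self.hkl[i])),
                             float(self.intensity[i]), s)


@dataclass
class Dataset:
    """An ordered collection of patterns with unique ids."""

    patterns: list[Pattern]

    def __post_init__(self):
        ids = [p.id for p in self.patterns]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pattern ids in dataset")

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def subset(self, index: Sequence[int]) -> "Dataset":
        return Dataset([self.patterns[i] for i in index])


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must be in (0, 180) degrees")

    @classmethod
    def hexagonal(cls, a: float, c: float) -> "UnitCell":
        return cls(a, a, c, 90.0, 90.0, 120.0)

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G*; 1/d² = hᵀ G* h."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sa, sb, sg = (math.sin(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        v = (self.a * self.b * self.c
             * math.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg))
        a_s = self.b * self.c * sa / v
        b_s = self.a * self.c * sb / v
        c_s = self.a * self.b * sg / v
        ca_s = (cb * cg - ca) / (sb * sg)
        cb_s = (ca * cg - cb) / (sa * sg)
        cg_s = (ca * cb - cg) / (sa * sb)
        return np.array([
            [a_s**2, a_s * b_s * cg_s, a_s * c_s * cb_s],
            [a_s * b_s * cg_s, b_s**2, b_s * c_s * ca_s],
            [a_s * c_s * cb_s, b_s * c_s * ca_s, c_s**2],
        ])


def resolution_d(hkl, cell: UnitCell):
    """d-spacing (Å) of one index or an (N, 3) block, from hᵀ G* h.

    For hexagonal cells this reduces to
    1/d² = 4(h² + hk + k²)/(3a²) + l²/c².
    """
    a = np.asarray(hkl, dtype=np.float64)
    single = a.ndim == 1
    if single:
        if not a.any():
            raise ValueError("(0,0,0) has no resolution")
        a = a[None, :]
    g = cell.reciprocal_metric()
    inv_d2 = np.einsum("ni,ij,nj->n", a, g, a)
    if np.any(inv_d2 <= 0):
        raise ValueError("(0,0,0) has no resolution")
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if single else d


def shell_filter(indices, cell: UnitCell, d_min: float, d_max: float):
    """Indices with d_min <= d < d_max (half-open on the low-d edge).

    The half-open convention prevents double counting across adjacent
    shells.
    """
    if not 0 < d_min < d_max:
        raise ValueError("require 0 < d_min < d_max")
    a = np.asarray(indices, dtype=np.int64).reshape(-1, 3)
    d = resolution_d(a, cell)
    return a[(d >= d_min) & (d < d_max)]


@dataclass
class MergedModel:
    """The merged full-intensity model on the canonical reciprocal lattice.

    Column-parallel arrays keyed by canonical Miller index: running
    intensity sums, observation counts, and the Monte Carlo mean (the
    estimate of the full intensity).  Entries with ``n_obs == 0`` exist on
    the lattice but are invisible to correlations.
    """

    hkl: np.ndarray
    sum_intensity: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3)
        self.sum_intensity = np.asarray(self.sum_intensity, dtype=np.float64)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        if not (len(self.hkl) == len(self.sum_intensity) == len(self.n_obs)):
            raise ValueError("model column length mismatch")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def mean_intensity(self) -> np.ndarray:
        """Mean intensity per entry; NaN where nothing was observed."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_obs > 0,
                            self.sum_intensity / np.maximum(self.n_obs, 1),
                            np.nan)

    @classmethod
    def from_means(cls, hkl, means, n_obs=None) -> "MergedModel":
        hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        means = np.asarray(means, dtype=np.float64)
        n = (np.ones(len(hkl), dtype=np.int64) if n_obs is None
             else np.asarray(n_obs, dtype=np.int64))
        return cls(hkl, means * np.maximum(n, 1), n)

    def entries(self) -> dict[MillerIndex, tuple[float, int, float]]:
        """Mapping view: hkl -> (sum_intensity, n_obs, mean_intensity)."""
        means = self.mean_intensity
        return {
            MillerIndex(*map(int, self.hkl[i])):
            (float(self.sum_intensity[i]), int(self.n_obs[i]),
             float(means[i]))
            for i in range(len(self))
        }


# ---------------------------------------------------------------------------
# native reflection tables

_MODEL_FLOAT_FMT = "%.9g"


def _parse_table_lines(lines: Iterable[tuple[int, str]], path: str):
    """Yield (pattern_id_or_None, h, k, l, I, sigma) per data row."""
    for lineno, raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*pattern_id:\s*(\S+)", line)
            if m:
                yield ("__header__", m.group(1), lineno)
            continue
        parts = line.split()
        if len(parts) not in (4, 5):
            raise ValueError(
                f"{path}:{lineno}: expected 'h k l I [sigma]', got {line!r}")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            inten = float(parts[3])
            sig = float(parts[4]) if len(parts) == 5 else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
        yield ("__row__", (h, k, l, inten, sig), lineno)


def _patterns_from_table(text: str, path: str, pg: PointGroup,
                         default_id: str) -> list[Pattern]:
    blocks: list[tuple[str, list]] = []
    current_id, rows = None, []
    for kind, payload, lineno in _parse_table_lines(
            enumerate(text.splitlines(), start=1), path):
        if kind == "__header__":
            if rows:
                blocks.append((current_id or default_id, rows))
                rows = []
            current_id = payload
        else:
            rows.append(payload)
    if rows:
        blocks.append((current_id or default_id, rows))
    if not blocks:
        raise ValueError(f"{path}: no reflections")
    patterns = []
    for pid, rows in blocks:
        hkl = np.array([r[:3] for r in rows], dtype=np.int64)
        inten = np.array([r[3] for r in rows])
        sigs = [r[4] for r in rows]
        sigma = None if any(s is None for s in sigs) else np.array(sigs)
        patterns.append(Pattern.from_observations(
            pid, hkl, inten, pg, sigma=sigma, source=path))
    return patterns


def read_patterns(path, pg: PointGroup) -> Dataset:
    """Read a native table that may hold several ``# pattern_id:`` blocks."""
    p = Path(path)
    pats = _patterns_from_table(p.read_text(), str(p), pg, default_id=p.stem)
    return Dataset(pats)


def read_reflection_table(path, pg: PointGroup) -> Pattern:
    """Read a single-pattern native table.

    A ``# pattern_id: X`` header sets the id; otherwise the filename stem
    is used.  Duplicate canonical indices (e.g. Friedel mates with Friedel
    pairing on) are averaged.
    """
    ds = read_patterns(path, pg)
    if ds.n_patterns != 1:
        raise ValueError(
            f"{path}: holds {ds.n_patterns} patterns; use read_patterns()")
    return ds.patterns[0]


def write_pattern(pattern: Pattern, fh: io.TextIOBase) -> None:
    fh.write(f"# pattern_id: {pattern.id}\n")
    for i in range(len(pattern)):
        h, k, l = map(int, pattern.hkl[i])
        if pattern.sigma is None:
            fh.write(f"{h} {k} {l} {_MODEL_FLOAT_FMT % pattern.intensity[i]}\n")
        else:
            fh.write(f"{h} {k} {l} {_MODEL_FLOAT_FMT % pattern.intensity[i]} "
                     f"{_MODEL_FLOAT_FMT % pattern.sigma[i]}\n")


def write_dataset(ds: Dataset, path) -> None:
    """Write all patterns to one native table with pattern_id headers."""
    with open(path, "w") as fh:
        fh.write("# emdetwin reflection table: h k l I [sigma]\n")
        for pat in ds:
            write_pattern(pat, fh)


# ---------------------------------------------------------------------------
# CrystFEL stream subset

_CHUNK_BEGIN = "----- Begin chunk -----"
_CHUNK_END = "----- End chunk -----"
_REFL_BEGIN = "Reflections measured after indexing"
_REFL_END = "End of reflections"


def read_stream_subset(path, pg: PointGroup) -> Dataset:
    """Read the reflection tables out of a CrystFEL-style stream.

    Only chunk delimiters and reflection blocks are interpreted; the first
    four whitespace-separated columns of a reflection row are h, k, l, I.
    Chunks without a reflection block (no indexing solution) are skipped
    and counted; a chunk with an unparseable reflection row is skipped
    with a warning.
    """
    text = Path(path).read_text()
    if _CHUNK_BEGIN not in text:
        raise ValueError(f"{path}: no stream chunks found")
    patterns, n_skipped = [], 0
    chunks = text.split(_CHUNK_BEGIN)[1:]
    for idx, chunk in enumerate(chunks):
        chunk = chunk.split(_CHUNK_END)[0]
        if _REFL_BEGIN not in chunk:
            n_skipped += 1
            continue
        block = chunk.split(_REFL_BEGIN, 1)[1]
        block = block.split(_REFL_END, 1)[0]
        rows = []
        ok = True
        for line in block.splitlines():
            line = line.strip()
            if not line or line.startswith(("h ", "h\t")):
                continue  # column header line
            parts = line.split()
            if len(parts) < 4:
                ok = False
                break
            try:
                rows.append((int(parts[0]), int(parts[1]), int(parts[2]),
                             float(parts[3])))
            except ValueError:
                ok = False
                break
        if not ok or not rows:
            log.warning("%s: chunk %d has an unparseable reflection block; "
                        "skipped", path, idx)
            n_skipped += 1
            continue
        hkl = np.array([r[:3] for r in rows], dtype=np.int64)
        inten = np.array([r[3] for r in rows])
        patterns.append(Pattern.from_observations(
            f"chunk_{idx}", hkl, inten, pg, source=str(path)))
    if n_skipped:
        log.info("%s: skipped %d chunk(s) without usable reflections",
                 path, n_skipped)
    if not patterns:
        raise ValueError(f"{path}: no chunks with reflection blocks")
    return Dataset(patterns)


# ---------------------------------------------------------------------------
# merged-model files

def write_model(model: MergedModel, path, header_lines: Sequence[str] = ()):
    """Write ``h k l mean_intensity n_obs`` rows sorted by (h, k, l)."""
    if len(model) == 0:
        raise ValueError("refusing to write an empty model")
    order = np.lexsort((model.hkl[:, 2], model.hkl[:, 1], model.hkl[:, 0]))
    means = model.mean_intensity
    with open(path, "w") as fh:
        fh.write("# emdetwin merged model: h k l mean_intensity n_obs"
                 f" (floats as {_MODEL_FLOAT_FMT})\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for i in order:
            h, k, l = map(int, model.hkl[i])
            n = int(model.n_obs[i])
            mean = 0.0 if n == 0 else means[i]
            fh.write(f"{h} {k} {l} {_MODEL_FLOAT_FMT % mean} {n}\n")


def read_model(path) -> MergedModel:
    hkl, means, counts = [], [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 'h k l I n_obs'")
        hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
        means.append(float(parts[3]))
        counts.append(int(parts[4]))
    if not hkl:
        raise ValueError(f"{path}: empty model file")
    return MergedModel.from_means(np.array(hkl, dtype=np.int64),
                                  np.array(means), np.array(counts))
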