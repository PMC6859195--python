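"""Non-uniform sampling schedules for the indirect dimension.

A schedule is the sorted set of complex-point indices actually measured on
an ``n_points``-point Nyquist grid.  Two kinds are generated here: plain
uniform-random schedules, and Poisson-gap schedules in which the gaps
between successive sampled points follow Poisson distributions whose rate
grows sinusoidally across the grid — dense sampling of the early,
high-signal part of the decay and sparse sampling of the tail.  Index 0 is
always sampled so that downstream first-point normalisation is defined.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

__all__ = [
    "SamplingSchedule",
    "random_schedule",
    "poisson_gap_schedule",
    "read_schedule",
    "write_schedule",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SamplingSchedule:
    """Sorted unique sampled indices on an ``n_points`` grid."""

    indices: np.ndarray
    n_points: int
    kind: str = "custom"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("schedule must hold at least one index")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("schedule indices must be strictly increasing")
        if idx[0] != 0:
            raise ValueError("index 0 must be sampled (first-point anchor)")
        if idx[-1] >= self.n_points or idx[0] < 0:
            raise ValueError(
                f"indices must lie in [0, {self.n_points}), got "
                f"[{idx[0]}, {idx[-1]}]"
            )

    @property
    def sp(self) -> int:
        """Number of sampled complex points."""
        return int(self.indices.size)

    @property
    def fraction(self) -> float:
        """Sampling fraction sp / n_points."""
        return self.sp / self.n_points

    def mask(self) -> np.ndarray:
        """0/1 indicator vector of length ``n_points``."""
        m = np.zeros(self.n_points, dtype=np.float64)
        m[self.indices] = 1.0
        return m


def _check_sp(n_points: int, sp: int) -> None:
    if not 1 <= sp <= n_points:
        raise ValueError(f"need 1 <= sp <= n_points, got sp={sp}, "
                         f"n_points={n_points}")


def random_schedule(n_points: int, sp: int, seed) -> SamplingSchedule:
    """Uniform-random schedule: index 0 plus ``sp - 1`` indices drawn
    without replacement from {1, ..., n_points - 1}."""
    _check_sp(n_points, sp)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rest = rng.choice(np.arange(1, n_points), size=sp - 1, replace=False)
    idx = np.sort(np.concatenate([[0], rest]))
    return SamplingSchedule(indices=idx, n_points=n_points, kind="random")


def poisson_gap_schedule(
    n_points: int,
    sp: int,
    seed,
    max_trials: int = 20000,
) -> SamplingSchedule:
    """Poisson-gap schedule with sinusoidally modulated gap rates.

    Walking the grid from index 0, the gap after a point at position ``k``
    is drawn from Poisson(lam * sin(pi/2 * (k + 0.5) / n_points)), so gaps
    are small early and large late.  The global rate scale ``lam`` is
    adjusted multiplicatively between trials until a walk places exactly
    ``sp`` points inside the grid.
    """
    _check_sp(n_points, sp)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sp == n_points:
        return SamplingSchedule(indices=np.arange(n_points),
                                n_points=n_points, kind="poisson-gap")

    # initial scale: average gap needed is n_points/sp - 1, mean sine weight 2/pi
    lam = 2.0 * (n_points / sp - 1.0) / (2.0 / np.pi)
    for _ in range(max_trials):
        idx = []
        k = 0
        while k < n_points:
            idx.append(k)
            w = np.sin(0.5 * np.pi * (k + 0.5) / n_points)
            k += 1 + int(rng.poisson(lam * w))
        count = len(idx)
        if count == sp:
            return SamplingSchedule(indices=np.asarray(idx, dtype=np.int64),
                                    n_points=n_points, kind="poisson-gap")
        # too many points -> gaps too small -> raise lam (and vice versa);
        # damped multiplicative update keeps the walk converging
        lam *= (count / sp) ** 0.7
        lam = max(lam, 1e-6)
    raise RuntimeError(
        f"Poisson-gap rate adjustment did not hit sp={sp} within "
        f"{max_trials} trials"
    )


def write_schedule(schedule: SamplingSchedule, path) -> None:
    """Write one 0-based index per line."""
    with open(path, "w") as fh:
        for i in schedule.indices:
            fh.write(f"{int(i)}\n")


def read_schedule(path, n_points: int, one_based: bool = False) -> SamplingSchedule:
    """Read a schedule text file: one index per line, optional extra
    columns ignored.  ``one_based=True`` converts 1-based files (as
    written by some NUS tools) to the internal 0-based convention.
    Unsorted or duplicated input is normalised with a warning.
    """
    raw: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()[0]
            try:
                val = int(tok)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {ln}: non-integer index {tok!r}"
                ) from exc
            if val < 0:
                raise ValueError(f"{path}: line {ln}: negative index {val}")
            raw.append(val - 1 if one_based else val)
    arr = np.asarray(raw, dtype=np.int64)
    uniq = np.unique(arr)
    if uniq.size != arr.size or np.any(np.diff(arr) <= 0):
        logger.warning("schedule file %s was unsorted or contained "
                       "duplicates; normalised", path)
    return SamplingSchedule(indices=uniq, n_points=n_points, kind="custom")
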