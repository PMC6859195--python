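"""Synthetic free-induction-decay (FID) model and training-data generator.

A 1D NMR signal is modelled as a sum of exponentially decaying complex
sinusoids (Lorentzian lines).  Each component is fully characterised by four
parameters: an intensity ``I``, a phase ``phi`` (degrees), a transverse
relaxation rate ``R2`` (s^-1, setting the linewidth ``R2/pi`` in Hz) and a
frequency offset ``nu`` (Hz, relative to the carrier).  The time-domain
signal on an ``n_points``-point Nyquist grid with dwell time ``1/sw`` is

    x[j] = sum_k I_k * exp(i*phi_k) * exp((i*2*pi*nu_k - R2_k) * j / sw)

Training data for the reconstruction network are random FIDs drawn from
broad parameter distributions: the number of components is uniform between
1 and ``floor(3/8 * sp)`` where ``sp`` is the number of sampled complex
points (the 3/8 cap keeps the problem information-theoretically
well-posed: 2 complex points suffice per Lorentzian, and staying below
half of that bound guards against over-fitting), I ~ U(0, 1),
R2 ~ U(3, 100) s^-1, nu uniform over the full sweep width and
phi ~ U(-5, +5) degrees.  FIDs are normalised by the magnitude of their
first time point before use.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AxisMeta",
    "Signal",
    "Fid",
    "max_signal_count",
    "draw_signals",
    "synthesize_fid",
    "synthesize_batch",
    "normalize_fid",
    "extract_sparse",
    "stream_batches",
    "save_fid_batch",
    "load_fid_batch",
    "peak_position_space",
]

#: guard against dividing by a numerically-zero first point
EPS_FIRST_POINT = 1e-12

# Parameter ranges of the training distribution.
INTENSITY_RANGE = (0.0, 1.0)
R2_RANGE = (3.0, 100.0)  # s^-1
PHASE_RANGE_DEG = (-5.0, 5.0)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclasses.dataclass(frozen=True)
class AxisMeta:
    """Metadata of one spectral axis.

    Parameters
    ----------
    sw:
        Sweep (spectral) width in Hz.
    n_points:
        Number of complex points on the full Nyquist grid; a power of two
        so FFTs need no padding.
    obs:
        Observe (Larmor) frequency in MHz, used for Hz <-> ppm conversion.
    carrier:
        Carrier position in ppm (the centre of the spectral window).
    """

    sw: float
    n_points: int
    obs: float = 70.95
    carrier: float = 108.0

    def __post_init__(self) -> None:
        if self.sw <= 0:
            raise ValueError(f"sweep width must be positive, got {self.sw}")
        if self.n_points < 2 or not _is_power_of_two(self.n_points):
            raise ValueError(
                f"n_points must be a power of two >= 2, got {self.n_points}"
            )
        if self.obs <= 0:
            raise ValueError(f"observe frequency must be positive, got {self.obs}")

    @property
    def dt(self) -> float:
        """Dwell time (s) between successive complex points."""
        return 1.0 / self.sw


@dataclasses.dataclass(frozen=True)
class Signal:
    """One Lorentzian component of a 1D spectrum.

    intensity is dimensionless (0-1 in training data), phase in degrees,
    r2 the transverse relaxation rate in s^-1, freq the offset from the
    carrier in Hz.
    """

    intensity: float
    phase: float
    r2: float
    freq: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.r2 <= 0:
            raise ValueError("R2 must be > 0")

    @property
    def linewidth(self) -> float:
        """Full width at half height of the absorption line, R2/pi (Hz)."""
        return self.r2 / np.pi


@dataclasses.dataclass
class Fid:
    """A complex time-domain FID with its axis metadata.

    ``norm_factor`` stores the |first point| divided out by
    :func:`normalize_fid` so reconstructed data can be rescaled.
    """

    data: np.ndarray
    axis: AxisMeta
    normalised: bool = False
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1 or self.data.shape[0] != self.axis.n_points:
            raise ValueError(
                f"FID length {self.data.shape} does not match axis n_points "
                f"{self.axis.n_points}"
            )
        if self.normalised and abs(abs(self.data[0]) - 1.0) > 1e-9:
            raise ValueError("normalised FID must have |data[0]| == 1")


def max_signal_count(sp: int) -> int:
    """Largest number of signals allowed for a schedule of ``sp`` points.

    The cap is floor(3/8 * sp): two complex (four real) numbers determine
    one Lorentzian, so up to sp/2 components are identifiable from sp
    complex samples; 3/8 stays safely below that bound.
    """
    if sp < 3:
        raise ValueError(f"sp must be >= 3 (cap would be 0), got {sp}")
    return (3 * sp) // 8


def peak_position_space(n_points: int, n_peaks: int) -> float:
    """Number of distinct peak-position configurations at grid resolution.

    With ``n_peaks`` peaks each placed on one of ``n_points`` frequency
    bins (resolution sw/n_points), there are n_points**n_peaks
    position-only configurations — a measure of how large the space of
    possible spectra is relative to any finite training set.
    """
    if n_points < 1 or n_peaks < 1:
        raise ValueError("n_points and n_peaks must be >= 1")
    return float(n_points) ** n_peaks


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_signals(sp: int, axis: AxisMeta, seed) -> list[Signal]:
    """Draw a random signal list from the training distribution.

    The component count is uniform on {1, ..., max_signal_count(sp)};
    parameters are drawn independently per component (see module
    docstring).  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    cap = max_signal_count(sp)
    n = int(rng.integers(1, cap + 1))
    intens = rng.uniform(*INTENSITY_RANGE, size=n)
    r2 = rng.uniform(*R2_RANGE, size=n)
    freq = rng.uniform(-axis.sw / 2.0, axis.sw / 2.0, size=n)
    phase = rng.uniform(*PHASE_RANGE_DEG, size=n)
    return [
        Signal(intensity=float(intens[k]), phase=float(phase[k]),
               r2=float(r2[k]), freq=float(freq[k]))
        for k in range(n)
    ]


def synthesize_fid(signals: Sequence[Signal], axis: AxisMeta) -> Fid:
    """Evaluate the signal model on the full Nyquist grid of ``axis``."""
    if len(signals) == 0:
        raise ValueError("cannot synthesise an FID from an empty signal list")
    t = np.arange(axis.n_points) * axis.dt
    data = np.zeros(axis.n_points, dtype=np.complex128)
    for s in signals:
        phi = np.deg2rad(s.phase)
        data += s.intensity * np.exp(1j * phi) * np.exp(
            (1j * 2.0 * np.pi * s.freq - s.r2) * t
        )
    return Fid(data=data, axis=axis)


def synthesize_batch(n_fids: int, sp: int, axis: AxisMeta, seed) -> np.ndarray:
    """Vectorised batch synthesis of random FIDs.

    Returns a complex array of shape ``(n_fids, axis.n_points)`` whose rows
    are distributed identically to ``synthesize_fid(draw_signals(...))``
    (same generator stream ordering per FID).
    """
    rng = _as_rng(seed)
    cap = max_signal_count(sp)
    counts = np.empty(n_fids, dtype=np.int64)
    params = []  # (intensity, r2, freq, phase) per FID
    for i in range(n_fids):
        counts[i] = rng.integers(1, cap + 1)
        n = counts[i]
        params.append((
            rng.uniform(*INTENSITY_RANGE, size=n),
            rng.uniform(*R2_RANGE, size=n),
            rng.uniform(-axis.sw / 2.0, axis.sw / 2.0, size=n),
            rng.uniform(*PHASE_RANGE_DEG, size=n),
        ))
    # flatten all components and accumulate rows with one big outer product
    fid_idx = np.repeat(np.arange(n_fids), counts)
    intens = np.concatenate([p[0] for p in params])
    r2 = np.concatenate([p[1] for p in params])
    freq = np.concatenate([p[2] for p in params])
    phase = np.deg2rad(np.concatenate([p[3] for p in params]))
    t = np.arange(axis.n_points) * axis.dt
    comp = (intens * np.exp(1j * phase))[:, None] * np.exp(
        (1j * 2.0 * np.pi * freq - r2)[:, None] * t[None, :]
    )
    out = np.zeros((n_fids, axis.n_points), dtype=np.complex128)
    np.add.at(out, fid_idx, comp)
    return out


def normalize_fid(fid: Fid) -> Fid:
    """Divide an FID by the magnitude of its first point.

    The phase of the first point is untouched (division by a real scalar).
    Idempotent, and invariant to any prior real rescaling of the FID.
    """
    a0 = float(np.abs(fid.data[0]))
    if a0 <= EPS_FIRST_POINT:
        raise ValueError(
            f"|first point| = {a0:.3e} <= {EPS_FIRST_POINT}; empty or "
            "noise-only FID cannot be first-point normalised"
        )
    return Fid(
        data=fid.data / a0,
        axis=fid.axis,
        normalised=True,
        norm_factor=fid.norm_factor * a0,
    )


def extract_sparse(fid: Fid, schedule) -> np.ndarray:
    """Extract scheduled points as a 2 x sp real matrix.

    Row 0 holds the real parts and row 1 the imaginary parts at the
    scheduled indices, in ascending index order — the input layout the
    reconstruction network expects.
    """
    idx = np.asarray(schedule.indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= fid.axis.n_points):
        raise IndexError(
            f"schedule index out of range for n_points={fid.axis.n_points}"
        )
    pts = fid.data[idx]
    return np.vstack([pts.real, pts.imag])


def stream_batches(
    n_total: int,
    batch_size: int,
    sp: int,
    axis: AxisMeta,
    seed,
) -> Iterator[np.ndarray]:
    """Yield normalised FID batches, ``(batch, n_points)`` complex.

    Batching keeps memory flat regardless of ``n_total`` so arbitrarily
    large training streams can be produced on a desk machine.
    """
    rng = _as_rng(seed)
    done = 0
    while done < n_total:
        b = min(batch_size, n_total - done)
        raw = synthesize_batch(b, sp, axis, rng)
        a0 = np.abs(raw[:, 0])
        a0 = np.where(a0 > EPS_FIRST_POINT, a0, 1.0)
        yield raw / a0[:, None]
        done += b


def save_fid_batch(path, fids: np.ndarray, axis: AxisMeta, seed: int | None = None,
                   schedule_indices: np.ndarray | None = None) -> None:
    """Write a batch of FIDs to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=np.asarray(fids, dtype=np.complex128))
        if schedule_indices is not None:
            f.create_dataset("schedules", data=np.asarray(schedule_indices,
                                                          dtype=np.int64))
        f.attrs["sw"] = axis.sw
        f.attrs["n_points"] = axis.n_points
        f.attrs["obs"] = axis.obs
        f.attrs["carrier"] = axis.carrier
        if seed is not None:
            f.attrs["seed"] = seed


def load_fid_batch(path):
    """Read a batch written by :func:`save_fid_batch`.

    Returns ``(fids, axis, schedule_indices_or_None)``.
    """
    import h5py

    with h5py.File(path, "r") as f:
        fids = f["fids"][...]
        sched = f["schedules"][...] if "schedules" in f else None
        axis = AxisMeta(
            sw=float(f.attrs["sw"]),
            n_points=int(f.attrs["n_points"]),
            obs=float(f.attrs["obs"]),
            carrier=float(f.attrs["carrier"]),
        )
    return fids, axis, sched
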