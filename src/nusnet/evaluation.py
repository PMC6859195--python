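"""Quantitative comparison of reconstructed and fully sampled spectra.

Two complementary metrics:

* per-slice normalised RMSD — for every direct-dimension (1H) frequency
  point, the root-mean-square difference between the reconstructed and
  the fully sampled indirect slice, divided by the global maximum of the
  fully sampled spectrum; averaged over the amide region
  (6.5-9.6 ppm 1H by default) this gives <RMSD>_spec;
* peak-intensity fidelity — peak heights refined by three-point parabolic
  interpolation in each dimension, each list normalised by its own
  maximum, compared as an RMSD (in %) and a squared Pearson correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .reconstruction import FREQ, Spectrum2D, bin_to_ppm, ppm_to_bin

__all__ = [
    "EvalReport",
    "slice_rmsd",
    "region_average_rmsd",
    "peak_height",
    "match_peaks",
    "intensity_comparison",
    "summarize",
    "evaluate_pair",
]


@dataclasses.dataclass
class EvalReport:
    """Per-spectrum evaluation results."""

    slice_ppm: np.ndarray  # direct-dimension ppm of every slice
    slice_rmsds: np.ndarray  # normalised RMSD per slice (fraction)
    region_rmsd: float  # <RMSD>_spec over the evaluation region
    peak_table: list  # (id, ppm_h, ppm_n, height_full, height_recon)
    intensity_rmsd_pct: float
    pearson_r2: float


def slice_rmsd(recon_slice: np.ndarray, full_slice: np.ndarray,
               norm: float) -> float:
    """Root-mean-square difference of two slices divided by ``norm``.

    ``norm`` is conventionally the global maximum of the fully sampled
    frequency-domain spectrum, making values comparable across slices.
    """
    recon_slice = np.asarray(recon_slice, dtype=np.float64)
    full_slice = np.asarray(full_slice, dtype=np.float64)
    if recon_slice.shape != full_slice.shape:
        raise ValueError("slice length mismatch")
    if norm <= 0:
        raise ValueError("norm must be positive")
    return float(np.sqrt(np.mean((recon_slice - full_slice) ** 2)) / norm)


def _check_freq_pair(recon: Spectrum2D, full: Spectrum2D) -> None:
    if recon.direct_domain != FREQ or recon.indirect_domain != FREQ or \
            full.direct_domain != FREQ or full.indirect_domain != FREQ:
        raise ValueError("both spectra must be fully frequency-domain")
    if recon.data.shape != full.data.shape:
        raise ValueError("spectra shapes differ")


def region_average_rmsd(recon: Spectrum2D, full: Spectrum2D,
                        ppm_lo: float = 6.5, ppm_hi: float = 9.6) -> float:
    """Mean per-slice normalised RMSD over a direct-dimension ppm window."""
    _check_freq_pair(recon, full)
    ppm = bin_to_ppm(full.direct, np.arange(full.data.shape[0]))
    sel = (ppm >= ppm_lo) & (ppm <= ppm_hi)
    if not np.any(sel):
        raise ValueError(
            f"no direct-dimension points in [{ppm_lo}, {ppm_hi}] ppm")
    norm = float(np.max(full.data))
    rmsds = [slice_rmsd(recon.data[i], full.data[i], norm)
             for i in np.nonzero(sel)[0]]
    return float(np.mean(rmsds))


def _parabolic_1d(ym1: float, y0: float, yp1: float) -> tuple[float, float]:
    """Vertex offset (in bins, |delta| <= 0.5 for a local max) and the
    peak-value correction of the parabola through three points."""
    denom = ym1 - 2.0 * y0 + yp1
    if denom >= 0.0 or abs(denom) < 1e-300:  # not a local max / flat
        return 0.0, 0.0
    delta = 0.5 * (ym1 - yp1) / denom
    corr = -0.125 * (ym1 - yp1) ** 2 / denom
    return delta, corr


def peak_height(spec: Spectrum2D, approx_ppm_h: float, approx_ppm_n: float,
                search: int = 1):
    """Refine a peak position and interpolate its height.

    Finds the grid maximum within a (2*search+1)^2 box around the given
    approximate position, then applies three-point parabolic interpolation
    independently in each dimension (the standard peak-centering
    refinement).  Returns ``((ppm_h, ppm_n), height)`` or ``None`` when
    the box contains no interior local maximum.
    """
    if spec.direct_domain != FREQ or spec.indirect_domain != FREQ:
        raise ValueError("peak heights are measured on frequency-domain data")
    bh = int(round(float(ppm_to_bin(spec.direct, approx_ppm_h))))
    bn = int(round(float(ppm_to_bin(spec.indirect, approx_ppm_n))))
    nd, nn = spec.data.shape
    if not (0 <= bh < nd and 0 <= bn < nn):
        return None
    lo_h, hi_h = max(bh - search, 1), min(bh + search, nd - 2)
    lo_n, hi_n = max(bn - search, 1), min(bn + search, nn - 2)
    if lo_h > hi_h or lo_n > hi_n:
        return None
    box = spec.data[lo_h:hi_h + 1, lo_n:hi_n + 1]
    ih, in_ = np.unravel_index(np.argmax(box), box.shape)
    ih += lo_h
    in_ += lo_n
    y0 = spec.data[ih, in_]
    # must be a local maximum of the grid in both dimensions
    if not (y0 >= spec.data[ih - 1, in_] and y0 >= spec.data[ih + 1, in_] and
            y0 >= spec.data[ih, in_ - 1] and y0 >= spec.data[ih, in_ + 1]):
        return None
    dh, ch = _parabolic_1d(spec.data[ih - 1, in_], y0, spec.data[ih + 1, in_])
    dn, cn = _parabolic_1d(spec.data[ih, in_ - 1], y0, spec.data[ih, in_ + 1])
    if ch == 0.0 and cn == 0.0 and (
            y0 == spec.data[ih - 1, in_] or y0 == spec.data[ih + 1, in_] or
            y0 == spec.data[ih, in_ - 1] or y0 == spec.data[ih, in_ + 1]):
        return None  # flat plateau, no defined maximum
    height = float(y0 + ch + cn)
    pos = (float(bin_to_ppm(spec.direct, ih + dh)),
           float(bin_to_ppm(spec.indirect, in_ + dn)))
    return pos, height


def match_peaks(spec: Spectrum2D, positions, tol_h: float = 0.1,
                tol_n: float = 0.5):
    """Measure peaks of ``spec`` near the given (ppm_h, ppm_n) positions.

    A measurement is kept when the refined position stays within the
    tolerance box of the requested one.  Returns a list parallel to
    ``positions`` with ``(refined_position, height)`` or ``None``.
    """
    out = []
    for (ph, pn) in positions:
        res = peak_height(spec, ph, pn)
        if res is not None:
            (rh, rn), _ = res
            if abs(rh - ph) > tol_h or abs(rn - pn) > tol_n:
                res = None
        out.append(res)
    return out


def intensity_comparison(heights_full, heights_recon) -> tuple[float, float]:
    """Normalised-intensity RMSD (%) and squared Pearson correlation.

    Each height list is normalised by its own maximum first, so the
    comparison is invariant to any common rescaling of either spectrum.
    """
    hf = np.asarray(heights_full, dtype=np.float64)
    hr = np.asarray(heights_recon, dtype=np.float64)
    if hf.shape != hr.shape or hf.ndim != 1:
        raise ValueError("height lists must be 1-D and the same length")
    if hf.size < 2:
        raise ValueError("correlation is undefined for fewer than 2 peaks")
    if hf.max() <= 0 or hr.max() <= 0:
        raise ValueError("height lists must contain positive maxima")
    nf = hf / hf.max()
    nr = hr / hr.max()
    rmsd_pct = float(np.sqrt(np.mean((nf - nr) ** 2)) * 100.0)
    r = np.corrcoef(nf, nr)[0, 1]
    return rmsd_pct, float(r ** 2)


def evaluate_pair(recon: Spectrum2D, full: Spectrum2D, peak_positions,
                  ppm_lo: float = 6.5, ppm_hi: float = 9.6) -> EvalReport:
    """Full evaluation of one reconstruction against the full spectrum."""
    _check_freq_pair(recon, full)
    ppm = bin_to_ppm(full.direct, np.arange(full.data.shape[0]))
    norm = float(np.max(full.data))
    rmsds = np.array([slice_rmsd(recon.data[i], full.data[i], norm)
                      for i in range(full.data.shape[0])])
    region = region_average_rmsd(recon, full, ppm_lo, ppm_hi)

    m_full = match_peaks(full, peak_positions)
    m_recon = match_peaks(recon, peak_positions)
    table = []
    hf, hr = [], []
    for k, (pos, mf, mr) in enumerate(zip(peak_positions, m_full, m_recon)):
        if mf is None or mr is None:
            continue
        table.append((k, pos[0], pos[1], mf[1], mr[1]))
        hf.append(mf[1])
        hr.append(mr[1])
    if len(hf) >= 2:
        rmsd_pct, r2 = intensity_comparison(hf, hr)
    else:
        rmsd_pct, r2 = float("nan"), float("nan")
    return EvalReport(slice_ppm=ppm, slice_rmsds=rmsds, region_rmsd=region,
                      peak_table=table, intensity_rmsd_pct=rmsd_pct,
                      pearson_r2=r2)


def summarize(replicates) -> dict:
    """Mean and sample standard deviation of the scalar metrics across
    schedule realisations (error bars over replicate reconstructions)."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to summarise")
    out = {}
    for name in ("region_rmsd", "intensity_rmsd_pct", "pearson_r2"):
        vals = np.array([getattr(r, name) for r in replicates],
                        dtype=np.float64)
        out[name] = {"mean": float(np.mean(vals)),
                     "sd": float(np.std(vals, ddof=1))}
    return out
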