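"""Quadrature reconstruction, complex-signal assembly, and quantitative
metrics (extinction ratio, peak height/width preservation, noise floor).

Axis-orientation convention
---------------------------
With the channel conventions of :mod:`quadcal.sim_forward` (inter-channel
phase offset ``+pi/2``) the assembled complex signal ``s_I + 1j * s_Q`` puts
a reflector's main peak at the *negative* of its depth.  The depth profile is
therefore computed from the conjugate, ``s_I - 1j * s_Q``, so that the main
peak of a reflector at ``zbar`` appears at ``+zbar`` and its residual mirror
artifact at ``-zbar``.  Extinction numbers are unaffected by this choice.

Two extinction flavours are exposed:

* :func:`extinction_ratio` reports ``main_db - mirror_db`` on a single
  profile (the peak-over-residual ratio);
* :func:`mirror_suppression` reports the original mirror peak of a
  real-signal reference profile over the residual mirror peak of the
  reconstructed profile (the attenuation of the artifact itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibrationConfig, CorrectionSet, calibrate
from .errors import GridMismatchError, IllConditionedError, WeakPeakError
from .preprocess import MirrorMeasurement, coherent_average
from .sim_forward import (
    HALF_PI,
    ChannelImbalance,
    KGrid,
    NoiseJitterSpec,
    RawBatch,
    simulate_mirror_sweep,
)

__all__ = [
    "DepthProfile",
    "ExtinctionReport",
    "QuadratureError",
    "quadrature_geometry",
    "reconstruct_quadrature",
    "reconstruct_aline",
    "reconstruct_measurement",
    "extinction_ratio",
    "mirror_suppression",
    "analytic_extinction",
    "peak_shape_metrics",
    "evaluate_sweep",
    "summarize_extinction",
    "sampling_density_study",
]


def _db(x) -> np.ndarray:
    return 20.0 * np.log10(np.maximum(np.abs(x), 1e-300))


@dataclass
class DepthProfile:
    """Complex depth-domain A-line on the centered normalized depth axis."""

    values: np.ndarray
    zbar: np.ndarray

    def db(self, ref: float | None = None) -> np.ndarray:
        """Magnitude in dB relative to ``ref`` (default: the profile max)."""
        if ref is None:
            ref = float(np.max(np.abs(self.values)))
        return _db(self.values) - _db(ref)

    @property
    def N(self) -> int:
        return self.values.size


@dataclass
class ExtinctionReport:
    """Main-vs-mirror peak metrics of one depth profile."""

    main_db: float
    mirror_db: float
    extinction_db: float
    main_pos: float
    mirror_pos: float
    fwhm_bins: float
    noise_floor_db: float


@dataclass(frozen=True)
class QuadratureError:
    """Small amplitude/phase deviation from perfect quadrature."""

    amp_mismatch: float = 0.0  # relative: (A_II - A_I) / A_I
    phase_offset: float = 0.0  # radians

    def __post_init__(self):
        if self.amp_mismatch <= -1.0:
            raise ValueError("amp_mismatch must be > -1")


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------


def quadrature_geometry(
    beta: float, dphi: float, min_sin: float = 0.1
) -> tuple[float, float]:
    """Linear-combination coefficients (a, b) with ``s_Q = a*s_II - b*s_I``.

    ``a = beta / sin(dphi)``, ``b = cos(dphi) / sin(dphi)``.  Valid for any
    phase delay away from 0 and pi (e.g. the 120-degree case of 3x3
    couplers); raises :class:`IllConditionedError` below ``min_sin``.
    """
    s = math.sin(dphi)
    if abs(s) < min_sin:
        raise IllConditionedError(f"|sin(dphi)| = {abs(s):.3g} < {min_sin}")
    return beta / s, math.cos(dphi) / s


def reconstruct_quadrature(
    s_I: np.ndarray,
    s_II_corr: np.ndarray,
    beta_k: np.ndarray,
    dphi_k: np.ndarray,
    min_sin: float = 0.1,
) -> np.ndarray:
    """Pointwise perfect-quadrature component from the two real channels.

    ``s_Q = (beta_k * s_II_corr - cos(dphi_k) * s_I) / sin(dphi_k)``.
    """
    s_I = np.asarray(s_I, dtype=float)
    s_II_corr = np.asarray(s_II_corr, dtype=float)
    if s_I.shape != s_II_corr.shape:
        raise GridMismatchError("channel vectors differ in shape")
    sin_d = np.sin(dphi_k)
    if np.min(np.abs(sin_d)) < min_sin:
        raise IllConditionedError("sin(dphi_k) too close to zero")
    return (beta_k * s_II_corr - np.cos(dphi_k) * s_I) / sin_d


def reconstruct_aline(
    s_I: np.ndarray,
    s_II: np.ndarray,
    cs: CorrectionSet | None = None,
    mode: str = "calibrated",
) -> DepthProfile:
    """Depth profile of one A-line.

    ``standard``   FFT of channel I alone (mirror-symmetric, full artifact);
    ``direct``     complex assembly of the two channels without corrections;
    ``calibrated`` spatial correction of channel II, quadrature
                   reconstruction, then complex assembly.
    """
    s_I = np.asarray(s_I, dtype=float)
    s_II = np.asarray(s_II, dtype=float)
    N = s_I.size
    if s_II.size != N:
        raise GridMismatchError("channel vectors differ in length")

    if mode == "standard":
        values = np.fft.fftshift(np.fft.fft(s_I))
        zbar = _zbar_for(N, cs)
        return DepthProfile(values=values, zbar=zbar)
    if mode == "direct":
        values = np.fft.fftshift(np.fft.fft(s_I - 1j * s_II))
        zbar = _zbar_for(N, cs)
        return DepthProfile(values=values, zbar=zbar)
    if mode != "calibrated":
        raise ValueError(f"unknown mode {mode!r}")

    if cs is None:
        raise GridMismatchError("calibrated mode requires a CorrectionSet")
    if cs.grid.N != N:
        raise GridMismatchError(
            f"corrections were computed for N={cs.grid.N}, data has N={N}"
        )
    spatial, a_k, b_k = cs.precomputed()
    s_ii_corr = np.real(np.fft.ifft(np.fft.fft(s_II) * spatial))
    s_q = a_k * s_ii_corr - b_k * s_I
    values = np.fft.fftshift(np.fft.fft(s_I - 1j * s_q))
    return DepthProfile(values=values, zbar=cs.grid.zbar)


def _zbar_for(N: int, cs: CorrectionSet | None) -> np.ndarray:
    if cs is not None and cs.grid.N == N:
        return cs.grid.zbar
    from .sim_forward import zbar_axis

    return zbar_axis(N)


def reconstruct_measurement(
    m: MirrorMeasurement, cs: CorrectionSet | None = None, mode: str = "calibrated"
) -> DepthProfile:
    """Reconstruct a (single-reflector) mirror measurement.

    When the measurement's side of zero-delay is known, the spatial stage
    acts on the side-aware analytic signal — numerically equivalent to
    :func:`reconstruct_aline` for Hermitian-symmetric correction vectors and
    exactly gauge-covariant (the c/psi gauge freedom of a
    :class:`CorrectionSet` drops out identically).
    """
    if (
        mode != "calibrated"
        or cs is None
        or m.nominal_side not in ("positive", "negative")
    ):
        return reconstruct_aline(m.s_I, m.s_II, cs, mode=mode)
    if cs.grid.N != m.grid.N:
        raise GridMismatchError(
            f"corrections were computed for N={cs.grid.N}, data has N={m.grid.N}"
        )
    from .preprocess import analytic_representation

    spatial, a_k, b_k = cs.precomputed()
    a_ii = analytic_representation(m.s_II, m.nominal_side)
    s_ii_corr = np.real(np.fft.ifft(np.fft.fft(a_ii) * spatial))
    s_q = a_k * s_ii_corr - b_k * m.s_I
    values = np.fft.fftshift(np.fft.fft(m.s_I - 1j * s_q))
    return DepthProfile(values=values, zbar=cs.grid.zbar)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _nearest_index(zbar: np.ndarray, pos: float) -> int:
    return int(np.argmin(np.abs(zbar - pos)))


def _search_peak(
    mag: np.ndarray, center: int, window: int, exclude: np.ndarray
) -> int:
    lo = max(0, center - window)
    hi = min(mag.size, center + window + 1)
    region = np.arange(lo, hi)
    region = region[~np.isin(region, exclude)]
    if region.size == 0:
        raise WeakPeakError("peak search window fully excluded")
    return int(region[np.argmax(mag[region])])


def _fwhm_bins(mag: np.ndarray, idx: int) -> float:
    """Full width at half maximum around ``idx``, linear interpolation."""
    half = mag[idx] / 2.0

    def crossing(step: int) -> float:
        j = idx
        while 0 < j + step < mag.size - 1 and mag[j + step] >= half:
            j += step
        j2 = j + step
        if not (0 <= j2 < mag.size):
            return abs(j - idx) + 0.5
        lo, hi = mag[j2], mag[j]
        frac = (hi - half) / (hi - lo) if hi > lo else 0.5
        return abs(j - idx) + frac

    return crossing(-1) + crossing(+1)


def _floor_db(mag: np.ndarray, peaks: list[int], guard: int = 10) -> float:
    mask = np.ones(mag.size, dtype=bool)
    for p in peaks:
        lo, hi = max(0, p - guard), min(mag.size, p + guard + 1)
        mask[lo:hi] = False
    if not mask.any():
        return float("nan")
    return float(_db(np.median(mag[mask])))


def extinction_ratio(
    p: DepthProfile,
    main_pos: float,
    search_bins: int = 3,
    dc_exclusion_bins: int = 1,
    floor_guard_bins: int = 10,
    min_above_floor_db: float = 10.0,
) -> ExtinctionReport:
    """Main-vs-mirror peak report for a single-reflector depth profile.

    The mirror peak is searched within ``search_bins`` of the reflected main
    position; zero-delay and ``dc_exclusion_bins`` on either side are
    excluded from all searches.  Raises :class:`WeakPeakError` when the main
    peak is less than ``min_above_floor_db`` above the floor.
    """
    mag = np.abs(p.values)
    N = mag.size
    dc = N // 2
    excluded = np.arange(dc - dc_exclusion_bins, dc + dc_exclusion_bins + 1)

    main_idx = _search_peak(mag, _nearest_index(p.zbar, main_pos), search_bins,
                            excluded)
    mirror_idx = _search_peak(
        mag, _nearest_index(p.zbar, -p.zbar[main_idx]), search_bins, excluded
    )
    main_db = float(_db(mag[main_idx]))
    mirror_db = float(_db(mag[mirror_idx]))
    floor_db = _floor_db(mag, [main_idx, mirror_idx], floor_guard_bins)
    if main_db < floor_db + min_above_floor_db:
        raise WeakPeakError(
            f"main peak {main_db:.1f} dB < floor {floor_db:.1f} dB + "
            f"{min_above_floor_db} dB"
        )
    return ExtinctionReport(
        main_db=main_db,
        mirror_db=mirror_db,
        extinction_db=main_db - mirror_db,
        main_pos=float(p.zbar[main_idx]),
        mirror_pos=float(p.zbar[mirror_idx]),
        fwhm_bins=_fwhm_bins(mag, main_idx),
        noise_floor_db=floor_db,
    )


def mirror_suppression(
    reconstructed: DepthProfile,
    reference: DepthProfile,
    main_pos: float | None = None,
    search_bins: int = 3,
    dc_exclusion_bins: int = 1,
) -> float:
    """Attenuation (dB) of the mirror peak relative to real-signal processing.

    Ratio of the reference profile's mirror peak (standard single-channel
    processing, where main and mirror are equal) over the reconstructed
    profile's residual at the mirrored position.
    """
    mag_rec = np.abs(reconstructed.values)
    mag_ref = np.abs(reference.values)
    N = mag_rec.size
    dc = N // 2
    excluded = np.arange(dc - dc_exclusion_bins, dc + dc_exclusion_bins + 1)
    if main_pos is None:
        allowed = np.setdiff1d(np.arange(N), excluded)
        main_idx = int(allowed[np.argmax(mag_rec[allowed])])
    else:
        main_idx = _search_peak(
            mag_rec, _nearest_index(reconstructed.zbar, main_pos), search_bins,
            excluded
        )
    mirror_center = _nearest_index(
        reconstructed.zbar, -reconstructed.zbar[main_idx]
    )
    ref_mirror = _search_peak(mag_ref, mirror_center, search_bins, excluded)
    res_mirror = _search_peak(mag_rec, mirror_center, search_bins, excluded)
    return float(_db(mag_ref[ref_mirror]) - _db(mag_rec[res_mirror]))


def analytic_extinction(err: QuadratureError) -> float:
    """Closed-form extinction (dB) for a small quadrature error.

    Amplitude-only: ``20*log10(1/|eps|)``; phase-only: ``20*log10(2/|dphi|)``;
    combined errors add as the complex residual ``eps + 1j*dphi/2``.  Zero
    error returns ``+inf``.
    """
    residual = abs(complex(err.amp_mismatch, err.phase_offset / 2.0))
    if residual == 0.0:
        return float("inf")
    return float(-20.0 * math.log10(residual))


def peak_shape_metrics(
    p: DepthProfile,
    reference: DepthProfile,
    dc_exclusion_bins: int = 1,
    floor_guard_bins: int = 10,
) -> tuple[float, float, float]:
    """(height gain dB, FWHM difference in bins, floor difference dB) of a
    profile against a single-channel reference profile."""
    if p.N != reference.N:
        raise GridMismatchError("profiles must share a grid")
    N = p.N
    dc = N // 2
    excluded = np.arange(dc - dc_exclusion_bins, dc + dc_exclusion_bins + 1)
    allowed = np.setdiff1d(np.arange(N), excluded)

    def main_of(mag: np.ndarray) -> int:
        return int(allowed[np.argmax(mag[allowed])])

    mag_p, mag_r = np.abs(p.values), np.abs(reference.values)
    ip, ir = main_of(mag_p), main_of(mag_r)
    height_gain = float(_db(mag_p[ip]) - _db(mag_r[ir]))
    fwhm_delta = _fwhm_bins(mag_p, ip) - _fwhm_bins(mag_r, ir)
    floor_p = _floor_db(mag_p, [ip, N - 1 - ip if ip != dc else ip],
                        floor_guard_bins)
    floor_r = _floor_db(mag_r, [ir, N - 1 - ir if ir != dc else ir],
                        floor_guard_bins)
    return height_gain, float(fwhm_delta), float(floor_p - floor_r)


# ---------------------------------------------------------------------------
# Sweep evaluation and study designs
# ---------------------------------------------------------------------------


def evaluate_sweep(
    sweep: list[RawBatch],
    cs: CorrectionSet,
    mode: str = "calibrated",
) -> pd.DataFrame:
    """Per-depth extinction reports for a (held-out) mirror sweep."""
    rows = []
    for batch in sweep:
        m = coherent_average(batch)
        profile = reconstruct_measurement(m, cs, mode=mode)
        if batch.truth is not None:
            main_pos = float(batch.truth.reflectors.depths[0])
        else:
            mag = np.abs(profile.values)
            dc = profile.N // 2
            mag = mag.copy()
            mag[dc - 1 : dc + 2] = 0.0
            main_pos = float(profile.zbar[int(np.argmax(mag))])
        rep = extinction_ratio(profile, main_pos)
        rows.append(
            {
                "zbar_true": main_pos,
                "main_db": rep.main_db,
                "mirror_db": rep.mirror_db,
                "extinction_db": rep.extinction_db,
                "main_pos": rep.main_pos,
                "mirror_pos": rep.mirror_pos,
                "fwhm_bins": rep.fwhm_bins,
                "noise_floor_db": rep.noise_floor_db,
            }
        )
    return pd.DataFrame(rows)


def summarize_extinction(
    table: pd.DataFrame, inner_range: float = HALF_PI / 2.0
) -> pd.DataFrame:
    """Median/min extinction over the inner (optimal) and full ranges."""
    if table.empty:
        return pd.DataFrame(
            columns=["range", "n", "median_db", "min_db", "max_db"]
        )
    inner = table[np.abs(table["zbar_true"]) <= inner_range]
    rows = []
    for name, t in (("inner", inner), ("full", table)):
        if len(t) == 0:
            continue
        rows.append(
            {
                "range": name,
                "n": len(t),
                "median_db": float(t["extinction_db"].median()),
                "min_db": float(t["extinction_db"].min()),
                "max_db": float(t["extinction_db"].max()),
            }
        )
    return pd.DataFrame(rows)


def sampling_density_study(
    imb: ChannelImbalance,
    grid: KGrid,
    depth_counts: list[int],
    seeds: list[int],
    heldout_depths: list[float],
    M: int = 2,
    noise_sigma: float = 0.0,
    jitter: float = 0.0,
    span: float = 0.95,
    config: CalibrationConfig | None = None,
    sim_mode: str = "exact",
) -> pd.DataFrame:
    """Held-out extinction versus the number of calibration depths.

    For each seed and calibration depth count, a fresh sweep is simulated,
    calibrated, and evaluated on the shared held-out depths.  Returns a
    long-form table with one row per (seed, count, held-out depth).
    """
    cfg = config or CalibrationConfig()
    rows = []
    for seed in seeds:
        for count in depth_counts:
            depths = uniform_depth_bins(grid, count, span=span)
            nj = NoiseJitterSpec(noise_sigma=noise_sigma, jitter=jitter, seed=seed)
            sweep = simulate_mirror_sweep(imb, grid, nj, depths, M, mode=sim_mode)
            cs = calibrate(sweep, cfg)
            nj_h = NoiseJitterSpec(
                noise_sigma=noise_sigma, jitter=jitter, seed=seed + 7919
            )
            heldout = simulate_mirror_sweep(
                imb, grid, nj_h, heldout_depths, M, mode=sim_mode
            )
            table = evaluate_sweep(heldout, cs)
            for _, rec in table.iterrows():
                rows.append(
                    {
                        "seed": seed,
                        "n_depths": count,
                        "zbar_true": rec["zbar_true"],
                        "extinction_db": rec["extinction_db"],
                    }
                )
    return pd.DataFrame(rows)


def uniform_depth_bins(
    grid: KGrid, count: int, span: float = 0.95, exclude_bins: int = 3
) -> list[float]:
    """``count`` integer-bin depths spread evenly over ``±span * pi/2``,
    skipping the zero-delay exclusion zone."""
    half_bins = int(span * HALF_PI / grid.zbar_spacing)
    candidates = np.arange(-half_bins, half_bins + 1)
    candidates = candidates[np.abs(candidates) > exclude_bins]
    idx = np.unique(np.round(np.linspace(0, candidates.size - 1, count)).astype(int))
    return [float(b * grid.zbar_spacing) for b in candidates[idx]]
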