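"""Calibration pipeline: per-depth amplitude-ratio / phase-offset extraction,
wavenumber fits, spatial-vector fitting with gauge normalization, spatial
correction, and chromatic-vector averaging.

The product is a :class:`CorrectionSet` holding four vectors:

* ``beta_z(zbar)``, ``dphi_z(zbar)`` — depth-dependent (RF) corrections,
  gauge-normalized so ``beta_z = 1`` and ``dphi_z = 0`` at zero-delay;
* ``beta_k(k)``, ``dphi_k(k)`` — chromatic corrections measured after the
  spatial correction has been applied.

Only the products ``beta_k * beta_z`` and sums ``dphi_k + dphi_z`` are
physical; the split carries a one-parameter gauge freedom fixed by the
zero-delay normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import (
    AmbiguousPeakError,
    CoverageError,
    DivisionGuardError,
    GaugeError,
    IllConditionedError,
    NoUsableDepthsError,
    UnderdeterminedError,
)
from .preprocess import (
    AnalyticPair,
    MirrorMeasurement,
    analytic_representation,
    coherent_average,
    extract_amplitude_phase,
    remove_background,
)
from .sim_forward import HALF_PI, KGrid, RawBatch

__all__ = [
    "DepthSample",
    "CorrectionSet",
    "CalibrationConfig",
    "locate_peak",
    "compute_beta_dphi",
    "fit_along_k",
    "fit_spatial_vectors",
    "apply_spatial_correction",
    "compute_chromatic_vectors",
    "calibrate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunable parameters of the calibration pipeline."""

    k_fit_method: str = "polynomial"  # or "smoothing-spline"
    k_poly_degree: int = 7
    k_spline_lam: float | None = None
    z_fit_method: str = "spline"  # or "polynomial", "smoothing-spline"
    z_poly_degree: int = 5
    z_spline_lam: float | None = None
    edge_fraction: float = 0.05  # distrusted spectral samples per edge
    z_edge_fraction: float = 0.02  # excluded zbar extremes per side
    dc_exclusion_bins: float = 3.0  # |zbar| < bins * spacing excluded
    outlier_mad: float = 5.0
    min_sin_dphi: float = 0.1
    max_depth_gap: float | None = None  # zbar units; warn when exceeded


@dataclass
class DepthSample:
    """Fitted beta(k) and dphi(k) from one mirror depth."""

    zbar_peak: float
    side: str
    beta_k: np.ndarray
    dphi_k: np.ndarray
    quality: float


@dataclass
class CorrectionSet:
    """Calibration product: spatial and chromatic correction vectors."""

    beta_z: np.ndarray
    dphi_z: np.ndarray
    beta_k: np.ndarray
    dphi_k: np.ndarray
    grid: KGrid
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._factors = None

    def validate(self, min_sin_dphi: float = 0.1) -> None:
        c = self.grid.N // 2
        if abs(self.beta_z[c] - 1.0) > 1e-6 or abs(self.dphi_z[c]) > 1e-6:
            raise GaugeError("spatial vectors are not normalized at zero-delay")
        if np.any(self.beta_k <= 0) or np.any(self.beta_z <= 0):
            raise GaugeError("amplitude corrections must be strictly positive")
        if np.min(np.abs(np.sin(self.dphi_k))) < min_sin_dphi:
            raise IllConditionedError("sin(dphi_k) too close to zero")

    def gauge_shift(self, c: float, psi: float) -> "CorrectionSet":
        """Return the gauge-equivalent set (c*beta_z, beta_k/c, dphi_z+psi,
        dphi_k-psi).  Used to assert gauge invariance; the result deliberately
        violates the zero-delay normalization."""
        return replace(
            self,
            beta_z=self.beta_z * c,
            beta_k=self.beta_k / c,
            dphi_z=self.dphi_z + psi,
            dphi_k=self.dphi_k - psi,
        )

    def precomputed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recurring factors: spatial phasor (standard FFT order), and the
        chromatic a/b coefficients of the quadrature reconstruction."""
        if self._factors is None:
            spatial = np.fft.ifftshift(self.beta_z * np.exp(-1j * self.dphi_z))
            sin_d = np.sin(self.dphi_k)
            a_k = self.beta_k / sin_d
            b_k = np.cos(self.dphi_k) / sin_d
            self._factors = (spatial, a_k, b_k)
        return self._factors


# ---------------------------------------------------------------------------
# Per-depth extraction
# ---------------------------------------------------------------------------


def locate_peak(pair: AnalyticPair, grid: KGrid) -> tuple[float, str, float]:
    """Sub-bin peak position of a single-reflector measurement.

    Uses a three-point log-parabolic (Gaussian) interpolation around the
    argmax of the mean depth-domain magnitude of the two channels.  A Hann
    window is applied first: the interpolation is strongly biased on the
    sidelobe-heavy spectrum of an unwindowed tone, and near-exact on the
    smooth windowed main lobe.  Returns ``(zbar_peak, side, quality_db)``.
    """
    window = np.hanning(pair.a_I.size)
    mag = 0.5 * (
        np.abs(np.fft.fftshift(np.fft.fft(window * pair.a_I)))
        + np.abs(np.fft.fftshift(np.fft.fft(window * pair.a_II)))
    )
    b = int(np.argmax(mag))
    peak = mag[b]
    candidates = np.flatnonzero(mag >= peak / 10 ** (3.0 / 20.0))
    if np.any(np.abs(candidates - b) > 2):
        raise AmbiguousPeakError("multiple non-adjacent peaks within 3 dB of max")

    delta = 0.0
    if 0 < b < grid.N - 1:
        m_minus, m0, m_plus = mag[b - 1], mag[b], mag[b + 1]
        if m_minus > m0 * 1e-12 and m_plus > m0 * 1e-12:
            lm, l0, lp = np.log(m_minus), np.log(m0), np.log(m_plus)
            denom = lm - 2.0 * l0 + lp
            if denom < 0:
                delta = 0.5 * (lm - lp) / denom
    zbar_peak = float(grid.zbar[b] + delta * grid.zbar_spacing)
    side = "positive" if zbar_peak >= 0 else "negative"
    quality = float(20.0 * np.log10(peak / np.median(mag)))
    return zbar_peak, side, quality


def compute_beta_dphi(pair: AnalyticPair) -> tuple[np.ndarray, np.ndarray]:
    """Raw amplitude ratio ``amp_I / amp_II`` and phase offset ``ph_II - ph_I``.

    The phase offset is shifted by a whole multiple of 2*pi so that its
    median lands on the branch nearest +pi/2.  Channel labels are never
    interchanged: swapping them maps beta -> 1/beta and dphi -> -dphi.
    """
    guard = 1e-12 * np.max(pair.amp_II)
    if np.any(pair.amp_II <= guard):
        raise DivisionGuardError("channel II amplitude vanishes somewhere")
    beta = pair.amp_I / pair.amp_II
    dphi = pair.ph_II - pair.ph_I
    shift = 2.0 * np.pi * np.round((HALF_PI - np.median(dphi)) / (2.0 * np.pi))
    return beta, dphi + shift


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_along_k(
    raw: np.ndarray,
    trusted_mask: np.ndarray | None = None,
    method: str = "polynomial",
    degree: int = 7,
    lam: float | None = None,
) -> np.ndarray:
    """Smooth a raw beta(k) or dphi(k) vector over the full wavenumber axis.

    ``polynomial`` fits a degree-``degree`` polynomial on centered/scaled
    coordinates using only trusted samples.  ``smoothing-spline`` fits a
    smoothing spline on data mirror-padded at both ends (stabilizes the
    edges; a polynomial is not padded as padding would break its exactness
    on polynomial input).
    """
    raw = np.asarray(raw, dtype=float)
    N = raw.size
    if trusted_mask is None:
        trusted_mask = np.ones(N, dtype=bool)
    trusted_mask = np.asarray(trusted_mask, dtype=bool)
    n_trusted = int(trusted_mask.sum())
    x = np.arange(N, dtype=float)

    if method == "polynomial":
        if n_trusted < degree + 1:
            raise UnderdeterminedError(
                f"{n_trusted} trusted samples < {degree + 1} coefficients"
            )
        poly = Polynomial.fit(x[trusted_mask], raw[trusted_mask], deg=degree)
        return poly(x)

    if method == "smoothing-spline":
        if n_trusted < 8:
            raise UnderdeterminedError("smoothing spline needs >= 8 trusted samples")
        x_pad = np.concatenate([x - N, x, x + N])
        y_pad = np.concatenate([raw[::-1], raw, raw[::-1]])
        m_pad = np.concatenate([trusted_mask[::-1], trusted_mask, trusted_mask[::-1]])
        spline = make_smoothing_spline(x_pad[m_pad], y_pad[m_pad], lam=lam)
        return np.asarray(spline(x))

    raise ValueError(f"unknown fit method {method!r}")


def edge_trust_mask(N: int, edge_fraction: float = 0.05) -> np.ndarray:
    """Trusted-sample mask excluding a fraction of samples at each edge."""
    n_edge = int(round(edge_fraction * N))
    mask = np.ones(N, dtype=bool)
    if n_edge > 0:
        mask[:n_edge] = False
        mask[-n_edge:] = False
    return mask


def fit_spatial_vectors(
    samples: list[DepthSample],
    grid: KGrid,
    config: CalibrationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the depth-dependent corrections across all measured depths.

    The per-depth beta/dphi values at the central wavenumber are collected,
    depths inside the zero-delay exclusion radius are dropped, the remainder
    is fitted/interpolated over the full ``zbar`` axis (held constant beyond
    the sampled hull), and the result is gauge-normalized at zero-delay.
    """
    cfg = config or CalibrationConfig()
    center = grid.N // 2
    excl = cfg.dc_exclusion_bins * grid.zbar_spacing

    pts = [
        (s.zbar_peak, float(s.beta_k[center]), float(s.dphi_k[center]))
        for s in samples
        if abs(s.zbar_peak) >= excl
    ]
    if not pts:
        raise NoUsableDepthsError("all depth samples fall in the zero-delay exclusion")
    z = np.array([p[0] for p in pts])
    if np.all(z > 0) or np.all(z < 0):
        raise CoverageError(
            "calibration depths cover only one side of zero-delay; "
            "measure mirrors at both positive and negative depths"
        )
    if z.size < 4:
        raise UnderdeterminedError("need at least 4 usable depth samples")
    order = np.argsort(z)
    z = z[order]
    beta_c = np.array([p[1] for p in pts])[order]
    dphi_c = np.array([p[2] for p in pts])[order]

    if cfg.max_depth_gap is not None:
        gap = np.max(np.diff(z))
        if gap > cfg.max_depth_gap:
            warnings.warn(
                f"largest depth spacing {gap:.4f} exceeds configured "
                f"maximum {cfg.max_depth_gap:.4f}",
                stacklevel=2,
            )

    zq = np.clip(grid.zbar, z[0], z[-1])  # hold edge values beyond the hull
    if cfg.z_fit_method == "spline":
        beta_z = CubicSpline(z, beta_c, bc_type="natural")(zq)
        dphi_z = CubicSpline(z, dphi_c, bc_type="natural")(zq)
    elif cfg.z_fit_method == "smoothing-spline":
        beta_z = make_smoothing_spline(z, beta_c, lam=cfg.z_spline_lam)(zq)
        dphi_z = make_smoothing_spline(z, dphi_c, lam=cfg.z_spline_lam)(zq)
    elif cfg.z_fit_method == "polynomial":
        if z.size < cfg.z_poly_degree + 1:
            raise UnderdeterminedError("too few depths for the polynomial degree")
        beta_z = Polynomial.fit(z, beta_c, deg=cfg.z_poly_degree)(zq)
        dphi_z = Polynomial.fit(z, dphi_c, deg=cfg.z_poly_degree)(zq)
    else:
        raise ValueError(f"unknown z fit method {cfg.z_fit_method!r}")

    beta_z = np.asarray(beta_z) / beta_z[center]
    dphi_z = np.asarray(dphi_z) - dphi_z[center]
    return beta_z, dphi_z


def apply_spatial_correction(
    m: MirrorMeasurement,
    beta_z: np.ndarray,
    dphi_z: np.ndarray,
    side: str | None = None,
) -> MirrorMeasurement:
    """Equalize channel II's depth response to channel I's.

    Channel II is replaced by the real part of the inverse FT of its spectrum
    multiplied by ``beta_z * exp(-1j * dphi_z)`` arranged on the centered
    depth axis; channel I is untouched.  When ``side`` is given (or the
    measurement carries a known ``nominal_side``), the correction acts on the
    side-aware analytic representation instead of the two-sided spectrum —
    equivalent for Hermitian-symmetric vectors, and the form under which the
    spatial/chromatic gauge freedom is an exact symmetry.  The vectors must
    be gauge-normalized at zero-delay.
    """
    center = m.grid.N // 2
    if abs(beta_z[center] - 1.0) > 1e-6 or abs(dphi_z[center]) > 1e-6:
        raise GaugeError("spatial vectors must be normalized at zero-delay")
    if side is None and m.nominal_side in ("positive", "negative"):
        side = m.nominal_side
    phasor = np.fft.ifftshift(beta_z * np.exp(-1j * dphi_z))
    source = (
        analytic_representation(m.s_II, side) if side is not None else m.s_II
    )
    s_ii = np.real(np.fft.ifft(np.fft.fft(source) * phasor))
    return MirrorMeasurement(
        s_I=m.s_I.copy(),
        s_II=s_ii,
        grid=m.grid,
        n_averaged=m.n_averaged,
        nominal_side=m.nominal_side,
    )


def compute_chromatic_vectors(
    corrected: list[MirrorMeasurement],
    zbar_peaks: list[float],
    grid: KGrid,
    config: CalibrationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average the per-depth chromatic curves of spatially corrected data.

    Depths inside the zero-delay exclusion or in the outermost ``zbar``
    fringe are dropped; remaining per-depth fitted curves whose deviation
    from the pointwise median exceeds ``outlier_mad`` times the pointwise
    MAD anywhere are flagged as outliers and excluded before averaging.
    """
    cfg = config or CalibrationConfig()
    excl = cfg.dc_exclusion_bins * grid.zbar_spacing
    edge = (1.0 - cfg.z_edge_fraction) * HALF_PI
    mask = edge_trust_mask(grid.N, cfg.edge_fraction)

    beta_curves, dphi_curves = [], []
    for m, z in zip(corrected, zbar_peaks):
        if abs(z) < excl or abs(z) > edge:
            continue
        pair = extract_amplitude_phase(m)
        beta_raw, dphi_raw = compute_beta_dphi(pair)
        beta_curves.append(
            fit_along_k(beta_raw, mask, cfg.k_fit_method, cfg.k_poly_degree,
                        cfg.k_spline_lam)
        )
        dphi_curves.append(
            fit_along_k(dphi_raw, mask, cfg.k_fit_method, cfg.k_poly_degree,
                        cfg.k_spline_lam)
        )
    if not beta_curves:
        raise NoUsableDepthsError("no depths remain after exclusions")

    def robust_mean(curves: list[np.ndarray]) -> np.ndarray:
        stack = np.vstack(curves)
        if stack.shape[0] >= 3:
            med = np.median(stack, axis=0)
            dev = np.abs(stack - med)
            mad = np.maximum(np.median(dev, axis=0), 1e-12)
            keep = ~np.any(dev > cfg.outlier_mad * mad, axis=1)
            if keep.any():
                stack = stack[keep]
        return stack.mean(axis=0)

    return robust_mean(beta_curves), robust_mean(dphi_curves)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _depth_sample(
    m: MirrorMeasurement, grid: KGrid, cfg: CalibrationConfig
) -> tuple[DepthSample, MirrorMeasurement]:
    pair = extract_amplitude_phase(m)
    zbar_peak, side, quality = locate_peak(pair, grid)
    beta_raw, dphi_raw = compute_beta_dphi(pair)
    mask = edge_trust_mask(grid.N, cfg.edge_fraction)
    beta_fit = fit_along_k(
        beta_raw, mask, cfg.k_fit_method, cfg.k_poly_degree, cfg.k_spline_lam
    )
    dphi_fit = fit_along_k(
        dphi_raw, mask, cfg.k_fit_method, cfg.k_poly_degree, cfg.k_spline_lam
    )
    sample = DepthSample(
        zbar_peak=zbar_peak,
        side=side,
        beta_k=beta_fit,
        dphi_k=dphi_fit,
        quality=quality,
    )
    return sample, m


def calibrate(
    sweep: list[RawBatch],
    config: CalibrationConfig | None = None,
    background: RawBatch | None = None,
) -> CorrectionSet:
    """Run the full calibration pipeline on a mirror sweep.

    Steps: (1) background removal and coherent averaging per depth, (2)
    per-depth peak location and beta/dphi extraction with wavenumber fits,
    (3) spatial-vector fitting with gauge normalization, (4) spatial
    correction followed by chromatic-vector averaging.
    """
    cfg = config or CalibrationConfig()
    if not sweep:
        raise NoUsableDepthsError("empty sweep")
    grid = sweep[0].grid

    measurements: list[MirrorMeasurement] = []
    samples: list[DepthSample] = []
    for batch in sweep:
        if background is not None:
            batch = remove_background(batch, background)
        m = coherent_average(batch)
        sample, m = _depth_sample(m, grid, cfg)
        samples.append(sample)
        measurements.append(m)
        log.debug(
            "depth sample: zbar=%.4f side=%s quality=%.1f dB",
            sample.zbar_peak,
            sample.side,
            sample.quality,
        )

    beta_z, dphi_z = fit_spatial_vectors(samples, grid, cfg)
    log.info("spatial vectors fitted from %d depth samples", len(samples))

    corrected = [apply_spatial_correction(m, beta_z, dphi_z) for m in measurements]
    beta_k, dphi_k = compute_chromatic_vectors(
        corrected, [s.zbar_peak for s in samples], grid, cfg
    )
    log.info("chromatic vectors averaged")

    cs = CorrectionSet(
        beta_z=beta_z,
        dphi_z=dphi_z,
        beta_k=beta_k,
        dphi_k=dphi_k,
        grid=grid,
        fit_meta={
            "k_fit_method": cfg.k_fit_method,
            "k_poly_degree": cfg.k_poly_degree,
            "z_fit_method": cfg.z_fit_method,
            "dc_exclusion_bins": cfg.dc_exclusion_bins,
            "edge_fraction": cfg.edge_fraction,
            "n_depths": len(samples),
        },
    )
    cs.validate(min_sin_dphi=cfg.min_sin_dphi)
    return cs
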