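"""Signal conditioning: background removal, coherent averaging, side-aware
analytic representation, and amplitude/phase extraction.

The analytic representation is the complex signal whose real part reproduces
the input and whose spectrum is one-sided.  During calibration the mirror
position is known, so the side (positive or negative depth bins) is chosen
explicitly; choosing the wrong side folds the peak onto its conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AveragingError,
    DCOffsetError,
    InvalidSizeError,
    ShapeMismatchError,
)
from .sim_forward import KGrid, RawBatch

__all__ = [
    "MirrorMeasurement",
    "AnalyticPair",
    "remove_background",
    "coherent_average",
    "analytic_representation",
    "extract_amplitude_phase",
]


@dataclass
class MirrorMeasurement:
    """One averaged two-channel real interferogram at one mirror depth."""

    s_I: np.ndarray
    s_II: np.ndarray
    grid: KGrid
    n_averaged: int = 1
    nominal_side: str = "unknown"

    def __post_init__(self):
        if self.s_I.shape != self.s_II.shape:
            raise ShapeMismatchError("channel vectors must share a shape")
        if self.s_I.shape != (self.grid.N,):
            raise ShapeMismatchError("channel vectors must have length grid.N")


@dataclass
class AnalyticPair:
    """Analytic representations of both channels plus amplitude/phase."""

    a_I: np.ndarray
    a_II: np.ndarray
    amp_I: np.ndarray
    amp_II: np.ndarray
    ph_I: np.ndarray
    ph_II: np.ndarray
    side: str = "positive"


def remove_background(batch: RawBatch, background: RawBatch) -> RawBatch:
    """Subtract the mean background trace, then the per-A-line mean.

    The background batch must share the sample count of the data batch; its
    A-lines are averaged into a single trace per channel.
    """
    if background.ch_I.shape[0] != batch.ch_I.shape[0]:
        raise ShapeMismatchError(
            f"background N={background.ch_I.shape[0]} != batch N={batch.ch_I.shape[0]}"
        )

    def clean(data: np.ndarray, bg: np.ndarray) -> np.ndarray:
        out = data - bg.mean(axis=1, keepdims=True)
        return out - out.mean(axis=0, keepdims=True)

    return RawBatch(
        ch_I=clean(batch.ch_I, background.ch_I),
        ch_II=clean(batch.ch_II, background.ch_II),
        grid=batch.grid,
        truth=batch.truth,
    )


def _analytic_weights(N: int, side: str) -> np.ndarray:
    w = np.zeros(N)
    w[0] = 1.0
    if N % 2 == 0:
        w[N // 2] = 1.0
        pos = slice(1, N // 2)
        neg = slice(N // 2 + 1, N)
    else:
        pos = slice(1, (N + 1) // 2)
        neg = slice((N + 1) // 2, N)
    if side == "positive":
        w[pos] = 2.0
    elif side == "negative":
        w[neg] = 2.0
    else:
        raise ValueError(f"side must be 'positive' or 'negative', got {side!r}")
    return w


def analytic_representation(s: np.ndarray, side: str = "positive") -> np.ndarray:
    """Side-aware analytic signal of a zero-mean real vector (or N x M matrix).

    For ``side="positive"`` the negative depth-frequency bins are zeroed and
    the positive ones doubled (DC and Nyquist kept as-is) so that the real
    part reproduces the input; ``side="negative"`` mirrors the construction.
    Complex input is reduced to its real part first, which makes the
    operation idempotent.  Raises :class:`DCOffsetError` when the residual
    mean exceeds ``1e-6`` of the RMS.
    """
    s = np.real(np.asarray(s))
    squeeze = s.ndim == 1
    if squeeze:
        s = s[:, None]
    rms = np.sqrt(np.mean(s**2, axis=0))
    if np.any(rms == 0):
        raise DCOffsetError("zero (constant) input has no analytic representation")
    mean = np.abs(s.mean(axis=0))
    if np.any(mean > 1e-6 * rms):
        raise DCOffsetError("input has a non-negligible DC component")
    w = _analytic_weights(s.shape[0], side)
    a = np.fft.ifft(np.fft.fft(s, axis=0) * w[:, None], axis=0)
    return a[:, 0] if squeeze else a


def coherent_average(batch: RawBatch) -> MirrorMeasurement:
    """Phase-locked average of all A-lines in a batch.

    A global phase per A-line is estimated from the dominant depth-domain
    peak of channel I and removed from the analytic signals of *both*
    channels (the shared correction preserves their relative phase) before
    averaging.  Raises :class:`AveragingError` when no dominant peak exists.
    """
    if batch.M < 1:
        raise InvalidSizeError("batch must contain at least one A-line")
    N = batch.grid.N
    ch_i = batch.ch_I - batch.ch_I.mean(axis=0, keepdims=True)
    ch_ii = batch.ch_II - batch.ch_II.mean(axis=0, keepdims=True)

    # The side cannot be read off a single real channel (its spectrum is
    # Hermitian-symmetric); the direct complex combination of the two
    # channels suppresses the mirror peak enough to disambiguate.
    spec_i = np.fft.fft(ch_i, axis=0)
    spec_c = np.fft.fft(ch_i - 1j * ch_ii, axis=0)
    mag = np.abs(spec_c).mean(axis=1)
    mag[0] = 0.0
    peak_bin = int(np.argmax(mag))
    floor = np.median(mag[1:])
    if floor > 0 and mag[peak_bin] < 4.0 * floor:
        raise AveragingError("no dominant spectral peak; cannot phase-lock")
    side = "positive" if 1 <= peak_bin <= N // 2 else "negative"

    a_i = analytic_representation(ch_i, side)
    a_ii = analytic_representation(ch_ii, side)
    phases = np.angle(spec_i[peak_bin, :])
    rot = np.exp(-1j * (phases - phases[0]))
    s_i = np.real((a_i * rot).mean(axis=1))
    s_ii = np.real((a_ii * rot).mean(axis=1))
    s_i -= s_i.mean()
    s_ii -= s_ii.mean()
    return MirrorMeasurement(
        s_I=s_i,
        s_II=s_ii,
        grid=batch.grid,
        n_averaged=batch.M,
        nominal_side=side,
    )


def extract_amplitude_phase(
    m: MirrorMeasurement, side: str | None = None
) -> AnalyticPair:
    """Amplitudes and unwrapped phases of both channels, same analytic side."""
    if side is None:
        side = m.nominal_side
    if side not in ("positive", "negative"):
        raise ValueError("side must be resolved to 'positive' or 'negative'")
    a_i = analytic_representation(m.s_I, side)
    a_ii = analytic_representation(m.s_II, side)
    return AnalyticPair(
        a_I=a_i,
        a_II=a_ii,
        amp_I=np.abs(a_i),
        amp_II=np.abs(a_ii),
        ph_I=np.unwrap(np.angle(a_i)),
        ph_II=np.unwrap(np.angle(a_ii)),
        side=side,
    )
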