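"""Forward model of a dual-channel, passively demultiplexed SS-OCT system.

This module is the ground-truth provider for the rest of the package.  It
synthesizes two real-valued, k-linear spectral interferograms (channels I and
II) whose mutual imbalance is fully controllable:

* a chromatic amplitude envelope and phase per channel (functions of
  wavenumber ``k``),
* a depth-dependent ("RF") amplitude and phase response per channel
  (functions of the normalized depth ``zbar``),
* additive white Gaussian noise, independent per channel,
* a per-A-line global phase jitter applied identically to both channels.

Conventions
-----------
* The normalized depth axis ``zbar`` spans ``[-pi/2, pi/2 - pi/N]`` for even
  ``N`` (``[-pi/2, pi/2]`` for odd ``N``) with zero-delay (DC) at index
  ``N // 2``.
* A reflector at ``zbar = z`` produces the phase ramp ``theta[n] = 2 * z * n``
  across samples ``n = 0 .. N-1``, so a reflector on an integer depth bin is a
  pure DFT tone and positive ``zbar`` maps to positive analytic frequency.
* The ideal channel pair satisfies ``Omega_II - Omega_I = pi/2`` so that the
  inter-channel phase difference measured downstream is ``+pi/2``.

Randomness: a single seed in :class:`NoiseJitterSpec` governs everything.
Within one simulated batch the stream order is (1) jitter phases (``M``
draws, always consumed), (2) channel-I noise (``N x M``, consumed only when
``noise_sigma > 0``), (3) channel-II noise.  Sweeps and phantoms spawn one
child generator per element, in element order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegeneratePortError,
    DepthRangeError,
    InvalidSizeError,
)

__all__ = [
    "HALF_PI",
    "KGrid",
    "PortModel",
    "ChannelImbalance",
    "ReflectorSet",
    "NoiseJitterSpec",
    "SimTruth",
    "RawBatch",
    "zbar_axis",
    "make_kgrid",
    "balance_ports",
    "get_preset",
    "PRESET_NAMES",
    "sigma_for_snr",
    "simulate_mirror_measurement",
    "simulate_mirror_sweep",
    "simulate_bscan_phantom",
]

HALF_PI = math.pi / 2.0

Func = Callable[[np.ndarray], np.ndarray]


def zbar_axis(n_samples: int) -> np.ndarray:
    """Normalized depth axis for ``n_samples`` spectral samples.

    Spacing is ``pi/N`` for even ``N`` (axis ``[-pi/2, pi/2 - pi/N]``) and
    ``pi/(N-1)`` for odd ``N`` (axis ``[-pi/2, pi/2]``); zero-delay sits at
    index ``N // 2`` in both cases.
    """
    if n_samples < 2:
        raise InvalidSizeError(f"need at least 2 samples, got {n_samples}")
    spacing = math.pi / n_samples if n_samples % 2 == 0 else math.pi / (n_samples - 1)
    return (np.arange(n_samples) - n_samples // 2) * spacing


@dataclass(frozen=True)
class KGrid:
    """Wavenumber and normalized-depth axes for one A-line layout."""

    N: int
    k: np.ndarray
    zbar: np.ndarray

    @property
    def zbar_spacing(self) -> float:
        return float(self.zbar[1] - self.zbar[0])

    def bin_of(self, zbar: float) -> float:
        """Fractional depth-bin index (DC at ``N // 2``) of a ``zbar`` value."""
        return zbar / self.zbar_spacing + self.N // 2


def make_kgrid(N: int) -> KGrid:
    """Build a :class:`KGrid` with ``N`` equispaced wavenumber samples.

    ``k`` is normalized to ``[-1, 1)`` (half-open, so trigonometric envelope
    terms are exactly periodic over the acquisition window); absolute optical
    units are out of scope.  Raises :class:`InvalidSizeError` for ``N < 8``.
    """
    if N < 8:
        raise InvalidSizeError(f"N must be >= 8, got {N}")
    return KGrid(N=N, k=np.linspace(-1.0, 1.0, N, endpoint=False), zbar=zbar_axis(N))


def _as_func(value) -> Func:
    """Promote a scalar to a constant vectorized function; pass callables."""
    if callable(value):
        return value
    const = float(value)
    return lambda x, _c=const: np.full_like(np.asarray(x, dtype=float), _c)


# ---------------------------------------------------------------------------
# Port-level model and channel imbalance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PortModel:
    """Four-port description of the demultiplexing circuit.

    Each entry may be a scalar or a vectorized function of ``k``.  Ports
    (1, 3) form balanced channel I and ports (2, 4) form channel II.
    """

    TS: Sequence
    TR: Sequence
    phi: Sequence
    IS: float | Func = 1.0
    IR: float | Func = 1.0


@dataclass(frozen=True)
class ChannelImbalance:
    """Ground-truth imbalance between the two balanced detection channels.

    Chromatic terms (``A_*``, ``Omega_*``) are functions of ``k``; depth
    terms (``alpha_*``, ``omega_*``) are functions of ``zbar``.  The derived
    ratio ``beta(k, z) = (A_I * alpha_I) / (A_II * alpha_II)`` and offset
    ``dphi(k, z) = (Omega_II - Omega_I) + (omega_II - omega_I)`` factor into
    chromatic and spatial parts by construction.
    """

    A_I: Func
    A_II: Func
    Omega_I: Func
    Omega_II: Func
    alpha_I: Func = field(default_factory=lambda: _as_func(1.0))
    alpha_II: Func = field(default_factory=lambda: _as_func(1.0))
    omega_I: Func = field(default_factory=lambda: _as_func(0.0))
    omega_II: Func = field(default_factory=lambda: _as_func(0.0))
    name: str = "custom"

    # -- derived ground-truth ratios -------------------------------------
    def beta_k(self, k: np.ndarray) -> np.ndarray:
        return np.asarray(self.A_I(k)) / np.asarray(self.A_II(k))

    def dphi_k(self, k: np.ndarray) -> np.ndarray:
        return np.asarray(self.Omega_II(k)) - np.asarray(self.Omega_I(k))

    def beta_z(self, zbar: np.ndarray) -> np.ndarray:
        return np.asarray(self.alpha_I(zbar)) / np.asarray(self.alpha_II(zbar))

    def dphi_z(self, zbar: np.ndarray) -> np.ndarray:
        return np.asarray(self.omega_II(zbar)) - np.asarray(self.omega_I(zbar))

    def beta(self, k: np.ndarray, zbar: float) -> np.ndarray:
        return self.beta_k(k) * float(self.beta_z(np.asarray([zbar]))[0])

    def dphi(self, k: np.ndarray, zbar: float) -> np.ndarray:
        return self.dphi_k(k) + float(self.dphi_z(np.asarray([zbar]))[0])


def balance_ports(ports: PortModel) -> ChannelImbalance:
    """Collapse a four-port model into per-channel complex envelopes.

    Channel I is the balanced subtraction of ports 1 and 3, channel II of
    ports 2 and 4; the resulting phasor magnitudes/phases become the
    chromatic envelopes of a :class:`ChannelImbalance` with flat depth
    responses.  Raises :class:`DegeneratePortError` when a port pair cancels
    identically.
    """
    ts = [_as_func(v) for v in ports.TS]
    tr = [_as_func(v) for v in ports.TR]
    ph = [_as_func(v) for v in ports.phi]
    i_s = _as_func(ports.IS)
    i_r = _as_func(ports.IR)

    def phasor(n: int) -> Func:
        def f(k, _n=n):
            k = np.asarray(k, dtype=float)
            amp = np.sqrt(tr[_n](k) * ts[_n](k) * i_r(k) * i_s(k))
            return amp * np.exp(1j * ph[_n](k))

        return f

    def envelope(a: int, b: int) -> Func:
        def f(k, _a=a, _b=b):
            return phasor(_a)(k) - phasor(_b)(k)

        return f

    env_i, env_ii = envelope(0, 2), envelope(1, 3)
    probe = np.linspace(-1.0, 1.0, 64)
    for label, env in (("I", env_i), ("II", env_ii)):
        if np.max(np.abs(env(probe))) < 1e-14:
            raise DegeneratePortError(f"ports of channel {label} cancel exactly")

    return ChannelImbalance(
        A_I=lambda k: np.abs(env_i(k)),
        A_II=lambda k: np.abs(env_ii(k)),
        Omega_I=lambda k: np.unwrap(np.angle(env_i(k))),
        Omega_II=lambda k: np.unwrap(np.angle(env_ii(k))),
        name="ports",
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _u(zbar: np.ndarray) -> np.ndarray:
    """Depth coordinate scaled to [-1, 1]."""
    return np.asarray(zbar, dtype=float) / HALF_PI


def _ac_dip(zbar: np.ndarray) -> np.ndarray:
    # AC-coupling-like attenuation near zero-delay, identical in both
    # channels (cancels in the channel ratio but lowers SNR near DC).
    u = _u(zbar)
    return 1.0 - 0.25 * np.exp(-((u / 0.04) ** 2))


def _chromatic_pair():
    a_i = lambda k: 1.0 + 0.05 * k - 0.03 * k**2 + 0.015 * k**3
    a_ii = _as_func(1.0)
    om_i = lambda k: 0.05 * np.asarray(k, dtype=float)
    om_ii = lambda k: HALF_PI + 0.05 * k + 0.05 * k - 0.03 * k**2 + 0.01 * k**3
    return a_i, a_ii, om_i, om_ii


def _rf_pair(sharp: bool):
    def alpha_i(z):
        u = _u(z)
        return _ac_dip(z) * (1.0 + 0.03 * u**2 - 0.02 * u**4)

    def alpha_ii(z):
        u = _u(z)
        base = _ac_dip(z) * (1.0 - 0.04 * u**2 + 0.015 * u**4)
        if sharp:
            bump = np.exp(-(((u - 0.18) / 0.05) ** 2)) + np.exp(
                -(((u + 0.18) / 0.05) ** 2)
            )
            base = base * (1.0 - 0.06 * bump)
        return base

    def omega_i(z):
        return 0.04 * _u(z)

    def omega_ii(z):
        u = _u(z)
        w = 0.04 * u - 0.15 * u + 0.06 * u**3
        if sharp:
            w = w + 0.04 * (
                np.exp(-(((u - 0.18) / 0.05) ** 2))
                - np.exp(-(((u + 0.18) / 0.05) ** 2))
            )
        return w

    return alpha_i, alpha_ii, omega_i, omega_ii


def get_preset(name: str) -> ChannelImbalance:
    """Return a named imbalance preset.

    ``ideal``          perfectly matched channels in exact quadrature.
    ``chromatic-only`` smooth low-order polynomial chromatic imbalance,
                       flat depth response.
    ``rf-only``        ideal chromatics; smooth, Hermitian-symmetric depth
                       responses (even amplitude, odd phase) with a common
                       AC-coupling dip near zero-delay.
    ``realistic``      chromatic-only and rf-only combined.
    ``rf-sharp``       realistic plus a sharp differential depth feature
                       near zero-delay (stresses axial sampling density).
    ``bandlimited``    like ``realistic`` but with chromatic envelopes built
                       from window-periodic trigonometric terms, so their
                       spectra are compact and the analytic-signal extraction
                       is leakage-free (useful for noiseless precision
                       studies).
    """
    one, zero = _as_func(1.0), _as_func(0.0)
    if name == "ideal":
        return ChannelImbalance(one, one, zero, _as_func(HALF_PI), name=name)
    if name == "bandlimited":
        a_i = lambda k: 1.0 + 0.05 * np.cos(np.pi * k) + 0.02 * np.sin(np.pi * k)
        om_i = zero
        om_ii = lambda k: HALF_PI + 0.05 * np.sin(np.pi * k) + 0.03 * (
            np.cos(np.pi * k) - 1.0
        )
        al_i, al_ii, w_i, w_ii = _rf_pair(sharp=False)
        return ChannelImbalance(
            a_i, one, om_i, om_ii, al_i, al_ii, w_i, w_ii, name=name
        )
    if name == "chromatic-only":
        a_i, a_ii, om_i, om_ii = _chromatic_pair()
        return ChannelImbalance(a_i, a_ii, om_i, om_ii, name=name)
    if name == "rf-only":
        al_i, al_ii, w_i, w_ii = _rf_pair(sharp=False)
        return ChannelImbalance(
            one, one, zero, _as_func(HALF_PI), al_i, al_ii, w_i, w_ii, name=name
        )
    if name in ("realistic", "rf-sharp"):
        a_i, a_ii, om_i, om_ii = _chromatic_pair()
        al_i, al_ii, w_i, w_ii = _rf_pair(sharp=name == "rf-sharp")
        return ChannelImbalance(
            a_i, a_ii, om_i, om_ii, al_i, al_ii, w_i, w_ii, name=name
        )
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "ideal",
    "chromatic-only",
    "rf-only",
    "realistic",
    "rf-sharp",
    "bandlimited",
)


# ---------------------------------------------------------------------------
# Scene and acquisition descriptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReflectorSet:
    """Point reflectors on the normalized depth axis.

    ``amplitudes`` are proportional to amplitude reflectivity (sqrt of the
    intensity reflectivity).
    """

    depths: Sequence[float]
    amplitudes: Sequence[float]

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if d.shape != a.shape:
            raise InvalidSizeError("depths and amplitudes must match in length")
        if np.any(np.abs(d) >= HALF_PI):
            raise DepthRangeError("reflector depths must lie within (-pi/2, pi/2)")
        if np.any(a < 0):
            raise InvalidSizeError("reflector amplitudes must be >= 0")


@dataclass(frozen=True)
class NoiseJitterSpec:
    """Additive white noise level, per-A-line phase-jitter half-width, seed."""

    noise_sigma: float = 0.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidSizeError("noise_sigma must be >= 0")
        if not (0.0 <= self.jitter <= math.pi):
            raise InvalidSizeError("jitter must be in [0, pi]")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth record attached to simulated batches."""

    imbalance: ChannelImbalance
    reflectors: ReflectorSet
    noise: NoiseJitterSpec
    mode: str


@dataclass
class RawBatch:
    """Two-channel real interferograms, ``N`` samples by ``M`` A-lines."""

    ch_I: np.ndarray
    ch_II: np.ndarray
    grid: KGrid
    truth: SimTruth | None = None

    def __post_init__(self):
        if self.ch_I.shape != self.ch_II.shape:
            raise InvalidSizeError("channel matrices must share a shape")
        if self.ch_I.shape[0] != self.grid.N:
            raise InvalidSizeError("channel rows must equal grid.N")

    @property
    def M(self) -> int:
        return self.ch_I.shape[1]


def sigma_for_snr(N: int, snr_db: float, amplitude: float = 1.0) -> float:
    """Per-sample noise sigma giving a single-A-line depth-domain SNR.

    SNR is the on-bin DFT peak magnitude of a unit tone (``amplitude * N/2``)
    over the median magnitude of the noise floor (Rayleigh median
    ``sigma * sqrt(N * ln 2)``).
    """
    peak = amplitude * N / 2.0
    floor = peak / 10.0 ** (snr_db / 20.0)
    return floor / math.sqrt(N * math.log(2.0))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _depth_filter(base: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Multiply the centered depth-domain spectrum of ``base`` by ``response``."""
    spec = np.fft.fftshift(np.fft.fft(base))
    return np.fft.ifft(np.fft.ifftshift(spec * response))


def simulate_mirror_measurement(
    imb: ChannelImbalance,
    reflectors: ReflectorSet,
    grid: KGrid,
    nj: NoiseJitterSpec,
    M: int,
    mode: str = "exact",
    rng: np.random.Generator | None = None,
) -> RawBatch:
    """Simulate one two-channel batch of ``M`` A-lines.

    ``mode="dirac"`` evaluates the depth response at each reflector depth (a
    point-peak approximation); ``mode="exact"`` applies the full response by
    multiplication in the depth domain.  Jitter is a global per-A-line phase
    common to both channels; noise is white Gaussian, independent per channel.
    """
    if M < 1:
        raise InvalidSizeError(f"M must be >= 1, got {M}")
    if mode not in ("exact", "dirac"):
        raise ValueError(f"mode must be 'exact' or 'dirac', got {mode!r}")
    depths = np.asarray(reflectors.depths, dtype=float)
    amps = np.asarray(reflectors.amplitudes, dtype=float)
    if np.any(np.abs(depths) >= HALF_PI):
        raise DepthRangeError("reflector outside (-pi/2, pi/2)")

    if rng is None:
        rng = np.random.default_rng(nj.seed)
    jitter = rng.uniform(-nj.jitter, nj.jitter, size=M)

    n = np.arange(grid.N, dtype=float)
    channels = {}
    specs = (
        ("I", imb.A_I, imb.Omega_I, imb.alpha_I, imb.omega_I),
        ("II", imb.A_II, imb.Omega_II, imb.alpha_II, imb.omega_II),
    )
    for label, A, Omega, alpha, omega in specs:
        base = np.zeros(grid.N, dtype=complex)
        envelope = np.asarray(A(grid.k), dtype=float) * np.exp(
            1j * np.asarray(Omega(grid.k), dtype=float)
        )
        for c_m, z_m in zip(amps, depths):
            tone = np.exp(2j * z_m * n)
            if mode == "dirac":
                a_m = float(np.asarray(alpha(np.array([z_m])))[0])
                w_m = float(np.asarray(omega(np.array([z_m])))[0])
                base += c_m * a_m * np.exp(1j * w_m) * envelope * tone
            else:
                base += c_m * envelope * tone
        if mode == "exact":
            response = np.asarray(alpha(grid.zbar), dtype=float) * np.exp(
                1j * np.asarray(omega(grid.zbar), dtype=float)
            )
            base = _depth_filter(base, response)
        channels[label] = np.real(base[:, None] * np.exp(1j * jitter)[None, :])

    if nj.noise_sigma > 0:
        channels["I"] = channels["I"] + nj.noise_sigma * rng.standard_normal(
            (grid.N, M)
        )
        channels["II"] = channels["II"] + nj.noise_sigma * rng.standard_normal(
            (grid.N, M)
        )

    truth = SimTruth(imbalance=imb, reflectors=reflectors, noise=nj, mode=mode)
    return RawBatch(ch_I=channels["I"], ch_II=channels["II"], grid=grid, truth=truth)


def simulate_mirror_sweep(
    imb: ChannelImbalance,
    grid: KGrid,
    nj: NoiseJitterSpec,
    depths: Sequence[float],
    M: int,
    amplitude: float = 1.0,
    mode: str = "exact",
) -> list[RawBatch]:
    """One single-reflector batch per depth; child RNG spawned per depth."""
    depths = list(depths)
    if not depths:
        return []
    parent = np.random.default_rng(nj.seed)
    rngs = parent.spawn(len(depths))
    return [
        simulate_mirror_measurement(
            imb,
            ReflectorSet([z], [amplitude]),
            grid,
            nj,
            M,
            mode=mode,
            rng=r,
        )
        for z, r in zip(depths, rngs)
    ]


def simulate_bscan_phantom(
    imb: ChannelImbalance,
    grid: KGrid,
    nj: NoiseJitterSpec,
    columns: Sequence[ReflectorSet],
    M: int = 1,
    mode: str = "exact",
) -> list[RawBatch]:
    """Synthetic layered phantom: one multi-reflector batch per lateral column."""
    columns = list(columns)
    if not columns:
        return []
    parent = np.random.default_rng(nj.seed)
    rngs = parent.spawn(len(columns))
    return [
        simulate_mirror_measurement(imb, refl, grid, nj, M, mode=mode, rng=r)
        for refl, r in zip(columns, rngs)
    ]
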