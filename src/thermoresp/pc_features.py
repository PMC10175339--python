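"""Log-Gabor filter banks, phase congruency and moment maps.

Phase congruency (PC) marks image locations where the Fourier components
are maximally in phase — edges and corners — independently of local
contrast, which makes it the feature measure of choice for aligning
images from different sensors (here visible vs. long-wave infrared).
The measure is computed from the quadrature (even/odd) responses of a
bank of 2-D log-Gabor filters over several scales and orientations, and
the per-orientation PC maps are then combined by classical moment
analysis into maximum/minimum moment images whose extrema mark corners
(both moments large) and edges (only the maximum moment large).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "LogGaborBankParams",
    "LogGaborBank",
    "FilterResponses",
    "PCMaps",
    "MomentMaps",
    "OrientationIndexMap",
    "build_log_gabor_bank",
    "filter_responses",
    "phase_congruency",
    "moment_maps",
    "orientation_index_map",
    "compute_pc_maps",
]

FloatArray = NDArray[np.floating]


@dataclass(frozen=True)
class LogGaborBankParams:
    """Parameters of the log-Gabor filter bank.

    Attributes
    ----------
    n_scales
        Number of filter scales ``k`` (>= 2).
    n_orientations
        Number of filter orientations ``N_o`` (>= 3), uniformly spaced
        over ``[0, pi)``.
    min_wavelength
        Wavelength in pixels of the finest-scale filter (>= 2).
    scale_mult
        Ratio between the wavelengths of successive scales (> 1).
    sigma_on_f
        Ratio of the radial Gaussian sigma to the filter centre
        frequency, on the log-frequency axis; 0.55 gives ~2 octaves.
    angular_spread
        Standard deviation (radians) of the angular Gaussian.  ``None``
        selects ``(pi / n_orientations) / 2``: the neighbouring lobe
        sits two sigma away, giving clean orientation selectivity while
        the midpoint between lobes still keeps ~60% gain.
    noise_k
        Number of noise standard deviations above the estimated mean
        noise energy used for the soft threshold ``T_N``.
    epsilon
        Small positive constant guarding divisions.
    sigmoid_gain, sigmoid_cutoff
        Gain and cut-off of the sigmoidal frequency-spread weight that
        penalises responses supported by few filter scales.
    """

    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 3.0
    scale_mult: float = 2.1
    sigma_on_f: float = 0.55
    angular_spread: float | None = None
    noise_k: float = 2.0
    epsilon: float = 1e-4
    sigmoid_gain: float = 10.0
    sigmoid_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.n_orientations < 3:
            raise ValueError("n_orientations must be >= 3")
        if self.min_wavelength < 2:
            raise ValueError("min_wavelength must be >= 2 pixels")
        if self.scale_mult <= 1:
            raise ValueError("scale_mult must be > 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def resolved_angular_spread(self) -> float:
        if self.angular_spread is not None:
            return self.angular_spread
        return (np.pi / self.n_orientations) / 2.0

    @property
    def orientation_angles(self) -> NDArray[np.float64]:
        """Filter orientations phi_o, uniformly spaced over [0, pi)."""
        n = self.n_orientations
        return np.arange(n) * np.pi / n

    def wavelength(self, k: int) -> float:
        """Centre wavelength (pixels) of scale ``k`` (0-based)."""
        return self.min_wavelength * self.scale_mult**k


@dataclass(frozen=True)
class LogGaborBank:
    """Frequency-domain transfer functions of a log-Gabor bank.

    ``transfer[k, o]`` is the (real, non-negative) transfer function of
    scale ``k`` / orientation ``o`` on the *padded* frequency grid; the
    filters are one-sided in orientation, so multiplying the image FFT
    and inverse-transforming yields the analytic (even + i*odd) signal.
    """

    params: LogGaborBankParams
    shape: tuple[int, int]
    padded_shape: tuple[int, int]
    pad: int
    transfer: FloatArray  # (n_scales, n_orientations, H_pad, W_pad)

    def radial_profile(self, k: int) -> tuple[FloatArray, FloatArray]:
        """1-D radial gain of scale ``k`` sampled along the +u axis.

        Returns (frequencies, gains) for frequency bins 0..Nyquist of
        the padded grid — useful for locating the gain peak.
        """
        h, w = self.padded_shape
        fx = np.fft.fftfreq(w)
        cols = np.arange(w // 2 + 1)
        # orientation 0 lobe lies along +u; sum over orientations would
        # include angular falloff, so rebuild the pure radial term
        radial = _radial_gain(np.abs(fx[cols]), self.params, k)
        return np.abs(fx[cols]), radial


def _radial_gain(f: FloatArray, params: LogGaborBankParams, k: int) -> FloatArray:
    """Log-Gaussian radial transfer, zero at DC."""
    f0 = 1.0 / params.wavelength(k)
    with np.errstate(divide="ignore"):
        lg = np.exp(-(np.log(np.maximum(f, 1e-300) / f0) ** 2)
                    / (2.0 * np.log(params.sigma_on_f) ** 2))
    lg = np.where(f <= 0, 0.0, lg)
    return lg


def build_log_gabor_bank(
    shape: tuple[int, int],
    params: LogGaborBankParams | None = None,
    *,
    pad: int | None = None,
) -> LogGaborBank:
    """Construct the bank of radial x angular transfer functions.

    Parameters
    ----------
    shape
        Image shape ``(rows, cols)``; both dimensions must be >= 16.
    params
        Bank parameters; defaults are conventional PC settings.
    pad
        Symmetric boundary padding (pixels) applied before filtering to
        suppress FFT wrap-around; defaults to the coarsest wavelength,
        capped at the image half-size.
    """
    params = params or LogGaborBankParams()
    h, w = int(shape[0]), int(shape[1])
    if h < 16 or w < 16:
        raise ValueError(f"image too small for filtering: {h}x{w} (need >= 16x16)")
    if pad is None:
        pad = int(np.ceil(params.wavelength(params.n_scales - 1)))
        pad = min(pad, h // 2, w // 2)
    hp, wp = h + 2 * pad, w + 2 * pad

    fy = np.fft.fftfreq(hp)[:, None]
    fx = np.fft.fftfreq(wp)[None, :]
    radius = np.hypot(fx, fy)
    theta = np.arctan2(-fy, fx)  # image y grows downward
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    # low-pass envelope keeps the coarse scales from picking up the
    # corners of the frequency plane
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))

    spread_sigma = params.resolved_angular_spread
    angles = params.orientation_angles

    transfer = np.empty((params.n_scales, params.n_orientations, hp, wp))
    for o, phi in enumerate(angles):
        # angular distance to the filter axis, wrapped to [-pi, pi]
        ds = sin_t * np.cos(phi) - cos_t * np.sin(phi)
        dc = cos_t * np.cos(phi) + sin_t * np.sin(phi)
        dtheta = np.abs(np.arctan2(ds, dc))
        angular = np.exp(-(dtheta**2) / (2 * spread_sigma**2))
        for k in range(params.n_scales):
            radial = _radial_gain(radius, params, k) * lowpass
            radial.flat[0] = 0.0  # exactly no DC component
            transfer[k, o] = radial * angular
    return LogGaborBank(params=params, shape=(h, w), padded_shape=(hp, wp),
                        pad=pad, transfer=transfer)


@dataclass(frozen=True)
class FilterResponses:
    """Even/odd quadrature responses and their amplitude per (scale, orientation)."""

    even: FloatArray       # (n_scales, n_orientations, H, W)
    odd: FloatArray
    amplitude: FloatArray  # sqrt(even^2 + odd^2)
    params: LogGaborBankParams

    @property
    def n_scales(self) -> int:
        return self.even.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.even.shape[1]


def filter_responses(image: FloatArray, bank: LogGaborBank) -> FilterResponses:
    """Apply the bank to an image; convolution done in the frequency domain.

    The image is padded with its symmetric reflection before the FFT so
    that wrap-around artefacts do not masquerade as edges.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if image.shape != bank.shape:
        raise ValueError(f"image shape {image.shape} != bank shape {bank.shape}")
    bad = ~np.isfinite(image)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-finite pixel value at (row={r}, col={c})")

    pad = bank.pad
    padded = np.pad(image, pad, mode="symmetric") if pad else image
    imfft = np.fft.fft2(padded)

    ns, no = bank.params.n_scales, bank.params.n_orientations
    h, w = bank.shape
    even = np.empty((ns, no, h, w))
    odd = np.empty((ns, no, h, w))
    sl = (slice(pad, pad + h), slice(pad, pad + w))
    for k in range(ns):
        for o in range(no):
            eo = np.fft.ifft2(imfft * bank.transfer[k, o])
            even[k, o] = eo.real[sl]
            odd[k, o] = eo.imag[sl]
    amplitude = np.hypot(even, odd)
    return FilterResponses(even=even, odd=odd, amplitude=amplitude,
                           params=bank.params)


@dataclass(frozen=True)
class PCMaps:
    """Per-orientation phase congruency and its intermediate terms."""

    pc_per_orientation: FloatArray   # (N_o, H, W), values in [0, 1]
    weights: FloatArray              # sigmoidal frequency-spread weight
    noise_thresholds: FloatArray     # (N_o,) soft thresholds T_N
    mean_phase_even: FloatArray      # unit mean-phase vector, even part
    mean_phase_odd: FloatArray
    total_amplitude: FloatArray      # AR_o = |sum_k (even, odd)| + eps
    energy: FloatArray               # summed local energy before thresholding
    orientation_angles: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]


def _rayleigh_noise_threshold(amp_smallest: FloatArray,
                              params: LogGaborBankParams) -> float:
    """Noise energy threshold from the finest-scale amplitude response.

    Assumes the response to noise is Rayleigh distributed; the median of
    the finest-scale amplitude estimates the Rayleigh scale, which is
    extrapolated across scales (amplitude falls as 1/scale_mult) and
    converted to the mean + noise_k sigma of the total noise energy.
    """
    tau = float(np.median(amp_smallest)) / np.sqrt(np.log(4.0))
    inv_m = 1.0 / params.scale_mult
    total_tau = tau * (1.0 - inv_m**params.n_scales) / (1.0 - inv_m)
    mean_noise = total_tau * np.sqrt(np.pi / 2.0)
    sigma_noise = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
    return mean_noise + params.noise_k * sigma_noise


def phase_congruency(responses: FilterResponses,
                     params: LogGaborBankParams | None = None) -> PCMaps:
    """Per-orientation phase congruency from quadrature responses.

    For each orientation the even/odd responses are summed over scales
    into a mean-phase vector; the local energy is the projection of each
    scale's response onto that vector minus the out-of-phase component,
    soft-thresholded by the Rayleigh noise estimate T_N, weighted by the
    sigmoidal frequency-spread term, and normalised by the total
    amplitude so that 0 <= PC <= 1.
    """
    params = params or responses.params
    eps = params.epsilon
    ns, no = responses.n_scales, responses.n_orientations

    even, odd, amp = responses.even, responses.odd, responses.amplitude
    sum_even = even.sum(axis=0)        # (N_o, H, W)
    sum_odd = odd.sum(axis=0)
    sum_amp = amp.sum(axis=0)

    total_amplitude = np.hypot(sum_even, sum_odd) + eps
    mean_even = sum_even / total_amplitude
    mean_odd = sum_odd / total_amplitude

    # local energy: in-phase projection minus |out-of-phase| per scale
    energy = np.zeros_like(sum_even)
    for k in range(ns):
        e_k, o_k = even[k], odd[k]
        energy += (e_k * mean_even + o_k * mean_odd
                   - np.abs(e_k * mean_odd - o_k * mean_even))

    # frequency-spread weight: responses concentrated at one scale are
    # penalised (they signal a sinusoid, not a localised feature)
    max_amp = amp.max(axis=0)
    width = sum_amp / (ns * (max_amp + eps))
    weights = 1.0 / (1.0 + np.exp(params.sigmoid_gain
                                  * (params.sigmoid_cutoff - width)))

    noise_thresholds = np.array([
        _rayleigh_noise_threshold(amp[0, o], params) for o in range(no)
    ])

    pc = weights * np.maximum(energy - noise_thresholds[:, None, None], 0.0)
    pc /= (sum_amp + eps)
    pc = np.clip(pc, 0.0, None)

    return PCMaps(
        pc_per_orientation=pc,
        weights=weights,
        noise_thresholds=noise_thresholds,
        mean_phase_even=mean_even,
        mean_phase_odd=mean_odd,
        total_amplitude=total_amplitude,
        energy=energy,
        orientation_angles=params.orientation_angles,
    )


@dataclass(frozen=True)
class MomentMaps:
    """Orientation-moment accumulators and principal moments of the PC stack.

    ``M`` (maximum moment) is large at both edges and corners; ``m``
    (minimum moment) is large only where PC is high across orientations,
    i.e. at corners.
    """

    p: FloatArray
    q: FloatArray
    r: FloatArray
    M: FloatArray
    m: FloatArray
    orientation_angles: NDArray[np.float64]


def moment_maps(pc: PCMaps) -> MomentMaps:
    """Classical moment analysis across the per-orientation PC maps."""
    stack = pc.pc_per_orientation
    angles = np.asarray(pc.orientation_angles, dtype=float)
    if stack.shape[0] < 1:
        raise ValueError("need at least one orientation")
    cos_phi = np.cos(angles)[:, None, None]
    sin_phi = np.sin(angles)[:, None, None]
    pc_cos = stack * cos_phi
    pc_sin = stack * sin_phi
    p = np.sum(pc_cos**2, axis=0)
    q = 2.0 * np.sum(pc_cos * pc_sin, axis=0)
    r = np.sum(pc_sin**2, axis=0)
    root = np.sqrt(q**2 + (p - r) ** 2)
    M = 0.5 * (r + p + root)
    m = 0.5 * (r + p - root)
    return MomentMaps(p=p, q=q, r=r, M=M, m=m, orientation_angles=angles)


@dataclass(frozen=True)
class OrientationIndexMap:
    """Per-pixel dominant orientation of the scale-summed amplitude.

    ``index`` is 1-based in ``[1, N_o]``; ties break toward the lowest
    index.  Because it is an argmax of amplitudes it is invariant to
    positive rescaling of the input image, which is what makes it usable
    as descriptor material across imaging modalities.
    """

    index: NDArray[np.int64]
    max_amplitude: FloatArray
    n_orientations: int


def orientation_index_map(responses: FilterResponses) -> OrientationIndexMap:
    """Argmax orientation of sum_k MR_ko at every pixel (1-based)."""
    summed = responses.amplitude.sum(axis=0)  # (N_o, H, W)
    index = np.argmax(summed, axis=0).astype(np.int64) + 1
    max_amplitude = summed.max(axis=0)
    return OrientationIndexMap(index=index, max_amplitude=max_amplitude,
                               n_orientations=responses.n_orientations)


def compute_pc_maps(
    image: FloatArray,
    params: LogGaborBankParams | None = None,
) -> tuple[PCMaps, MomentMaps, OrientationIndexMap]:
    """Convenience chain: bank -> responses -> PC -> moments + index map."""
    params = params or LogGaborBankParams()
    bank = build_log_gabor_bank(np.shape(image), params)
    resp = filter_responses(image, bank)
    pc = phase_congruency(resp, params)
    return pc, moment_maps(pc), orientation_index_map(resp)
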