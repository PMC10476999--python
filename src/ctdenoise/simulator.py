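"""Low-dose CT simulation: ray transform, quantum noise, FBP.

Two ways of turning a normal-dose (NDCT) image into a low-dose (LDCT)
counterpart:

*Projection mode* (:func:`simulate_ldct`) follows the physical photon
model.  The HU image is converted to linear attenuation, forward
projected with a parallel-beam ray transform to line integrals
``p_i``, and the measured counts along each ray are drawn as

    c_i = K * Poisson(N0_eff * exp(-p_i)),      N0_eff = N0 * dose_fraction,

i.e. Beer-Lambert attenuation of the incident intensity followed by
photon-counting (Poisson) noise.  Counts are log-converted back to
noisy line integrals (with a one-count photon-starvation floor) and
reconstructed by filtered back-projection.  Quantum noise in the
reconstruction then scales like ``1/sqrt(dose_fraction)``: quarter dose
doubles the noise standard deviation.

*Image mode* (:func:`inject_image_noise`) is the fast shortcut used
when projection data are unavailable: each pixel's attenuation value is
pushed through a single-ray Beer-Lambert intensity proxy
``I = N0_eff * exp(-mu * L_eff)``, Poisson-sampled and inverted.  It
reproduces the dose dependence of the noise magnitude but not its
streaky spatial correlation.

Geometry is parallel-beam only: equi-spaced angles over [0, pi),
detector count equal to the padded image diagonal, linear-interpolation
back-projection (via scikit-image's radon/iradon).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import radon as _sk_radon
from skimage.transform import iradon as _sk_iradon

from .imaging_core import CTImage, Domain

__all__ = [
    "SinogramDomain",
    "Sinogram",
    "DoseModel",
    "Geometry",
    "MU_WATER_MM",
    "hu_to_attenuation",
    "attenuation_to_hu",
    "radon",
    "add_quantum_noise",
    "counts_to_line_integrals",
    "fbp",
    "simulate_ldct",
    "inject_image_noise",
]

#: Linear attenuation coefficient of water (mm^-1) at ~120 kVp.
MU_WATER_MM = 0.0192


class SinogramDomain(enum.Enum):
    LINE_INTEGRAL = "LINE_INTEGRAL"
    COUNTS = "COUNTS"


@dataclass(frozen=True)
class Sinogram:
    """Projection-domain grid: n_angles x n_detectors.

    ``values`` holds dimensionless line integrals (optical depth) or
    photon counts depending on ``domain``.
    """

    values: np.ndarray
    angles: np.ndarray
    detector_spacing: float
    domain: SinogramDomain

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        a = np.asarray(self.angles, dtype=np.float64)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "angles", a)
        if v.ndim != 2:
            raise ValueError("sinogram values must be 2-D (angles x detectors)")
        if a.shape != (v.shape[0],):
            raise ValueError("angles length must equal the number of projections")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DoseModel:
    """Photon budget of the acquisition.

    N0 is the incident photon intensity per detector bin at full dose;
    dose_fraction scales it (0.25 = quarter dose); K is the
    photon-to-electron conversion gain (1 = pure photon counting).
    """

    N0: float = 1.0e5
    K: float = 1.0
    dose_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N0 <= 0 or self.K <= 0:
            raise ValueError("N0 and K must be positive")
        if not (0 < self.dose_fraction <= 1.0):
            raise ValueError("dose_fraction must be in (0, 1]")

    @property
    def n0_effective(self) -> float:
        return self.N0 * self.dose_fraction


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry."""

    n_angles: int = 180

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("need at least one projection angle")


# ---------------------------------------------------------------------------
# HU <-> attenuation
# ---------------------------------------------------------------------------


def hu_to_attenuation(image: CTImage, mu_water: float = MU_WATER_MM) -> CTImage:
    """mu = mu_water * (1 + HU/1000), clipped at 0 (units mm^-1)."""
    if image.domain is not Domain.HU:
        raise ValueError(f"expected an HU image, got {image.domain}")
    mu = np.clip(mu_water * (1.0 + image.pixels / 1000.0), 0.0, None)
    return image.with_pixels(mu, domain=Domain.ATTENUATION)


def attenuation_to_hu(image: CTImage, mu_water: float = MU_WATER_MM) -> CTImage:
    """Inverse of :func:`hu_to_attenuation` (exact for HU >= -1000)."""
    if image.domain is not Domain.ATTENUATION:
        raise ValueError(f"expected an ATTENUATION image, got {image.domain}")
    hu = 1000.0 * (image.pixels / mu_water - 1.0)
    return image.with_pixels(hu, domain=Domain.HU)


# ---------------------------------------------------------------------------
# Ray transform and FBP
# ---------------------------------------------------------------------------


def radon(image: CTImage, geometry: Geometry = Geometry()) -> Sinogram:
    """Parallel-beam line integrals of an attenuation image.

    Angles are equi-spaced over [0, pi); the image is padded to its
    diagonal so nothing falls outside the field of view.  Pixel spacing
    converts the pixel-unit path length into mm, making the line
    integrals dimensionless optical depths.  Linear in the input.
    """
    if image.domain is not Domain.ATTENUATION:
        raise ValueError(f"radon expects an ATTENUATION image, got {image.domain}")
    theta_deg = np.arange(geometry.n_angles) * (180.0 / geometry.n_angles)
    sino = _sk_radon(image.pixels, theta=theta_deg, circle=False)
    # skimage returns (detectors, angles) with unit pixel size
    values = sino.T * image.pixel_spacing
    return Sinogram(
        values=values,
        angles=np.deg2rad(theta_deg),
        detector_spacing=image.pixel_spacing,
        domain=SinogramDomain.LINE_INTEGRAL,
    )


def fbp(
    sino: Sinogram,
    output_size: int,
    filter_name: str = "ramp",
    pixel_spacing: float | None = None,
) -> CTImage:
    """Filtered back-projection of a line-integral sinogram.

    ``filter_name`` is "ramp" (default) or "hann" (Hann-apodized ramp).
    Returns an ATTENUATION image of ``output_size x output_size``.
    Linear; a zero sinogram reconstructs to a zero image.  Fewer than 8
    angles is allowed but flagged with a degraded-quality warning.
    """
    if sino.domain is not SinogramDomain.LINE_INTEGRAL:
        raise ValueError("fbp expects LINE_INTEGRAL sinograms (log-convert counts first)")
    if filter_name not in ("ramp", "hann"):
        raise ValueError("filter must be 'ramp' or 'hann'")
    if sino.n_angles < 8:
        import warnings

        warnings.warn(
            f"FBP from only {sino.n_angles} angles: reconstruction quality degraded",
            RuntimeWarning,
            stacklevel=2,
        )
    spacing = sino.detector_spacing if pixel_spacing is None else pixel_spacing
    recon = _sk_iradon(
        (sino.values / spacing).T,
        theta=np.rad2deg(sino.angles),
        filter_name=filter_name,
        circle=False,
        output_size=output_size,
    )
    return CTImage(pixels=recon, domain=Domain.ATTENUATION, pixel_spacing=spacing)


# ---------------------------------------------------------------------------
# Quantum noise
# ---------------------------------------------------------------------------


def _rng(seed: int) -> np.random.Generator:
    # Philox: counter-based, reproducible across platforms
    return np.random.Generator(np.random.Philox(key=seed))


def add_quantum_noise(sino: Sinogram, dose: DoseModel) -> Sinogram:
    """Poisson photon counting: c = K * Poisson(N0_eff * exp(-p)).

    Reproducible given ``dose.seed``.
    """
    if sino.domain is not SinogramDomain.LINE_INTEGRAL:
        raise ValueError("quantum noise is added to LINE_INTEGRAL sinograms")
    if np.any(sino.values < 0):
        raise ValueError("line integrals must be non-negative")
    rate = dose.n0_effective * np.exp(-sino.values)
    counts = dose.K * _rng(dose.seed).poisson(rate).astype(np.float64)
    return replace(sino, values=counts, domain=SinogramDomain.COUNTS)


def counts_to_line_integrals(sino: Sinogram, dose: DoseModel, count_floor: float = 1.0) -> Sinogram:
    """Invert the exponential: p_hat = -ln(max(c/K, floor) / N0_eff).

    The one-count floor keeps photon-starved (zero-count) bins finite.
    """
    if sino.domain is not SinogramDomain.COUNTS:
        raise ValueError("expected a COUNTS sinogram")
    photons = np.maximum(sino.values / dose.K, count_floor)
    p = -np.log(photons / dose.n0_effective)
    return replace(sino, values=p, domain=SinogramDomain.LINE_INTEGRAL)


# ---------------------------------------------------------------------------
# End-to-end simulation
# ---------------------------------------------------------------------------


def simulate_ldct(
    ndct: CTImage,
    dose: DoseModel = DoseModel(),
    geometry: Geometry = Geometry(),
    filter_name: str = "ramp",
) -> CTImage:
    """Full projection-domain LDCT simulation of an NDCT image.

    hu -> attenuation -> radon -> Poisson counts -> log -> FBP ->
    attenuation -> hu.  Deterministic given ``dose.seed``; noise
    magnitude decreases as dose_fraction -> 1 or N0 -> inf.
    """
    mu = hu_to_attenuation(ndct)
    clean = radon(mu, geometry)
    noisy_counts = add_quantum_noise(clean, dose)
    noisy_p = counts_to_line_integrals(noisy_counts, dose)
    recon = fbp(noisy_p, output_size=ndct.height, filter_name=filter_name)
    return attenuation_to_hu(recon)


def fbp_reference(
    ndct: CTImage, geometry: Geometry = Geometry(), filter_name: str = "ramp"
) -> CTImage:
    """Noiseless radon -> FBP round trip of an NDCT image.

    The proper comparison baseline for simulated LDCT images: it shares
    the (small, deterministic) reconstruction error of the discrete
    FBP, so differences from it are pure quantum noise.
    """
    mu = hu_to_attenuation(ndct)
    recon = fbp(radon(mu, geometry), output_size=ndct.height, filter_name=filter_name)
    return attenuation_to_hu(recon)


def inject_image_noise(
    ndct: CTImage, dose: DoseModel = DoseModel(), path_length_mm: float = 100.0
) -> CTImage:
    """Mayo-style direct image-domain Poisson noise insertion.

    Per-pixel intensity proxy ``I = N0_eff * exp(-mu * L_eff)`` with a
    fixed effective path length ``L_eff`` (mm), Poisson-sampled, then
    inverted back to HU.  An approximation: correct dose scaling of the
    noise magnitude, no projection-domain correlation.
    """
    mu = hu_to_attenuation(ndct)
    rate = dose.n0_effective * np.exp(-mu.pixels * path_length_mm)
    counts = np.maximum(_rng(dose.seed).poisson(rate).astype(np.float64), 1.0)
    mu_hat = -np.log(counts / dose.n0_effective) / path_length_mm
    noisy = mu.with_pixels(mu_hat, domain=Domain.ATTENUATION)
    return attenuation_to_hu(noisy)
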