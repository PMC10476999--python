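"""Synthetic abdomen-like CT phantoms and paired NDCT/LDCT datasets.

Clinical training data for low-dose CT denoising (paired normal-dose /
quarter-dose slices) cannot ship with the package, so this module
generates ellipse-composition phantoms that exercise the same image
features the loss is designed around:

* piecewise-constant anatomy-like regions (air, fat, soft tissue, liver),
* at least one high-attenuation bone-like structure (spine, >300 HU),
* at least one low-contrast lesion (|contrast| <= 50 HU),
* at least one textured region (band-limited correlated noise), whose
  elevated high-frequency energy is what makes it hard to denoise.

HU palette (fixed constants): air -1000, fat -90, soft tissue 40,
liver 55, lesion 55 + contrast, bone 700.

Everything is deterministic given the spec seed; dataset generation
writes a JSON manifest from which the pairs can be regenerated
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .imaging_core import CTImage, Domain, write_image
from .simulator import DoseModel, Geometry, simulate_ldct, inject_image_noise

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "regenerate_dataset"]

HU_AIR = -1000.0
HU_FAT = -90.0
HU_SOFT = 40.0
HU_LIVER = 55.0
HU_BONE = 700.0

#: Physical body extent emulated by a phantom (mm); pixel spacing is
#: derived from it so line integrals stay body-like at any grid size.
BODY_EXTENT_MM = 350.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``size`` must be >= 32 and divisible by 4 (the default patch grid).
    ``lesion_contrast`` is the lesion-minus-liver HU difference
    (|contrast| <= 50: low-contrast by construction).
    ``texture_amplitude`` (HU std) and ``texture_correlation_length``
    (pixels) shape the band-limited texture field.
    """

    size: int = 224
    n_ellipses: int = 4
    bone_fraction: float = 0.04
    lesion_contrast: float = -20.0
    texture_amplitude: float = 25.0
    texture_correlation_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError(f"phantom size must be >= 32, got {self.size}")
        if self.size % 4:
            raise ValueError("phantom size must be divisible by 4 (patch grid)")
        if abs(self.lesion_contrast) > 50:
            raise ValueError("lesion contrast must satisfy |contrast| <= 50 HU")
        if self.texture_amplitude < 0 or self.texture_correlation_length <= 0:
            raise ValueError("texture parameters out of range")

    @property
    def pixel_spacing(self) -> float:
        return BODY_EXTENT_MM / self.size


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float, angle: float = 0.0) -> np.ndarray:
    """Boolean ellipse in normalized [-1, 1] coordinates."""
    coords = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    yr = (yy - cy) * ca + (xx - cx) * sa
    xr = -(yy - cy) * sa + (xx - cx) * ca
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def _band_limited_noise(size: int, corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-std correlated noise via frequency-domain Gaussian shaping."""
    white = rng.standard_normal((size, size))
    fu = np.fft.fftfreq(size)[:, None]
    fv = np.fft.fftfreq(size)[None, :]
    rho2 = fu**2 + fv**2
    shaping = np.exp(-0.5 * rho2 * (2.0 * np.pi * corr_len) ** 2)
    shaped = np.real(np.fft.ifft2(np.fft.fft2(white) * shaping))
    std = shaped.std()
    return shaped / std if std > 0 else shaped


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> CTImage:
    """Deterministic HU-domain phantom per ``spec`` (values in [-1000, 2000])."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    img = np.full((size, size), HU_AIR)

    # body outline: fat layer with soft tissue interior
    body_ry = 0.78 + 0.04 * rng.uniform(-1, 1)
    body_rx = 0.88 + 0.04 * rng.uniform(-1, 1)
    body = _ellipse_mask(size, 0.0, 0.0, body_ry, body_rx)
    img[body] = HU_FAT
    interior = _ellipse_mask(size, 0.0, 0.0, body_ry - 0.08, body_rx - 0.08)
    img[interior] = HU_SOFT

    # random organ-like ellipses inside the interior
    for _ in range(spec.n_ellipses):
        cy, cx = rng.uniform(-0.35, 0.35, size=2)
        ry, rx = rng.uniform(0.08, 0.25, size=2)
        hu = rng.uniform(20.0, 80.0)
        mask = _ellipse_mask(size, cy, cx, ry, rx, angle=rng.uniform(0, np.pi))
        img[mask & interior] = hu

    # liver: large right-side region hosting texture and the lesion
    liver = _ellipse_mask(size, -0.12, 0.30, 0.30, 0.34, angle=0.3)
    liver &= interior
    img[liver] = HU_LIVER

    # spine: bone-like high-attenuation structure near the posterior
    bone_r = float(np.sqrt(spec.bone_fraction))
    bone = _ellipse_mask(size, 0.52, 0.0, bone_r, bone_r)
    img[bone & body] = HU_BONE

    # low-contrast lesion inside the liver
    lesion = _ellipse_mask(size, -0.12, 0.38, 0.07, 0.06)
    img[lesion & liver] = HU_LIVER + spec.lesion_contrast

    # band-limited texture within the liver (lesion kept clean)
    if spec.texture_amplitude > 0:
        texture = _band_limited_noise(size, spec.texture_correlation_length, rng)
        region = liver & ~lesion
        img[region] += spec.texture_amplitude * texture[region]

    np.clip(img, -1000.0, 2000.0, out=img)
    return CTImage(pixels=img, domain=Domain.HU, pixel_spacing=spec.pixel_spacing)


# ---------------------------------------------------------------------------
# Paired dataset generation
# ---------------------------------------------------------------------------


def _derive_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def _assign_splits(n: int) -> list[str]:
    """Train/val/test 6:2:2 by index (exact when n is divisible by 5)."""
    n_train = round(0.6 * n)
    n_val = round(0.2 * n)
    return ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)


def generate_dataset(
    n: int,
    spec: PhantomSpec = PhantomSpec(),
    dose: DoseModel = DoseModel(dose_fraction=0.25),
    out_dir: str | Path = "data",
    mode: str = "projection",
    n_angles: int = 180,
) -> dict:
    """Write ``n`` NDCT/LDCT pairs plus a manifest; return the manifest.

    Each pair gets phantom and noise seeds derived from ``spec.seed``,
    and a 6:2:2 train/val/test split assignment.  ``mode`` selects the
    projection-domain simulator or the fast image-domain noise
    insertion.
    """
    if mode not in ("projection", "image"):
        raise ValueError("mode must be 'projection' or 'image'")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    splits = _assign_splits(n)
    entries = []
    for i in range(n):
        phantom_seed = _derive_seed(spec.seed, 1, i)
        noise_seed = _derive_seed(spec.seed, 2, i)
        entry = {
            "index": i,
            "phantom_seed": phantom_seed,
            "noise_seed": noise_seed,
            "split": splits[i],
            "ndct": f"ndct_{i:04d}.npy",
            "ldct": f"ldct_{i:04d}.npy",
        }
        _write_pair(out, entry, spec, dose, mode, n_angles)
        entries.append(entry)

    manifest = {
        "n": n,
        "mode": mode,
        "n_angles": n_angles,
        "spec": asdict(spec),
        "dose": asdict(dose),
        "entries": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_pair(out: Path, entry: dict, spec: PhantomSpec, dose: DoseModel, mode: str, n_angles: int) -> None:
    ndct = generate_phantom(replace(spec, seed=entry["phantom_seed"]))
    pair_dose = replace(dose, seed=entry["noise_seed"])
    if mode == "projection":
        ldct = simulate_ldct(ndct, pair_dose, Geometry(n_angles=n_angles))
    else:
        ldct = inject_image_noise(ndct, pair_dose)
    write_image(ndct, out / entry["ndct"])
    write_image(ldct, out / entry["ldct"])


def regenerate_dataset(manifest: dict | str | Path, out_dir: str | Path) -> None:
    """Rebuild every pair listed in a manifest, bit-identically."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(**manifest["spec"])
    dose = DoseModel(**manifest["dose"])
    for entry in manifest["entries"]:
        _write_pair(out, entry, spec, dose, manifest["mode"], manifest["n_angles"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
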