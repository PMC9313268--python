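"""Synthetic ground-truth phantoms for the measurement and processing chains.

Two generators live here:

* bright-field transmittance pairs — a blank illumination image and the same
  field attenuated by ``exp(-mu * L)`` inside a sample mask, with optional
  vignetting and per-exposure shot/read noise; and
* SPIM-like fluorescence stacks — Gaussian nuclei blobs and piecewise-linear
  vessel tubes corrupted by multiplicative sinusoidal stripes (constant along
  one axis) and salt-and-pepper impulse noise.

Both retain the clean/ground-truth data alongside the corrupted output so
recovery and filter-quality tests can score against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .attenuation import TransmittanceImagePair
from .errors import InvalidSpecError
from .stack_processing import FluorescenceStack

__all__ = [
    "NoiseModel",
    "TransmittancePhantomSpec",
    "TransmittancePhantom",
    "StackPhantomSpec",
    "StackPhantom",
    "generate_transmittance_pair",
    "generate_fluorescence_stack",
    "vignette_field",
]


# ---------------------------------------------------------------------------
# transmittance phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Detector noise description.

    ``kind`` is one of ``"none"``, ``"gaussian"`` (additive, standard
    deviation ``sigma`` in detector units) or ``"poisson"`` (shot noise with
    ``gain`` photoelectrons per detector unit).
    """

    kind: str = "none"
    sigma: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise InvalidSpecError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma < 0:
            raise InvalidSpecError("gaussian sigma must be >= 0")
        if self.kind == "poisson" and self.gain <= 0:
            raise InvalidSpecError("poisson gain must be > 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return clean.copy()
        if self.kind == "gaussian":
            noisy = clean + rng.normal(0.0, self.sigma, size=clean.shape)
        else:
            noisy = rng.poisson(clean * self.gain).astype(np.float64) / self.gain
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class TransmittancePhantomSpec:
    """Generative parameters of one blank/sample transmittance pair.

    ``mu_true`` (1/mm) may be a scalar or a full 2-D map; ``thickness_mm`` is
    the light-path length L; ``illumination_level`` the mean blank intensity
    in detector units.  ``vignette_strength`` in ``[0, 1)`` scales a radially
    symmetric cosine-fourth falloff.  ``sample_mask`` restricts attenuation
    to a tissue footprint (default: full frame).
    """

    image_height_px: int
    image_width_px: int
    mu_true: Union[float, np.ndarray] = 1.0
    thickness_mm: float = 1.0
    illumination_level: float = 10000.0
    vignette_strength: float = 0.0
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    sample_mask: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise InvalidSpecError("image dimensions must be positive")
        mu = np.asarray(self.mu_true, dtype=np.float64)
        if mu.ndim not in (0, 2):
            raise InvalidSpecError("mu_true must be a scalar or a 2-D map")
        if mu.ndim == 2 and mu.shape != (self.image_height_px, self.image_width_px):
            raise InvalidSpecError(
                f"mu_true map shape {mu.shape} does not match image shape "
                f"({self.image_height_px}, {self.image_width_px})"
            )
        if (mu < 0).any() or not np.isfinite(mu).all():
            raise InvalidSpecError("mu_true must be finite and >= 0 everywhere")
        if not self.thickness_mm > 0:
            raise InvalidSpecError("thickness_mm must be > 0")
        if not self.illumination_level > 0:
            raise InvalidSpecError("illumination_level must be > 0")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise InvalidSpecError("vignette_strength must be in [0, 1)")
        if self.sample_mask is not None:
            mask = np.asarray(self.sample_mask)
            if mask.shape != (self.image_height_px, self.image_width_px):
                raise InvalidSpecError("sample_mask shape must match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height_px, self.image_width_px)

    def mu_map(self) -> np.ndarray:
        mu = np.asarray(self.mu_true, dtype=np.float64)
        if mu.ndim == 0:
            mu = np.full(self.shape, float(mu))
        if self.sample_mask is not None:
            mu = np.where(np.asarray(self.sample_mask, dtype=bool), mu, 0.0)
        return mu


@dataclass
class TransmittancePhantom:
    """A generated pair plus its noise-free images and ground-truth mu map."""

    pair: TransmittanceImagePair
    mu_true_map: np.ndarray
    blank_clean: np.ndarray
    sample_clean: np.ndarray
    spec: TransmittancePhantomSpec


def vignette_field(height_px: int, width_px: int, strength: float) -> np.ndarray:
    """Radially symmetric cosine-fourth illumination falloff.

    Unity at the image center; the corner value is ``1 - 0.75 * strength``.
    """
    yy, xx = np.mgrid[0:height_px, 0:width_px].astype(np.float64)
    cy, cx = (height_px - 1) / 2.0, (width_px - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_max = math.hypot(cy, cx) or 1.0
    theta = (r / r_max) * (math.pi / 4.0)
    return 1.0 - strength * (1.0 - np.cos(theta) ** 4)


def generate_transmittance_pair(
    spec: TransmittancePhantomSpec,
    sample_id: str = "",
    condition: str = "",
) -> TransmittancePhantom:
    """Generate one blank/sample pair from the Beer–Lambert forward model.

    The blank is ``illumination_level x vignette`` plus noise; the sample
    image is the same clean field multiplied by ``exp(-mu_true * L)`` inside
    the mask, plus an independent noise draw (two separate exposures).  All
    intensities are clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    field_img = spec.illumination_level * vignette_field(
        spec.image_height_px, spec.image_width_px, spec.vignette_strength
    )
    mu_map = spec.mu_map()
    blank_clean = field_img
    sample_clean = field_img * np.exp(-mu_map * spec.thickness_mm)
    blank = spec.noise_model.apply(blank_clean, rng)
    sample = spec.noise_model.apply(sample_clean, rng)
    pair = TransmittanceImagePair(
        blank_image=blank,
        sample_image=sample,
        thickness_mm=spec.thickness_mm,
        sample_id=sample_id,
        condition=condition,
    )
    return TransmittancePhantom(
        pair=pair,
        mu_true_map=mu_map,
        blank_clean=blank_clean.copy(),
        sample_clean=sample_clean,
        spec=spec,
    )


def write_pair_tiff(
    phantom: TransmittancePhantom,
    blank_path,
    sample_path,
) -> None:
    """Write a generated pair as 16-bit TIFFs (values rounded to integers).

    Intensities are stored in detector units, clipped to the uint16 range;
    the quantization step is therefore one detector unit.  Choose
    ``illumination_level`` well inside ``[0, 65535]`` to use the range.
    """
    import tifffile

    for arr, path in ((phantom.pair.blank_image, blank_path),
                      (phantom.pair.sample_image, sample_path)):
        q = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, q)


# ---------------------------------------------------------------------------
# fluorescence stack phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackPhantomSpec:
    """Generative parameters of a two-channel SPIM-like stack phantom.

    ``stripe_axis`` names the axis along which stripe intensity is constant
    (the illumination propagation axis); the sinusoidal modulation varies
    along the in-plane axis perpendicular to it.  ``impulse_fraction`` of the
    voxels (an exact count, chosen without replacement) are replaced by
    min/max impulse values.
    """

    shape_zyx: tuple[int, int, int] = (16, 64, 64)
    n_nuclei: int = 20
    nucleus_sigma_px: float = 2.0
    n_vessels: int = 3
    vessel_radius_px: float = 2.0
    stripe_axis: int = 2
    stripe_amplitude: float = 0.0
    stripe_period_px: float = 8.0
    impulse_fraction: float = 0.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape_zyx) != 3 or any(s < 1 for s in self.shape_zyx):
            raise InvalidSpecError("shape_zyx must be three positive integers")
        if self.background_level < 0:
            raise InvalidSpecError("background_level must be >= 0")
        if self.n_nuclei < 0 or self.n_vessels < 0:
            raise InvalidSpecError("object counts must be >= 0")
        if self.nucleus_sigma_px <= 0 or self.vessel_radius_px <= 0:
            raise InvalidSpecError("object sizes must be > 0")
        if self.stripe_axis not in (1, 2):
            raise InvalidSpecError("stripe_axis must be an in-plane axis (1 or 2)")
        if not 0.0 <= self.stripe_amplitude < 1.0:
            raise InvalidSpecError("stripe_amplitude must be in [0, 1)")
        if self.stripe_period_px <= 0:
            raise InvalidSpecError("stripe_period_px must be > 0")
        if not 0.0 <= self.impulse_fraction < 1.0:
            raise InvalidSpecError("impulse_fraction must be in [0, 1)")


@dataclass
class StackPhantom:
    """Corrupted two-channel stack plus the clean pre-corruption volumes.

    ``nuclei_impulse_indices`` / ``vessels_impulse_indices`` list the flat
    voxel indices replaced by impulse noise in each channel (exact count
    ``round(impulse_fraction * n_voxels)``).
    """

    nuclei: FluorescenceStack
    vessels: FluorescenceStack
    nuclei_clean: np.ndarray
    vessels_clean: np.ndarray
    spec: StackPhantomSpec
    nuclei_impulse_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp))
    vessels_impulse_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.intp))


def _render_nuclei(spec: StackPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = spec.shape_zyx
    vol = np.zeros(spec.shape_zyx, dtype=np.float64)
    sigma = spec.nucleus_sigma_px
    half = max(1, int(math.ceil(3.0 * sigma)))
    for _ in range(spec.n_nuclei):
        cz = rng.uniform(0, nz)
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        z0, z1 = max(0, int(cz) - half), min(nz, int(cz) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(np.float64)
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        vol[z0:z1, y0:y1, x0:x1] += np.exp(-d2 / (2.0 * sigma**2))
    return vol


def _render_vessels(spec: StackPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = spec.shape_zyx
    vol = np.zeros(spec.shape_zyx, dtype=np.float64)
    if spec.n_vessels == 0:
        return vol
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    inside = np.zeros(pts.shape[0], dtype=bool)
    n_waypoints = 3
    for _ in range(spec.n_vessels):
        # a piecewise-linear path wandering through the volume
        way = rng.uniform([0, 0, 0], [nz, ny, nx], size=(n_waypoints + 1, 3))
        for a, b in zip(way[:-1], way[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                continue
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            closest = a + t[:, None] * ab
            d2 = ((pts - closest) ** 2).sum(axis=1)
            inside |= d2 <= spec.vessel_radius_px**2
    vol.ravel()[inside] = 1.0
    return vol


def _apply_stripes(vol: np.ndarray, spec: StackPhantomSpec,
                   rng: np.random.Generator) -> np.ndarray:
    if spec.stripe_amplitude == 0.0:
        return vol.copy()
    # modulation varies along the in-plane axis perpendicular to stripe_axis
    mod_axis = 1 if spec.stripe_axis == 2 else 2
    n = vol.shape[mod_axis]
    phase = rng.uniform(0, 2 * math.pi)
    coord = np.arange(n, dtype=np.float64)
    mod = 1.0 + spec.stripe_amplitude * np.sin(
        2.0 * math.pi * coord / spec.stripe_period_px + phase
    )
    shape = [1, 1, 1]
    shape[mod_axis] = n
    return vol * mod.reshape(shape)


def _apply_impulses(
    vol: np.ndarray, spec: StackPhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    out = vol.copy()
    n_total = vol.size
    n_bad = int(math.floor(spec.impulse_fraction * n_total + 0.5))
    if n_bad == 0:
        return out, np.empty(0, dtype=np.intp)
    idx = rng.choice(n_total, size=n_bad, replace=False)
    salt = rng.random(n_bad) < 0.5
    vmax = float(vol.max()) or 1.0
    flat = out.ravel()
    flat[idx[salt]] = vmax
    flat[idx[~salt]] = 0.0
    return out, idx.astype(np.intp)


def generate_fluorescence_stack(
    spec: StackPhantomSpec,
    voxel_spacing_um: tuple[float, float, float] = (5.0, 1.0, 1.0),
) -> StackPhantom:
    """Generate nuclei and vessel channels with stripe and impulse corruption.

    The same corruption (stripes, then impulses) is applied independently to
    each channel; the clean pre-corruption volumes are retained.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei_clean = _render_nuclei(spec, rng) + spec.background_level
    vessels_clean = _render_vessels(spec, rng) + spec.background_level
    channels, impulse_idx = [], []
    for clean in (nuclei_clean, vessels_clean):
        striped = _apply_stripes(clean, spec, rng)
        corrupted, idx = _apply_impulses(striped, spec, rng)
        channels.append(np.clip(corrupted, 0.0, None))
        impulse_idx.append(idx)
    return StackPhantom(
        nuclei=FluorescenceStack(channels[0], channel="nuclei",
                                 voxel_spacing_um=voxel_spacing_um),
        vessels=FluorescenceStack(channels[1], channel="vessels",
                                  voxel_spacing_um=voxel_spacing_um),
        nuclei_clean=nuclei_clean,
        vessels_clean=vessels_clean,
        spec=spec,
        nuclei_impulse_indices=impulse_idx[0],
        vessels_impulse_indices=impulse_idx[1],
    )
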