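"""Beer–Lambert attenuation estimation from paired bright-field images.

The transmitted-light forward model is ``I = I0 * exp(-mu * L)`` with ``I0``
the incident (blank) intensity, ``I`` the transmitted intensity, ``mu`` the
attenuation coefficient in 1/mm and ``L`` the sample thickness in mm.  The
per-region estimate inverts the forward model on region-mean intensities:

    mu = ln(mean(I0_region) / mean(I_region)) / L

Note on orientation: ``ln(I/I0)/L`` (the sign-flipped ratio) is negative for
any absorbing sample; this module uses ``ln(I0/I)/L`` so that more opaque
samples yield larger, nonnegative coefficients, consistent with the forward
equation.  Both readings differ only in sign.

The randomized measurement protocol draws ``regions_per_run`` rectangular
regions per run (each side a fixed fraction of the image side), repeats
``runs_per_image`` runs per image, and pools every region-level coefficient
across a sample's images into one mean +/- SEM.  At the defaults
(3 regions x 15 runs x 3 images) that is 135 individual measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .errors import (
    DegenerateRegionError,
    InvalidInputError,
    ProtocolFailureError,
    RegionBoundsError,
)

#: Intensity floor (detector units) applied before region averaging so that
#: zero-valued pixels cannot produce infinite log-ratios.
INTENSITY_FLOOR = 1e-6

#: Rec. 601 luminance weights used to collapse RGB input to one channel.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TransmittanceImagePair:
    """A blank/sample image pair with the light-path thickness.

    Parameters
    ----------
    blank_image
        2-D nonnegative incident-light intensity grid (acquired without the
        sample).
    sample_image
        2-D nonnegative transmitted-light intensity grid (acquired with the
        sample), same shape as ``blank_image``.
    thickness_mm
        Light-path length through the sample, mm; strictly positive.
    sample_id, condition
        Free-text labels carried through to measurement provenance.
    """

    blank_image: np.ndarray
    sample_image: np.ndarray
    thickness_mm: float
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.blank_image = np.asarray(self.blank_image, dtype=np.float64)
        self.sample_image = np.asarray(self.sample_image, dtype=np.float64)
        if self.blank_image.ndim != 2 or self.sample_image.ndim != 2:
            raise InvalidInputError("images must be 2-D grids")
        if self.blank_image.shape != self.sample_image.shape:
            raise InvalidInputError(
                f"blank shape {self.blank_image.shape} != "
                f"sample shape {self.sample_image.shape}"
            )
        if not (np.isfinite(self.blank_image).all()
                and np.isfinite(self.sample_image).all()):
            raise InvalidInputError("image intensities must be finite")
        if (self.blank_image < 0).any() or (self.sample_image < 0).any():
            raise InvalidInputError("image intensities must be >= 0")
        if not (math.isfinite(self.thickness_mm) and self.thickness_mm > 0):
            raise InvalidInputError(
                f"thickness_mm must be positive, got {self.thickness_mm!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.blank_image.shape


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular image region, half-open ``[origin, origin + size)``.

    Coordinates are 0-based, row-major, origin at the top-left corner.
    """

    row_origin: int
    col_origin: int
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise InvalidInputError("region sides must be >= 1 px")
        if self.row_origin < 0 or self.col_origin < 0:
            raise RegionBoundsError("region origin must be nonnegative")

    def check_bounds(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        if self.row_origin + self.height_px > h or self.col_origin + self.width_px > w:
            raise RegionBoundsError(
                f"region {self} exceeds image bounds {image_shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_origin, self.row_origin + self.height_px),
            slice(self.col_origin, self.col_origin + self.width_px),
        )


@dataclass(frozen=True)
class ProtocolParams:
    """Parameters of the randomized region-sampling protocol.

    ``region_fraction_mode`` selects how the region fraction is read:
    ``"linear"`` makes each region side the given fraction of the matching
    image side (default); ``"area"`` makes the region *area* that fraction of
    the image area (side scale ``sqrt(fraction)``).
    """

    regions_per_run: int = 3
    runs_per_image: int = 15
    region_fraction: float = 0.15
    seed: int = 0
    region_fraction_mode: str = "linear"
    max_resample_attempts: int = 10

    def __post_init__(self) -> None:
        if self.regions_per_run < 1 or self.runs_per_image < 1:
            raise InvalidInputError("counts must be >= 1")
        if not 0.0 < self.region_fraction <= 1.0:
            raise InvalidInputError("region_fraction must be in (0, 1]")
        if self.region_fraction_mode not in ("linear", "area"):
            raise InvalidInputError(
                f"unknown region_fraction_mode {self.region_fraction_mode!r}"
            )
        if self.max_resample_attempts < 1:
            raise InvalidInputError("max_resample_attempts must be >= 1")


@dataclass(frozen=True)
class AttenuationMeasurement:
    """One region-level attenuation coefficient with its provenance."""

    mu: float
    region: RegionSpec
    run_index: int
    image_index: int
    mean_blank: float
    mean_sample: float


@dataclass
class SampleAttenuationSummary:
    """All individual measurements for one sample, collapsed to mean +/- SEM."""

    sample_id: str
    condition: str
    measurements: list[AttenuationMeasurement]
    mu_mean: float
    mu_sem: float
    n_measurements: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def region_mu(
    pair: TransmittanceImagePair,
    region: RegionSpec,
    *,
    run_index: int = 0,
    image_index: int = 0,
) -> AttenuationMeasurement:
    """Compute the attenuation coefficient of one region.

    Intensities are floored at :data:`INTENSITY_FLOOR` before averaging.  The
    result is ``ln(mean_blank / mean_sample) / thickness_mm`` and is *not*
    clipped at zero: slightly negative values on noisy near-transparent
    regions are kept so that averaging over many regions stays unbiased.

    Raises
    ------
    RegionBoundsError
        If the region does not fit inside the images.
    DegenerateRegionError
        If the floored region-mean sample intensity is at the floor, which
        would produce an unbounded coefficient.
    """
    region.check_bounds(pair.shape)
    rows, cols = region.slices()
    mean_blank = float(
        np.maximum(pair.blank_image[rows, cols], INTENSITY_FLOOR).mean()
    )
    mean_sample = float(
        np.maximum(pair.sample_image[rows, cols], INTENSITY_FLOOR).mean()
    )
    if mean_sample <= INTENSITY_FLOOR or mean_blank <= INTENSITY_FLOOR:
        raise DegenerateRegionError(
            f"region {region} has near-zero mean intensity "
            f"(blank={mean_blank:g}, sample={mean_sample:g})"
        )
    mu = math.log(mean_blank / mean_sample) / pair.thickness_mm
    return AttenuationMeasurement(
        mu=mu,
        region=region,
        run_index=run_index,
        image_index=image_index,
        mean_blank=mean_blank,
        mean_sample=mean_sample,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def region_side(dim_px: int, fraction: float, mode: str = "linear") -> int:
    """Region side length for one image dimension (half-up rounding, min 1)."""
    scale = fraction if mode == "linear" else math.sqrt(fraction)
    return max(1, _round_half_up(scale * dim_px))


def _draw_region(
    image_height_px: int,
    image_width_px: int,
    height_px: int,
    width_px: int,
    rng: np.random.Generator,
) -> RegionSpec:
    row = int(rng.integers(0, image_height_px - height_px + 1))
    col = int(rng.integers(0, image_width_px - width_px + 1))
    return RegionSpec(row, col, height_px, width_px)


def sample_regions(
    image_height_px: int,
    image_width_px: int,
    params: ProtocolParams,
    rng: np.random.Generator,
) -> list[RegionSpec]:
    """Draw ``regions_per_run`` uniformly placed regions for one run.

    Regions may overlap; origins are uniform over all valid placements and
    the draw is deterministic given the generator state.
    """
    if image_height_px < 1 or image_width_px < 1:
        raise InvalidInputError("image dimensions must be >= 1")
    h = region_side(image_height_px, params.region_fraction,
                    params.region_fraction_mode)
    w = region_side(image_width_px, params.region_fraction,
                    params.region_fraction_mode)
    if h > image_height_px or w > image_width_px:
        raise InvalidInputError(
            f"image ({image_height_px}x{image_width_px}) smaller than one "
            f"region ({h}x{w})"
        )
    return [
        _draw_region(image_height_px, image_width_px, h, w, rng)
        for _ in range(params.regions_per_run)
    ]


def _image_rng(seed: int, image_index: int) -> np.random.Generator:
    # Fixed per-image substream: adding images never perturbs earlier draws.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(image_index,))
    )


def run_protocol(
    pairs: Sequence[TransmittanceImagePair],
    params: ProtocolParams = ProtocolParams(),
) -> SampleAttenuationSummary:
    """Run the full randomized protocol over one sample's image pairs.

    For every image, ``runs_per_image`` runs each draw ``regions_per_run``
    regions and compute one coefficient per region; all region-level values
    are pooled as the sample's individual measurements.  A degenerate region
    (near-zero sample mean) is redrawn up to ``max_resample_attempts`` times
    before the whole protocol fails for that image.
    """
    if not pairs:
        raise InvalidInputError("need at least one image pair")
    sample_ids = {p.sample_id for p in pairs}
    conditions = {p.condition for p in pairs}
    if len(sample_ids) != 1 or len(conditions) != 1:
        raise InvalidInputError(
            "all pairs of one protocol run must share sample_id and condition"
        )

    measurements: list[AttenuationMeasurement] = []
    for image_index, pair in enumerate(pairs):
        rng = _image_rng(params.seed, image_index)
        h_img, w_img = pair.shape
        h = region_side(h_img, params.region_fraction, params.region_fraction_mode)
        w = region_side(w_img, params.region_fraction, params.region_fraction_mode)
        if h > h_img or w > w_img:
            raise InvalidInputError(
                f"image {image_index} ({h_img}x{w_img}) smaller than one "
                f"region ({h}x{w})"
            )
        for run_index in range(params.runs_per_image):
            for _ in range(params.regions_per_run):
                for attempt in range(params.max_resample_attempts):
                    region = _draw_region(h_img, w_img, h, w, rng)
                    try:
                        m = region_mu(pair, region, run_index=run_index,
                                      image_index=image_index)
                    except DegenerateRegionError:
                        continue
                    measurements.append(m)
                    break
                else:
                    raise ProtocolFailureError(
                        f"image {image_index} of sample "
                        f"{pair.sample_id!r}: all "
                        f"{params.max_resample_attempts} region draws were "
                        f"degenerate in run {run_index}"
                    )

    mus = np.array([m.mu for m in measurements])
    n = mus.size
    mu_mean = float(mus.mean())
    mu_sem = float(mus.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SampleAttenuationSummary(
        sample_id=pairs[0].sample_id,
        condition=pairs[0].condition,
        measurements=measurements,
        mu_mean=mu_mean,
        mu_sem=mu_sem,
        n_measurements=n,
    )

def measurements_table(summary: SampleAttenuationSummary):
    """All individual measurements of one sample as a tidy DataFrame."""
    import pandas as pd

    rows = [
        {
            "sample_id": summary.sample_id,
            "condition": summary.condition,
            "image_index": m.image_index,
            "run_index": m.run_index,
            "row_origin": m.region.row_origin,
            "col_origin": m.region.col_origin,
            "height_px": m.region.height_px,
            "width_px": m.region.width_px,
            "mean_blank": m.mean_blank,
            "mean_sample": m.mean_sample,
            "mu": m.mu,
        }
        for m in summary.measurements
    ]
    return pd.DataFrame(rows)


def summaries_table(summaries: Sequence[SampleAttenuationSummary]):
    """Per-sample summaries (mean, SEM, n) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "mu_mean": s.mu_mean,
                "mu_sem": s.mu_sem,
                "n_measurements": s.n_measurements,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# file input
# ---------------------------------------------------------------------------

def _load_grayscale(path: str | Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - message wrapping only
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(np.float64) @ _LUMA_WEIGHTS
    elif arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise InvalidInputError(
            f"{path}: expected a 2-D grayscale or RGB image, got shape "
            f"{arr.shape}"
        )
    return arr.astype(np.float64)


def load_image_pair(
    blank_path: str | Path,
    sample_path: str | Path,
    thickness_mm: float,
    sample_id: str = "",
    condition: str = "",
) -> TransmittanceImagePair:
    """Read a blank/sample pair from TIFF or PNG files.

    RGB input is collapsed to luminance with Rec. 601 weights; integer data
    are promoted to float64 without rescaling.
    """
    blank = _load_grayscale(blank_path)
    sample = _load_grayscale(sample_path)
    if blank.shape != sample.shape:
        raise InvalidInputError(
            f"dimension mismatch: {blank_path} is {blank.shape}, "
            f"{sample_path} is {sample.shape}"
        )
    return TransmittanceImagePair(
        blank_image=blank,
        sample_image=sample,
        thickness_mm=thickness_mm,
        sample_id=sample_id,
        condition=condition,
    )
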