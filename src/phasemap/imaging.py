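"""Synthetic droplet micrographs and their classical analysis.

Two grayscale channels per sample mirror the two fluorescence channels of
the instrument: one dye fills every aqueous droplet (droplet-location
channel) and a second reports condensates, which appear as bright puncta
strictly inside phase-separated droplets (PS channel).

Analysis is a classical pipeline — Gaussian smoothing, robust global
thresholding, connected components, and a circularity/radius filter for
droplets; local-maxima detection above an adaptive threshold for
condensate puncta. A droplet is scored PS when at least one punctum lies
within ``factor * radius`` of its centre (distance-to-center check), and
the sample's PS fraction is PS droplets / detected droplets. Droplets
touching the image border are discarded (they are not fully visible).
The detector interfaces (filters, distance check, fraction) are kept
independent of the detection backend so a learned detector could be
slotted in behind the same contracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure, segmentation
from skimage.feature import peak_local_max

from .errors import DegenerateSample, OutOfFrame, OverlapViolation


@dataclass(frozen=True)
class RenderSpec:
    """Geometry, photometry and noise of the synthetic micrographs.

    Intensities are arbitrary camera units; images are written as 16-bit
    TIFFs. Defaults give a comfortably resolved droplet field: 256x256 px
    at 1.3 µm/px with 8–14 µm droplet radii and signal well above the
    Gaussian read noise.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.3
    radius_range_um: tuple[float, float] = (8.0, 14.0)
    droplet_intensity: float = 500.0
    condensate_intensity: float = 800.0
    background: float = 100.0
    noise_sd: float = 20.0
    condensates_per_droplet: tuple[int, int] = (1, 3)
    condensate_sigma_px: float = 1.5
    margin_px: float = 2.0

    def __post_init__(self) -> None:
        if self.radius_range_um[0] <= 0:
            raise ValueError("droplet radii must be positive")
        if self.droplet_intensity < self.background or self.condensate_intensity < self.background:
            raise ValueError("signal intensities must be >= background")

    @property
    def radius_range_px(self) -> tuple[float, float]:
        return (
            self.radius_range_um[0] / self.pixel_size_um,
            self.radius_range_um[1] / self.pixel_size_um,
        )


@dataclass(frozen=True)
class ImagePair:
    """Droplet-location channel + PS channel, same shape, µm pixel size."""

    droplet_channel: np.ndarray
    ps_channel: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.droplet_channel.shape != self.ps_channel.shape:
            raise ValueError("both channels must share a shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class DropletRecord:
    """One detected droplet: pixel centre, physical radius, shape score, PS."""

    center: tuple[float, float]  # (row, col), origin top-left, 0-based
    radius_um: float
    radius_px: float
    circularity: float
    ps_flag: bool = False


def sample_droplet_layout(n: int, spec: RenderSpec, rng=None,
                          max_tries: int = 20_000) -> list[tuple[tuple[float, float], float]]:
    """Place ``n`` non-overlapping droplets fully inside the frame.

    Returns a list of ((row, col), radius_px). Rejection sampling; raises
    if the frame cannot accommodate the requested population.
    """
    rng = np.random.default_rng(rng)
    h, w = spec.shape
    r_lo, r_hi = spec.radius_range_px
    placed: list[tuple[tuple[float, float], float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise OverlapViolation(
                f"could only place {len(placed)} of {n} droplets in the frame"
            )
        r = rng.uniform(r_lo, r_hi)
        row = rng.uniform(r + spec.margin_px, h - 1 - r - spec.margin_px)
        col = rng.uniform(r + spec.margin_px, w - 1 - r - spec.margin_px)
        ok = all(
            math.hypot(row - c[0], col - c[1]) >= r + pr + spec.margin_px
            for c, pr in placed
        )
        if ok:
            placed.append(((row, col), r))
    return placed


def _check_layout(droplets, spec: RenderSpec) -> None:
    h, w = spec.shape
    for i, (center, radius, _flag) in enumerate(droplets):
        row, col = center
        if (
            row - radius < 0 or col - radius < 0
            or row + radius > h - 1 or col + radius > w - 1
        ):
            raise OutOfFrame(f"droplet {i} does not fit inside the frame")
        for j in range(i):
            c2, r2, _ = droplets[j]
            if math.hypot(row - c2[0], col - c2[1]) < radius + r2:
                raise OverlapViolation(f"droplets {j} and {i} overlap")


def render_images(
    droplets: list[tuple[tuple[float, float], float, bool]],
    spec: RenderSpec,
    seed=None,
    puncta: list[tuple[float, float]] | None = None,
) -> ImagePair:
    """Render a droplet population as a two-channel image pair.

    ``droplets`` are ((row, col), radius_px, ps_flag) triples. The droplet
    channel holds background + uniform disks; the PS channel holds
    background + Gaussian puncta strictly inside each PS droplet (sampled
    unless ``puncta`` supplies explicit positions). Gaussian read noise is
    added to both channels. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    _check_layout(droplets, spec)
    h, w = spec.shape
    rows, cols = np.mgrid[0:h, 0:w]
    droplet_img = np.full((h, w), spec.background, dtype=float)
    ps_img = np.full((h, w), spec.background, dtype=float)

    for (row, col), radius, _flag in droplets:
        mask = (rows - row) ** 2 + (cols - col) ** 2 <= radius**2
        droplet_img[mask] = spec.droplet_intensity

    if puncta is None:
        puncta = []
        lo, hi = spec.condensates_per_droplet
        for (row, col), radius, flag in droplets:
            if not flag:
                continue
            k = int(rng.integers(lo, hi + 1))
            for _ in range(k):
                rho = radius * 0.5 * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                puncta.append((row + rho * np.sin(theta), col + rho * np.cos(theta)))

    amp = spec.condensate_intensity - spec.background
    s2 = 2.0 * spec.condensate_sigma_px**2
    for prow, pcol in puncta:
        d2 = (rows - prow) ** 2 + (cols - pcol) ** 2
        near = d2 < (6.0 * spec.condensate_sigma_px) ** 2
        ps_img[near] += amp * np.exp(-d2[near] / s2)

    if spec.noise_sd > 0:
        droplet_img = droplet_img + rng.normal(0, spec.noise_sd, size=(h, w))
        ps_img = ps_img + rng.normal(0, spec.noise_sd, size=(h, w))
    np.clip(droplet_img, 0, None, out=droplet_img)
    np.clip(ps_img, 0, None, out=ps_img)
    return ImagePair(droplet_channel=droplet_img, ps_channel=ps_img,
                     pixel_size_um=spec.pixel_size_um)


def _robust_background(img: np.ndarray) -> tuple[float, float]:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med, 1.4826 * mad


def detect_droplets(
    pair: ImagePair,
    radius_bounds_um: tuple[float, float] = (4.0, 40.0),
    circularity_min: float = 0.8,
    smooth_sigma_px: float = 1.0,
) -> list[DropletRecord]:
    """Locate droplets in the droplet channel and filter by shape and radius.

    Segmentation: Gaussian smoothing, then a global threshold halfway
    between the robust background level and the bright foreground; border
    -touching components are discarded, and the survivors are filtered by
    radius (equivalent-disk, in µm) and circularity (4*pi*A/P^2, with the
    Crofton perimeter estimate, clipped to [0, 1]).
    """
    img = gaussian_filter(pair.droplet_channel, smooth_sigma_px)
    med, sd = _robust_background(img)
    bright = float(np.percentile(img, 99.5))
    if bright < med + 5 * max(sd, 1e-12):
        return []  # no foreground distinguishable from background
    threshold = 0.5 * (med + bright)
    labels = measure.label(img > threshold)
    labels = segmentation.clear_border(labels)
    records: list[DropletRecord] = []
    for region in measure.regionprops(labels):
        radius_px = math.sqrt(region.area / math.pi)
        perimeter = region.perimeter_crofton
        if perimeter <= 0:
            continue
        circularity = min(1.0, 4.0 * math.pi * region.area / perimeter**2)
        radius_um = radius_px * pair.pixel_size_um
        if not radius_bounds_um[0] <= radius_um <= radius_bounds_um[1]:
            continue
        if circularity < circularity_min:
            continue
        records.append(
            DropletRecord(
                center=tuple(region.centroid),
                radius_um=radius_um,
                radius_px=radius_px,
                circularity=circularity,
            )
        )
    return records


def detect_condensates(
    pair: ImagePair,
    min_distance_px: int = 3,
    n_sigma: float = 8.0,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Condensate puncta: local maxima above an adaptive threshold.

    The threshold is the robust background level plus ``n_sigma`` robust
    standard deviations of the PS channel. Returns an (n, 2) array of
    (row, col) peak positions (empty when nothing exceeds the threshold).
    """
    img = gaussian_filter(pair.ps_channel, smooth_sigma_px)
    med, sd = _robust_background(img)
    threshold = med + n_sigma * max(sd, 1e-12)
    peaks = peak_local_max(img, min_distance=min_distance_px, threshold_abs=threshold)
    return peaks.astype(float)


def assign_ps(
    droplets: list[DropletRecord],
    puncta: np.ndarray,
    factor: float = 0.9,
) -> list[DropletRecord]:
    """Distance-to-center check: flag droplets containing >= 1 punctum.

    Each punctum is assigned to at most one droplet — the nearest centre
    (ties broken by lowest droplet index) — and counts only if it lies
    within ``factor * radius`` of that centre.
    """
    for rec in droplets:
        rec.ps_flag = False
    puncta = np.atleast_2d(np.asarray(puncta, dtype=float))
    if puncta.size == 0 or not droplets:
        return droplets
    centers = np.array([rec.center for rec in droplets])
    radii = np.array([rec.radius_px for rec in droplets])
    for p in puncta:
        dists = np.linalg.norm(centers - p, axis=1)
        nearest = int(np.argmin(dists))  # argmin keeps the first on exact ties
        if dists[nearest] <= factor * radii[nearest]:
            droplets[nearest].ps_flag = True
    return droplets


def ps_fraction(droplets: list[DropletRecord]) -> float:
    """PS droplets / detected droplets."""
    if not droplets:
        raise DegenerateSample("no detected droplets to compute a PS fraction")
    return sum(r.ps_flag for r in droplets) / len(droplets)


def analyze_pair(pair: ImagePair, **detect_kwargs) -> tuple[list[DropletRecord], float]:
    """Full classical pipeline on one image pair: records + PS fraction."""
    records = detect_droplets(pair, **detect_kwargs)
    puncta = detect_condensates(pair)
    records = assign_ps(records, puncta)
    return records, ps_fraction(records)


# -- TIFF I/O -----------------------------------------------------------


def write_image_pair(pair: ImagePair, directory, sample_id: str) -> tuple[Path, Path]:
    """Write the two channels as 16-bit grayscale TIFFs in one folder."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, tag in ((pair.droplet_channel, "droplets"),
                         (pair.ps_channel, "ps")):
        arr = np.clip(np.round(channel), 0, 65535).astype(np.uint16)
        path = directory / f"{sample_id}_{tag}.tif"
        tifffile.imwrite(path, arr)
        paths.append(path)
    return tuple(paths)


def read_image_pair(directory, sample_id: str, pixel_size_um: float) -> ImagePair:
    import tifffile

    directory = Path(directory)
    droplet = tifffile.imread(directory / f"{sample_id}_droplets.tif").astype(float)
    ps = tifffile.imread(directory / f"{sample_id}_ps.tif").astype(float)
    return ImagePair(droplet_channel=droplet, ps_channel=ps,
                     pixel_size_um=pixel_size_um)


def records_to_dataframe(records: list[DropletRecord], sample_id: str = ""):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "droplet_index": i,
                "row": r.center[0],
                "col": r.center[1],
                "radius_um": r.radius_um,
                "circularity": r.circularity,
                "ps_flag": r.ps_flag,
            }
            for i, r in enumerate(records)
        ]
    )
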