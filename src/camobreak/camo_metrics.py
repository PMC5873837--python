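"""Per-photograph camouflage covariates measured on the luminance channel.

Pattern is quantified by granularity analysis: the luminance image is
decomposed into band-pass spatial-frequency bands on a sqrt(2)-spaced
schedule of scales, and the "energy" of each band within a region is the
(population) standard deviation of the band-filtered values over the
region's pixels.  Pattern difference between target and background is the
sum of absolute band-energy differences.  Luminance-distribution difference
is the total-variation distance between 100-bin luminance histograms over
the fixed range [0, 1].  Patch contrast is SD/mean (coefficient of
variation).  All metrics are functions of luminance only and therefore take
identical values on the trichromatic and simulated-dichromat renderings of
a scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import (
    LuminanceImage,
    RGBImage,
    RegionSet,
    TargetPolygon,
    build_regions,
    rasterize_polygon,
    to_luminance,
)

__all__ = [
    "GranularitySchedule",
    "GranularitySpectrum",
    "CamouflageMetrics",
    "band_schedule",
    "granularity_spectrum",
    "pattern_difference",
    "luminance_distribution_difference",
    "patch_contrast",
    "measure_photo",
    "metrics_to_frame",
]

#: relative tolerance at the cap so that nominal sizes like 256 = 2 * sqrt(2)^14
#: survive floating-point accumulation of the sqrt(2) powers
CAP_RTOL = 1e-6


@dataclass(frozen=True)
class GranularitySchedule:
    """Ordered band scales in px: s_k = start * sqrt(2)^k, up to the cap."""

    band_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in self.band_sizes)
        if len(s) < 1 or any(x <= 0 for x in s):
            raise ValueError("need at least one positive band size")
        for a, b in zip(s, s[1:]):
            if not np.isclose(b / a, np.sqrt(2.0), rtol=1e-9):
                raise ValueError("consecutive sizes must differ by sqrt(2)")
        object.__setattr__(self, "band_sizes", s)

    def __len__(self) -> int:
        return len(self.band_sizes)


@dataclass(frozen=True)
class GranularitySpectrum:
    """Band energies (SD of band-filtered luminance) for one region."""

    schedule: GranularitySchedule
    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=np.float64)
        if e.ndim != 1 or len(e) != len(self.schedule):
            raise ValueError("one energy per scheduled band required")
        if not np.all(np.isfinite(e)) or (e < 0).any():
            raise ValueError("energies must be finite and nonnegative")
        object.__setattr__(self, "energies", e)


@dataclass(frozen=True)
class CamouflageMetrics:
    """All per-photograph covariates for the two background comparisons."""

    photo_id: str
    pattern_diff_near: float
    pattern_diff_whole: float
    lum_dist_diff_near: float
    lum_dist_diff_whole: float
    contrast_target: float
    contrast_near: float
    contrast_whole: float
    mean_lum_target: float
    mean_lum_near: float
    mean_lum_whole: float
    target_area: int
    band_sizes: tuple[float, ...] = field(default=(), compare=False)


def band_schedule(cap_px: float, start_px: float = 2.0) -> GranularitySchedule:
    """Scales start_px * sqrt(2)^k for k = 0, 1, ... while <= cap_px.

    The cap itself is included (a 1e-6 relative tolerance absorbs
    floating-point drift in the sqrt(2) powers), so cap 256 yields 15 bands
    ending at 256 and cap 128 yields 13 bands ending at 128.
    """
    if cap_px < start_px:
        raise ValueError("cap_px must be >= start_px")
    sizes = []
    k = 0
    while True:
        # 2**(k/2) is exact for even k, so nominal sizes (2, 4, ..., 128, 256)
        # come out bit-exact; the tolerance covers the irrational odd steps
        s = start_px * 2.0 ** (k / 2.0)
        if s > cap_px * (1.0 + CAP_RTOL):
            break
        sizes.append(s)
        k += 1
    return GranularitySchedule(tuple(sizes))


def _band_edges(sched: GranularitySchedule) -> list[tuple[float, float]]:
    # Wavelength pass-bands: boundaries at geometric midpoints between
    # neighbouring scheduled sizes, i.e. [s / 2^(1/4), s * 2^(1/4)).
    q = 2.0 ** 0.25
    return [(s / q, s * q) for s in sched.band_sizes]


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.rfftfreq(shape[1])[None, :]
    return np.sqrt(fx * fx + fy * fy)


def granularity_spectrum(
    lum: LuminanceImage,
    region: np.ndarray,
    sched: GranularitySchedule,
) -> GranularitySpectrum:
    """Granularity (band-pass energy) spectrum of a region.

    Pixels outside the region are filled with the region's mean luminance
    before the FFT, keeping the DC of the padded image equal to the region
    mean and suppressing mask-edge artifacts.  Each band is an ideal
    (hard-edged) annular filter in the Fourier amplitude domain passing
    wavelengths in [s / 2^(1/4), s * 2^(1/4)); the DC component is always
    removed.  Energy = population SD of the filtered values over region
    pixels.
    """
    mask = np.asarray(region, dtype=bool)
    if mask.shape != lum.values.shape:
        raise ValueError("region mask and image shapes differ")
    if not mask.any():
        raise ValueError("empty region")
    if min(lum.values.shape) < max(sched.band_sizes):
        raise ValueError("image smaller than the largest scheduled band")

    filled = np.where(mask, lum.values, lum.values[mask].mean())
    spectrum = np.fft.rfft2(filled)
    freq = _radial_frequency(filled.shape)

    energies = np.empty(len(sched))
    for i, (lo, hi) in enumerate(_band_edges(sched)):
        # pass wavelengths [lo, hi)  <=>  frequencies (1/hi, 1/lo]
        keep = (freq > 1.0 / hi) & (freq <= 1.0 / lo)
        band = np.fft.irfft2(spectrum * keep, s=filled.shape)
        energies[i] = band[mask].std()  # population SD
    return GranularitySpectrum(sched, energies)


def pattern_difference(
    target_spec: GranularitySpectrum, bg_spec: GranularitySpectrum
) -> float:
    """Sum of absolute band-energy differences; 0 = perfect pattern match."""
    if target_spec.schedule != bg_spec.schedule:
        raise ValueError("granularity schedules differ")
    return float(np.abs(target_spec.energies - bg_spec.energies).sum())


def luminance_distribution_difference(
    target_px: np.ndarray, bg_px: np.ndarray, n_bins: int = 100
) -> float:
    """Total-variation distance between luminance histograms in [0, 1].

    Both pixel sets are binned into ``n_bins`` equal bins over the fixed
    range [0, 1]; each histogram is normalized to sum 1 and the statistic is
    sum(|p_i - q_i|) / 2, so 0 means identical distributions and 1 means
    disjoint support.  The fixed global range keeps values comparable across
    photographs.
    """
    t = np.asarray(target_px, dtype=np.float64).ravel()
    b = np.asarray(bg_px, dtype=np.float64).ravel()
    if t.size == 0 or b.size == 0:
        raise ValueError("empty pixel set")
    p, _ = np.histogram(t, bins=n_bins, range=(0.0, 1.0))
    q, _ = np.histogram(b, bins=n_bins, range=(0.0, 1.0))
    p = p / p.sum()
    q = q / q.sum()
    return float(np.abs(p - q).sum() / 2.0)


def patch_contrast(px: np.ndarray) -> float:
    """Contrast of a patch: population SD of luminance divided by its mean."""
    v = np.asarray(px, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty pixel set")
    m = v.mean()
    if m == 0.0:
        raise ValueError("zero mean luminance: contrast undefined")
    return float(v.std() / m)


def measure_photo(
    img: RGBImage,
    poly: TargetPolygon,
    sched: GranularitySchedule,
    photo_id: str = "",
    inner_gap_px: float = 15.0,
    outer_radius_px: float = 500.0,
    regions: RegionSet | None = None,
) -> CamouflageMetrics:
    """Compute every camouflage covariate for one annotated photograph.

    "near" metrics compare the target against the surrounding annulus
    (doughnut between inner_gap_px and outer_radius_px of the target edge);
    "whole" metrics compare it against the entire background minus the
    target and spacer.
    """
    lum = to_luminance(img)
    if regions is None:
        target_mask = rasterize_polygon(poly, img.width, img.height)
        regions = build_regions(target_mask, inner_gap_px, outer_radius_px)

    spec_t = granularity_spectrum(lum, regions.target_mask, sched)
    spec_near = granularity_spectrum(lum, regions.annulus_mask, sched)
    spec_whole = granularity_spectrum(lum, regions.whole_bg_mask, sched)

    px_t = lum.values[regions.target_mask]
    px_near = lum.values[regions.annulus_mask]
    px_whole = lum.values[regions.whole_bg_mask]

    return CamouflageMetrics(
        photo_id=photo_id,
        pattern_diff_near=pattern_difference(spec_t, spec_near),
        pattern_diff_whole=pattern_difference(spec_t, spec_whole),
        lum_dist_diff_near=luminance_distribution_difference(px_t, px_near),
        lum_dist_diff_whole=luminance_distribution_difference(px_t, px_whole),
        contrast_target=patch_contrast(px_t),
        contrast_near=patch_contrast(px_near),
        contrast_whole=patch_contrast(px_whole),
        mean_lum_target=float(px_t.mean()),
        mean_lum_near=float(px_near.mean()),
        mean_lum_whole=float(px_whole.mean()),
        target_area=int(regions.target_mask.sum()),
        band_sizes=sched.band_sizes,
    )


def metrics_to_frame(metrics: list[CamouflageMetrics]) -> pd.DataFrame:
    """One row per photograph, ready to join with the game-event table."""
    cols = [
        "photo_id",
        "pattern_diff_near",
        "pattern_diff_whole",
        "lum_dist_diff_near",
        "lum_dist_diff_whole",
        "contrast_target",
        "contrast_near",
        "contrast_whole",
        "mean_lum_target",
        "mean_lum_near",
        "mean_lum_whole",
        "target_area",
    ]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metrics])
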