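"""Synthetic camouflage scenes and simulated visual-search game sessions.

The scene generator emulates textured natural backgrounds (isotropic
1/f^beta noise with a characteristic texture scale) with an embedded
elliptical target whose luminance offset and pattern-scale mismatch are
controllable ground truth.  The session simulator is the generative inverse
of the analysis model: latent log capture time is a linear predictor over
the photograph's measured camouflage covariates plus session and photograph
random intercepts and lognormal residual noise, censored at a 30-s timeout;
incorrect clicks are Poisson.  Every simulated session presents 20 slides
with the target placed uniformly within the central 60% of the image.

All randomness flows from integer seeds through ``numpy.random.default_rng``
seed sequences; per-session substreams are derived by counter, so a study
is bit-reproducible and order-independent across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camo_metrics import (
    CamouflageMetrics,
    band_schedule,
    measure_photo,
    metrics_to_frame,
)
from .imaging import RGBImage, TargetPolygon, simulate_dichromat

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "BehaviorModel",
    "SceneLibrary",
    "generate_scene",
    "default_scene_specs",
    "build_scene_library",
    "simulate_slide",
    "simulate_study",
    "EVENT_COLUMNS",
    "AGE_CLASSES",
]

AGE_CLASSES = ("<10", "10-15", "16-35", "36-50", ">50")

#: probability of each age bracket among simulated participants
_AGE_PROBS = (0.05, 0.10, 0.50, 0.25, 0.10)

EVENT_COLUMNS = [
    "session_id",
    "viewing_condition",
    "age_class",
    "played_before",
    "slide_number",
    "photo_id",
    "season",
    "outcome",
    "capture_time_s",
    "n_incorrect_clicks",
    "target_cx",
    "target_cy",
    "edge_distance_px",
]


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth parameters for one synthetic camouflage scene.

    The background is isotropic noise with power spectrum ~ 1/f^beta
    modulated by a log-Gaussian bump at ``texture_scale_px`` (a pure power
    law is scale-free, so a characteristic scale is required for the
    pattern-scale mismatch to be measurable), plus a large-scale
    illumination mottle (fractional amplitude ``bg_mottle_amplitude`` at
    wavelength ``bg_mottle_scale_frac`` x image size) emulating the
    non-stationary lighting of natural scenes -- this is what makes the
    near-surround covariates genuinely different from whole-background
    ones.  The target is an elliptical patch of background-like texture
    with its dominant scale multiplied by ``target_pattern_scale_shift``
    and its mean luminance shifted by ``target_lum_offset``; it shares the
    local illumination mottle and is alpha-blended over a 2 px edge.
    """

    image_size: int = 384
    bg_spectral_slope: float = 2.0
    bg_mean_lum: float = 0.5
    bg_contrast: float = 0.2
    bg_mottle_amplitude: float = 0.15
    bg_mottle_scale_frac: float = 0.5
    target_axes: tuple[float, float] = (24.0, 16.0)
    target_lum_offset: float = 0.0
    target_pattern_scale_shift: float = 1.0
    texture_scale_px: float = 16.0
    texture_bandwidth_oct: float = 0.7
    chroma_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 < self.bg_mean_lum < 1.0):
            raise ValueError("bg_mean_lum must lie in (0, 1)")
        if self.bg_contrast < 0:
            raise ValueError("bg_contrast must be >= 0")
        a, b = self.target_axes
        if a <= 1 or b <= 1:
            raise ValueError("target axes must exceed 1 px")
        if 2.0 * max(a, b) > 0.6 * self.image_size:
            raise ValueError("target larger than the central 60% placement area")
        if self.target_pattern_scale_shift <= 0:
            raise ValueError("pattern scale shift must be positive")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene: image, enclosing target polygon, and its truth."""

    photo_id: str
    image: RGBImage
    target_polygon: TargetPolygon
    truth: SceneSpec


@dataclass(frozen=True)
class BehaviorModel:
    """Generative coefficients for latent log capture time (log-seconds).

    Slopes act on the measured covariates of the presented photograph:
    log pattern difference, luminance-distribution difference, target area
    (px), background mean luminance and contrast, slide number, the
    first-slide and played-before indicators, log edge distance, and age
    bracket offsets (relative to the youngest bracket).  ``i_view_*`` terms
    are the viewing-condition interactions (dichromat = 1).  Defaults are
    chosen so each viewing interaction moves expected log time by roughly
    0.2-0.3 across the covariate's simulated range -- the order of the
    20-40% relative-risk effects such search experiments report -- with the
    sign pattern: dichromats are slower overall, more influenced by pattern
    and luminance mismatch, and relatively worse with small targets and
    dark backgrounds.
    """

    intercept: float = float(np.log(4.0))
    b_viewing: float = 0.15
    b_pattern: float = 0.15
    b_lumdiff: float = 0.30
    b_area: float = -1.0e-4
    b_bglum: float = -0.30
    b_contrast: float = 0.0
    b_slide: float = -0.02
    b_first: float = 0.40
    b_played: float = -0.20
    b_edge: float = -0.15
    b_age: tuple[float, float, float, float] = (-0.20, -0.30, -0.25, -0.10)
    i_view_pattern: float = 0.20
    i_view_lumdiff: float = 0.40
    i_view_area: float = -6.0e-5
    i_view_bglum: float = -0.50
    i_view_contrast: float = 0.0
    i_view_slide: float = 0.0
    sd_session: float = 0.30
    sd_photo: float = 0.20
    sd_season: float = 0.0
    sd_resid: float = 0.50
    timeout_s: float = 30.0
    false_click_rate: float = 0.30

    def __post_init__(self) -> None:
        for name in ("sd_session", "sd_photo", "sd_season", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")
        if self.false_click_rate < 0:
            raise ValueError("false_click_rate must be >= 0")

    def linear_predictor(self, cov: dict) -> float:
        """Deterministic part of latent log capture time for one slide."""
        v = 1.0 if cov["viewing_condition"] == "dichromat" else 0.0
        age_idx = AGE_CLASSES.index(cov["age_class"])
        age_eff = 0.0 if age_idx == 0 else self.b_age[age_idx - 1]
        return (
            self.intercept
            + self.b_viewing * v
            + (self.b_pattern + self.i_view_pattern * v) * cov["log_pattern_diff"]
            + (self.b_lumdiff + self.i_view_lumdiff * v) * cov["lum_dist_diff"]
            + (self.b_area + self.i_view_area * v) * cov["target_area"]
            + (self.b_bglum + self.i_view_bglum * v) * cov["bg_lum_mean"]
            + (self.b_contrast + self.i_view_contrast * v) * cov["bg_contrast"]
            + (self.b_slide + self.i_view_slide * v) * cov["slide_number"]
            + self.b_first * float(cov["first_slide"])
            + self.b_played * float(cov["played_before"])
            + self.b_edge * cov["log_edge_dist"]
            + age_eff
        )


def _spectral_texture(
    rng: np.random.Generator,
    size: int,
    beta: float,
    scale_px: float,
    bandwidth_oct: float,
) -> np.ndarray:
    """Zero-mean, unit-SD noise field with a 1/f^beta power spectrum shaped
    by a log-Gaussian bump centered at wavelength ``scale_px``."""
    white = rng.standard_normal((size, size))
    spec = np.fft.rfft2(white)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.sqrt(fx * fx + fy * fy)
    amp = np.zeros_like(f)
    nz = f > 0
    sigma = bandwidth_oct * np.log(2.0)
    amp[nz] = f[nz] ** (-beta / 2.0) * np.exp(
        -0.5 * (np.log(f[nz] * scale_px) / sigma) ** 2
    )
    field = np.fft.irfft2(spec * amp, s=(size, size))
    sd = field.std()
    if sd == 0.0:
        return field
    return (field - field.mean()) / sd


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, n: int = 64) -> TargetPolygon:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return TargetPolygon(np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)]))


def generate_scene(spec: SceneSpec, photo_id: str = "") -> SyntheticScene:
    """Render one synthetic scene; bit-identical for the same spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size

    z_bg = _spectral_texture(
        rng, s, spec.bg_spectral_slope, spec.texture_scale_px, spec.texture_bandwidth_oct
    )
    z_t = _spectral_texture(
        rng,
        s,
        spec.bg_spectral_slope,
        spec.texture_scale_px * spec.target_pattern_scale_shift,
        spec.texture_bandwidth_oct,
    )
    z_c = _spectral_texture(rng, s, 2.0, 32.0, 1.0)
    z_c2 = _spectral_texture(rng, s, 2.0, 32.0, 1.0)
    z_mottle = _spectral_texture(rng, s, 2.0, spec.bg_mottle_scale_frac * s, 0.5)

    mottle = spec.bg_mean_lum * spec.bg_mottle_amplitude * z_mottle
    bg = spec.bg_mean_lum * (1.0 + spec.bg_contrast * z_bg) + mottle
    t_mean = np.clip(spec.bg_mean_lum + spec.target_lum_offset, 0.02, 0.98)
    # the target shares the local illumination field of the scene
    tex = t_mean * (1.0 + spec.bg_contrast * z_t) + mottle

    a, b = spec.target_axes
    cx = cy = (s - 1) / 2.0
    X, Y = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float))
    rho = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
    # alpha-blend over a 2 px feather inside the ellipse boundary
    alpha = np.clip((1.0 - rho) * min(a, b) / 2.0, 0.0, 1.0)
    lum = np.clip(alpha * tex + (1.0 - alpha) * bg, 0.0, 1.0)

    chroma = spec.chroma_amplitude * z_c
    blue_dev = 0.5 * spec.chroma_amplitude * z_c2
    px = np.empty((s, s, 3))
    px[..., 0] = np.clip(lum + chroma, 0.0, 1.0)
    px[..., 1] = np.clip(lum - chroma, 0.0, 1.0)
    px[..., 2] = np.clip(lum + blue_dev, 0.0, 1.0)

    poly = _ellipse_polygon(cx, cy, a, b)
    return SyntheticScene(
        photo_id=photo_id or f"scene{spec.seed:08d}",
        image=RGBImage(px),
        target_polygon=poly,
        truth=spec,
    )


def default_scene_specs(
    n_scenes: int, seed: int, image_size: int = 384
) -> list[SceneSpec]:
    """A realistic scene grid: backgrounds varying in brightness and
    contrast, targets varying in size, luminance offset and pattern-scale
    mismatch, spanning poor to near-perfect camouflage."""
    rng = np.random.default_rng([int(seed), 901])
    specs = []
    for _ in range(n_scenes):
        a = rng.uniform(14.0, 40.0)
        b = rng.uniform(10.0, a)
        specs.append(
            SceneSpec(
                image_size=image_size,
                bg_mean_lum=rng.uniform(0.30, 0.70),
                bg_contrast=rng.uniform(0.08, 0.30),
                target_axes=(a, b),
                target_lum_offset=rng.uniform(-0.25, 0.25),
                target_pattern_scale_shift=float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


@dataclass(frozen=True)
class SceneLibrary:
    """Generated scenes plus their measured camouflage covariates."""

    scenes: tuple[SyntheticScene, ...]
    metrics: pd.DataFrame = field(compare=False)
    seasons: dict = field(default_factory=dict, compare=False)

    def metrics_row(self, photo_id: str) -> pd.Series:
        return self.metrics.set_index("photo_id").loc[photo_id]


def build_scene_library(
    specs: list[SceneSpec],
    cap_px: float = 256.0,
    inner_gap_px: float = 15.0,
    outer_radius_px: float = 100.0,
    n_seasons: int = 2,
) -> SceneLibrary:
    """Generate scenes and measure their camouflage metrics.

    The annulus outer radius defaults to 100 px (rather than the field
    protocol's 500 px) so that on desk-scale synthetic images the "near"
    surround is genuinely distinct from the whole background.  Each photo
    is assigned a season label cyclically.
    """
    scenes = []
    metrics: list[CamouflageMetrics] = []
    sched = band_schedule(cap_px)
    for i, spec in enumerate(specs):
        scene = generate_scene(spec, photo_id=f"P{i:04d}")
        scenes.append(scene)
        metrics.append(
            measure_photo(
                scene.image,
                scene.target_polygon,
                sched,
                photo_id=scene.photo_id,
                inner_gap_px=inner_gap_px,
                outer_radius_px=outer_radius_px,
            )
        )
    seasons = {s.photo_id: f"season{i % n_seasons}" for i, s in enumerate(scenes)}
    return SceneLibrary(tuple(scenes), metrics_to_frame(metrics), seasons)


def simulate_slide(cov: dict, behavior: BehaviorModel, rng: np.random.Generator) -> dict:
    """Simulate one slide: latent lognormal search time censored at timeout.

    ``cov`` must carry the linear-predictor covariates plus ``session_eff``,
    ``photo_eff`` and ``season_eff`` (random-intercept draws), the placed
    target center and the image geometry.  Returns a SlideRecord-style dict;
    timeout slides carry no capture time.  Incorrect-click count is Poisson;
    incorrect click coordinates are uniform over the image and the final
    correct click lands on the target center.
    """
    eta = (
        behavior.linear_predictor(cov)
        + cov.get("session_eff", 0.0)
        + cov.get("photo_eff", 0.0)
        + cov.get("season_eff", 0.0)
    )
    if behavior.sd_resid > 0:
        eta += rng.normal(0.0, behavior.sd_resid)
    latent_t = float(np.exp(eta))

    n_bad = int(rng.poisson(behavior.false_click_rate))
    w = cov.get("image_width", 1.0)
    h = cov.get("image_height", 1.0)
    clicks = [
        (float(rng.uniform(0, w)), float(rng.uniform(0, h)), False) for _ in range(n_bad)
    ]

    record = {
        "session_id": cov.get("session_id", ""),
        "viewing_condition": cov["viewing_condition"],
        "age_class": cov["age_class"],
        "played_before": bool(cov["played_before"]),
        "slide_number": int(cov["slide_number"]),
        "photo_id": cov.get("photo_id", ""),
        "season": cov.get("season", ""),
        "n_incorrect_clicks": n_bad,
        "target_cx": cov.get("target_cx", np.nan),
        "target_cy": cov.get("target_cy", np.nan),
        "edge_distance_px": cov.get("edge_distance_px", np.nan),
        "clicks": clicks,
    }
    if latent_t > behavior.timeout_s:
        record["outcome"] = "timeout"
        record["capture_time_s"] = np.nan
    else:
        record["outcome"] = "capture"
        record["capture_time_s"] = latent_t
        clicks.append((float(record["target_cx"]), float(record["target_cy"]), True))
    return record


def simulate_study(
    n_sessions: int,
    library: SceneLibrary,
    behavior: BehaviorModel,
    seed: int,
    dichromat_fraction: float = 0.5,
    n_slides: int = 20,
    scope: str = "near",
) -> pd.DataFrame:
    """Simulate a full citizen-science study and return the raw event table.

    Each session is assigned a viewing condition (dichromat with probability
    ``dichromat_fraction``), an age bracket and a played-before flag, then
    plays ``n_slides`` slides of scenes sampled with replacement, with the
    target center placed uniformly within the central 60% of the image.
    The generative covariates are the library's measured metrics under the
    given background ``scope`` ("near" = annulus, "whole" = whole
    background).  Timeout slides are logged without capture times, so the
    downstream exclusion rules are exercised.
    """
    if len(library.scenes) < 1:
        raise ValueError("need at least one scene")
    if scope not in ("near", "whole"):
        raise ValueError("scope must be 'near' or 'whole'")

    metrics = {r["photo_id"]: r for r in library.metrics.to_dict("records")}
    photo_ids = [s.photo_id for s in library.scenes]
    sizes = {s.photo_id: s.truth.image_size for s in library.scenes}

    study_rng = np.random.default_rng([int(seed), 0])
    photo_eff = {
        pid: float(study_rng.normal(0.0, behavior.sd_photo)) for pid in photo_ids
    }
    season_labels = sorted(set(library.seasons.values()))
    season_eff = {
        lab: float(study_rng.normal(0.0, behavior.sd_season)) for lab in season_labels
    }

    rows = []
    for i in range(n_sessions):
        rng = np.random.default_rng([int(seed), 1, i])
        viewing = "dichromat" if rng.uniform() < dichromat_fraction else "trichromat"
        age_class = AGE_CLASSES[rng.choice(len(AGE_CLASSES), p=_AGE_PROBS)]
        played_before = bool(rng.uniform() < 0.3)
        session_eff = float(rng.normal(0.0, behavior.sd_session))
        session_id = f"S{i:05d}"

        for slide in range(1, n_slides + 1):
            pid = photo_ids[rng.integers(0, len(photo_ids))]
            m = metrics[pid]
            size = sizes[pid]
            cx = float(rng.uniform(0.2 * size, 0.8 * size))
            cy = float(rng.uniform(0.2 * size, 0.8 * size))
            edge = min(cx, size - cx, cy, size - cy)
            pat = float(m[f"pattern_diff_{scope}"])
            if pat <= 0:
                raise ValueError(f"nonpositive pattern difference for {pid}")
            bg = "near" if scope == "near" else "whole"
            cov = {
                "session_id": session_id,
                "viewing_condition": viewing,
                "age_class": age_class,
                "played_before": played_before,
                "slide_number": slide,
                "first_slide": slide == 1,
                "photo_id": pid,
                "season": library.seasons.get(pid, "season0"),
                "log_pattern_diff": float(np.log(pat)),
                "lum_dist_diff": float(m[f"lum_dist_diff_{bg}"]),
                "target_area": float(m["target_area"]),
                "bg_lum_mean": float(m[f"mean_lum_{bg}"]),
                "bg_contrast": float(m[f"contrast_{bg}"]),
                "log_edge_dist": float(np.log(edge)),
                "session_eff": session_eff,
                "photo_eff": photo_eff[pid],
                "season_eff": season_eff[library.seasons.get(pid, season_labels[0])],
                "target_cx": cx,
                "target_cy": cy,
                "edge_distance_px": edge,
                "image_width": size,
                "image_height": size,
            }
            rec = simulate_slide(cov, behavior, rng)
            rec.pop("clicks")
            rows.append(rec)

    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.DataFrame(rows)[EVENT_COLUMNS]


def render_study_images(library: SceneLibrary) -> dict[str, dict[str, RGBImage]]:
    """Trichromatic and simulated-dichromat renderings for every scene.

    Both viewing conditions share one set of measured covariates because
    every metric is a function of luminance, which the dichromat transform
    preserves exactly.
    """
    out: dict[str, dict[str, RGBImage]] = {}
    for scene in library.scenes:
        out[scene.photo_id] = {
            "trichromat": scene.image,
            "dichromat": simulate_dichromat(scene.image),
        }
    return out
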