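"""Synthetic regeneration scenes and simulated detections.

The study sites (a replanted white pine plantation flown at 6 cm GSD) left
no public spatial data, so this module generates scenes with the same
statistical structure the accuracy assessment assumes:

* crown centers from a homogeneous Poisson process at a configured stem
  density (optionally a jittered planting grid, since the site is a
  plantation);
* crown sizes from a truncated log-normal whose *post-truncation* mean and
  standard deviation are moment-matched to the configured pixel-area
  statistics (default: mean 297.43 px, sd 203.53 px on [24, 1276] px at
  0.06 m/px — the empirical distribution of the manually delineated
  training crowns);
* simulated detections: each crown independently yields a jittered,
  rescaled bounding box with probability ``p_detect``; commission (false)
  boxes arrive as a Poisson process per hectare; confidence scores come
  from scaled-Beta distributions with true-positive mass above the 0.95
  operating threshold and false-positive mass below it, so confidence
  filtering behaves qualitatively like the real detector's.

Everything is driven by an explicit ``numpy`` seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats
from shapely.geometry import Polygon

from .geometry import BBox, buffer_point
from .postprocess import Detection

__all__ = [
    "SceneConfig",
    "DetectorConfig",
    "ConfDist",
    "Scene",
    "generate_scene",
    "sample_crown_areas_px",
    "simulate_detections",
    "fit_truncated_lognormal",
    "benchmark_layout",
]

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic regeneration scene.

    Defaults emulate the medium-density study block: 4744 stems/ha, 6 cm
    ground sampling distance, and the empirical crown pixel-area
    distribution of the hand-digitized training crowns.
    """

    extent_m: tuple[float, float] = (60.0, 60.0)
    gsd_m: float = 0.06
    density_stems_ha: float = 4744.0
    crown_area_px_mean: float = 297.43
    crown_area_px_sd: float = 203.53
    crown_area_px_min: float = 24.0
    crown_area_px_max: float = 1276.0
    other_fraction: float = 0.05
    point_process: str = "poisson"  # or "grid" (perturbed planting rows)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gsd_m <= 0:
            raise ValueError("gsd_m must be positive")
        if self.density_stems_ha <= 0:
            raise ValueError("density_stems_ha must be positive")
        if self.crown_area_px_min < 1:
            raise ValueError("crown_area_px_min must be >= 1")
        if not (self.crown_area_px_min <= self.crown_area_px_mean <= self.crown_area_px_max):
            raise ValueError("crown area mean must lie within [min, max]")
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")
        if self.point_process not in ("poisson", "grid"):
            raise ValueError(f"unknown point process {self.point_process!r}")

    @property
    def extent(self) -> BBox:
        return BBox(0.0, 0.0, self.extent_m[0], self.extent_m[1])

    @property
    def area_ha(self) -> float:
        return self.extent_m[0] * self.extent_m[1] / M2_PER_HA


@dataclass(frozen=True)
class ConfDist:
    """Beta distribution rescaled to [lo, hi] for confidence scores."""

    a: float
    b: float
    lo: float = 0.0
    hi: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class DetectorConfig:
    """Stochastic surrogate for an object detector's output.

    ``p_detect`` is the per-crown detection probability; ``commission_per_ha``
    the expected density of false boxes; ``duplicate_rate`` the expected
    number of extra (redundant) boxes per detected crown, there for NMS to
    clean up. TP confidences concentrate above 0.95 and FP confidences
    below it by default.
    """

    p_detect: float = 0.82
    jitter_sd_m: float = 0.05
    scale_noise: float = 0.1
    commission_per_ha: float = 0.0
    duplicate_rate: float = 0.0
    conf_tp_dist: ConfDist = field(default_factory=lambda: ConfDist(5.0, 1.0, 0.90, 1.0))
    conf_fp_dist: ConfDist = field(default_factory=lambda: ConfDist(2.0, 4.0, 0.50, 1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("p_detect must be in [0, 1]")
        for name in ("jitter_sd_m", "scale_noise", "commission_per_ha", "duplicate_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Scene:
    """A synthetic scene: extent + GSD + labeled crown and 'Other' polygons."""

    config: SceneConfig
    crowns: list[Polygon]
    others: list[Polygon]
    crs: str = "local-meters"

    @property
    def extent(self) -> BBox:
        return self.config.extent


def fit_truncated_lognormal(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose truncation to [lower, upper] has the
    requested mean and sd.

    Truncation pulls both moments in, so the underlying sigma must exceed
    the naive log-normal fit; solved by root-finding on the closed-form
    truncated moments.
    """
    if not lower < mean < upper:
        raise ValueError("mean must lie strictly inside the truncation bounds")

    la, lb = math.log(lower), math.log(upper)

    def trunc_moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        z = stats.norm.cdf((lb - mu) / sigma) - stats.norm.cdf((la - mu) / sigma)
        if z <= 0:
            return np.array([1e6, 1e6])

        def raw(k: int) -> float:
            shift = k * sigma
            num = stats.norm.cdf((lb - mu) / sigma - shift) - stats.norm.cdf(
                (la - mu) / sigma - shift
            )
            return math.exp(k * mu + 0.5 * k * k * sigma * sigma) * num / z

        m1 = raw(1)
        var = raw(2) - m1 * m1
        return np.array([m1 - mean, math.sqrt(max(var, 1e-12)) - sd])

    # start from the untruncated log-normal with the target CV
    cv2 = (sd / mean) ** 2
    sigma0 = math.sqrt(math.log1p(cv2))
    mu0 = math.log(mean) - 0.5 * sigma0**2
    sol = optimize.root(trunc_moments, x0=[mu0, math.log(sigma0)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"truncated log-normal fit failed: {sol.message}")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    return mu, sigma


_LOGNORM_CACHE: dict[tuple[float, float, float, float], tuple[float, float]] = {}


def sample_crown_areas_px(cfg: SceneConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` crown pixel areas from the truncated log-normal.

    Inverse-CDF sampling restricted to [F(min), F(max)] — exact truncation,
    no rejection loop.
    """
    key = (
        cfg.crown_area_px_mean,
        cfg.crown_area_px_sd,
        cfg.crown_area_px_min,
        cfg.crown_area_px_max,
    )
    if key not in _LOGNORM_CACHE:
        _LOGNORM_CACHE[key] = fit_truncated_lognormal(*key)
    mu, sigma = _LOGNORM_CACHE[key]
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    fa, fb = dist.cdf(cfg.crown_area_px_min), dist.cdf(cfg.crown_area_px_max)
    u = fa + (fb - fa) * rng.random(n)
    return dist.ppf(u)


# a 64-gon underestimates the disc area by ~0.16%; inflate the radius so the
# polygon area equals the drawn area
_AREA_CORRECTION = math.sqrt(2.0 * math.pi / (64 * math.sin(2.0 * math.pi / 64)))


def _crown_radius(area_m2: float) -> float:
    return math.sqrt(area_m2 / math.pi) * _AREA_CORRECTION


def _sample_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = cfg.extent_m
    lam = cfg.density_stems_ha * (w * h) / M2_PER_HA
    if cfg.point_process == "poisson":
        n = rng.poisson(lam)
        return np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    # perturbed planting grid: square spacing at the target density, jitter
    # sd = 20% of spacing; emulates plantation rows
    spacing = math.sqrt((w * h) / lam) if lam > 0 else max(w, h)
    xs = np.arange(spacing / 2, w, spacing)
    ys = np.arange(spacing / 2, h, spacing)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts += rng.normal(0.0, 0.2 * spacing, size=pts.shape)
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    return pts[inside]


def generate_scene(cfg: SceneConfig, rng: Optional[np.random.Generator] = None) -> Scene:
    """Generate a scene at the configured density and crown-size statistics.

    Crown centers are inset from the extent edge by each crown's radius so
    every polygon lies fully inside the extent. Crowns may overlap — crown
    overlap is a real feature of dense regeneration, not an artifact.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    w, h = cfg.extent_m

    # the smallest configured crown must fit inside the extent; drawing
    # zero crowns from the point process, by contrast, is a valid outcome
    r_min = _crown_radius(cfg.crown_area_px_min * cfg.gsd_m**2)
    if min(w, h) < 2.0 * r_min:
        raise ValueError(
            f"extent {w} x {h} m cannot contain any crown: the smallest "
            f"configured crown has diameter {2 * r_min:.3f} m"
        )
    # crowns larger than the extent are truncated to the largest that fits
    fit_px = (min(w, h) / (2.0 * _AREA_CORRECTION)) ** 2 * math.pi / cfg.gsd_m**2
    area_px_hi = min(cfg.crown_area_px_max, fit_px)

    centers = _sample_centers(cfg, rng)
    n = len(centers)
    areas_px = np.minimum(sample_crown_areas_px(cfg, n, rng), area_px_hi)
    areas_m2 = areas_px * cfg.gsd_m**2
    crowns: list[Polygon] = []
    for center, a_m2 in zip(centers, areas_m2):
        r = _crown_radius(a_m2)
        c = np.clip(center, [r, r], [max(w - r, r), max(h - r, r)])
        crowns.append(buffer_point(c, r))

    others = _sample_other_vegetation(cfg, rng)
    return Scene(config=cfg, crowns=crowns, others=others)


def _sample_other_vegetation(cfg: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    """Non-target vegetation patches covering ~other_fraction of the scene."""
    w, h = cfg.extent_m
    target_area = cfg.other_fraction * w * h
    patches: list[Polygon] = []
    covered = 0.0
    while covered < target_area:
        r = rng.uniform(0.3, 1.0)
        c = rng.uniform([r, r], [max(w - r, r), max(h - r, r)])
        p = buffer_point(c, r)
        patches.append(p)
        covered += p.area
    return patches


def simulate_detections(
    scene: Scene, d: DetectorConfig, rng: Optional[np.random.Generator] = None
) -> list[Detection]:
    """Simulate detector output over a scene.

    With ``p_detect=1``, ``jitter_sd_m=0``, ``scale_noise=0`` and no
    commission, exactly one box per crown, each its envelope.
    """
    if rng is None:
        rng = np.random.default_rng(d.seed)
    dets: list[Detection] = []
    w, h = scene.config.extent_m

    detected = rng.random(len(scene.crowns)) < d.p_detect
    n_det = int(detected.sum())
    confs = d.conf_tp_dist.sample(rng, n_det)
    i_conf = 0
    for crown, hit in zip(scene.crowns, detected):
        if not hit:
            continue
        n_boxes = 1 + (rng.poisson(d.duplicate_rate) if d.duplicate_rate > 0 else 0)
        base_conf = confs[i_conf]
        i_conf += 1
        for k in range(n_boxes):
            bb = _jittered_box(crown, d, rng)
            conf = base_conf if k == 0 else float(
                np.clip(base_conf - rng.uniform(0.0, 0.05), 0.0, 1.0)
            )
            dets.append(Detection(box=bb, confidence=float(conf), label="White Pine"))

    if d.commission_per_ha > 0:
        n_fp = rng.poisson(d.commission_per_ha * scene.config.area_ha)
        fp_confs = d.conf_fp_dist.sample(rng, n_fp)
        sizes = sample_crown_areas_px(scene.config, n_fp, rng) * scene.config.gsd_m**2
        for conf, a_m2 in zip(fp_confs, sizes):
            half = math.sqrt(a_m2) / 2.0
            cx, cy = rng.uniform(half, max(w - half, half)), rng.uniform(
                half, max(h - half, half)
            )
            dets.append(
                Detection(
                    box=BBox(cx - half, cy - half, cx + half, cy + half),
                    confidence=float(conf),
                    label="White Pine",
                )
            )
    return dets


def benchmark_layout(
    n_crowns: int = 500,
    n_others: int = 500,
    n_crowns_hit: int = 412,
    n_others_hit: int = 2,
    spacing_m: float = 5.0,
    crown_radius_m: float = 0.5,
    other_radius_m: float = 0.4,
) -> tuple[list[Polygon], list[Polygon], list[Detection]]:
    """Deterministic validation layout with an exactly known confusion matrix.

    Crowns sit on a square grid at ``spacing_m``; 'Other' discs sit on the
    same grid offset by half a spacing diagonally, so no geometry touches
    any other. Detections are the envelopes of the first ``n_crowns_hit``
    crowns plus one small box inside each of the first ``n_others_hit``
    Other discs. Feeding the result to the assessment must return exactly
    (TP, FP, FN, TN) = (n_crowns_hit, n_others_hit,
    n_crowns - n_crowns_hit, n_others - n_others_hit).
    """
    if spacing_m < 2.0 * (crown_radius_m * 2.0 + other_radius_m):
        raise ValueError("spacing too small for guaranteed disjointness")
    n_cols = math.ceil(math.sqrt(max(n_crowns, n_others)))

    def grid_pos(i: int, offset: float) -> tuple[float, float]:
        r, c = divmod(i, n_cols)
        return (offset + c * spacing_m, offset + r * spacing_m)

    crowns = [buffer_point(grid_pos(i, spacing_m), crown_radius_m) for i in range(n_crowns)]
    others = [
        buffer_point(grid_pos(i, spacing_m / 2.0), other_radius_m) for i in range(n_others)
    ]
    dets = [
        Detection(box=BBox(*crowns[i].bounds), confidence=0.97, label="White Pine")
        for i in range(n_crowns_hit)
    ]
    h = other_radius_m / 2.0
    for i in range(n_others_hit):
        cx, cy = grid_pos(i, spacing_m / 2.0)
        dets.append(
            Detection(
                box=BBox(cx - h, cy - h, cx + h, cy + h),
                confidence=0.96,
                label="White Pine",
            )
        )
    return crowns, others, dets


def _jittered_box(crown: Polygon, d: DetectorConfig, rng: np.random.Generator) -> BBox:
    xmin, ymin, xmax, ymax = crown.bounds
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    hw, hh = 0.5 * (xmax - xmin), 0.5 * (ymax - ymin)
    if d.jitter_sd_m > 0:
        cx += rng.normal(0.0, d.jitter_sd_m)
        cy += rng.normal(0.0, d.jitter_sd_m)
    if d.scale_noise > 0:
        s = math.exp(rng.normal(0.0, d.scale_noise))
        hw *= s
        hh *= s
    return BBox(cx - hw, cy - hh, cx + hw, cy + hh)
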