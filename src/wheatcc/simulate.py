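"""Synthetic canopy scenes and multi-factor trial tables.

Two generators make the whole pipeline testable without field data:

* :func:`generate_canopy_image` paints random elliptical leaf blobs over a
  soil background and returns both the RGB image and the exact boolean
  ground-truth mask, so segmentation accuracy can be scored against a
  known cover fraction.

* :func:`generate_trial` emulates a multi-site, multi-season winter-wheat
  N-response trial (4 cultivars x 5 N rates x 3 replicates x 3 Feekes
  stages by default).  Canopy cover rises across stages and with N supply;
  shoot dry matter (SDM, t/ha), leaf area index (LAI) and shoot N
  accumulation (SNA, kg/ha) follow cultivar-specific power laws of CC with
  multiplicative lognormal noise; shoot N concentration (SNC, % of dry
  matter) is derived through the accounting identity SNA = 10 * SDM * SNC
  so that identity holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageSceneConfig",
    "CultivarParams",
    "TrialConfig",
    "generate_canopy_image",
    "generate_trial",
    "write_image_set",
]


@dataclass(frozen=True)
class ImageSceneConfig:
    """Parameters of one synthetic canopy scene.

    leaf_color_mean must be green-dominant (G−R > 0) and soil_color_mean
    red-dominant (G−R ≤ 0) so the scene is separable by the G−R index.
    The generator hits ``target_cover`` exactly (to the nearest pixel).
    """

    width: int = 320
    height: int = 240
    target_cover: float = 0.5
    leaf_color_mean: tuple[int, int, int] = (60, 130, 50)
    soil_color_mean: tuple[int, int, int] = (140, 70, 60)
    color_noise_sd: float = 6.0
    n_leaf_blobs: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.target_cover <= 1.0:
            raise ValueError(
                f"target_cover must be in [0, 1], got {self.target_cover}"
            )
        lr, lg, _ = self.leaf_color_mean
        sr, sg, _ = self.soil_color_mean
        if lg - lr <= 0:
            raise ValueError("leaf color must be green-dominant (G-R > 0)")
        if sg - sr > 0:
            raise ValueError("soil color must satisfy G-R <= 0")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be >= 0")


def _ellipse_pixels(
    rng: np.random.Generator, width: int, height: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices inside one random rotated ellipse ("leaf")."""
    cy = rng.uniform(0, height)
    cx = rng.uniform(0, width)
    scale = max(min(width, height) / 14.0, 2.0)
    a = rng.uniform(0.5, 1.5) * scale          # semi-major
    b = a * rng.uniform(0.2, 0.5)              # slender, leaf-like
    theta = rng.uniform(0, np.pi)
    r0 = int(max(np.floor(cy - a), 0))
    r1 = int(min(np.ceil(cy + a), height - 1))
    c0 = int(max(np.floor(cx - a), 0))
    c1 = int(min(np.ceil(cx + a), width - 1))
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    dy, dx = rows - cy, cols - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rows[inside].ravel(), cols[inside].ravel()


def generate_canopy_image(
    config: ImageSceneConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic nadir canopy scene with exact known cover.

    Leaf blobs are accumulated until the mask reaches the pixel count
    implied by ``target_cover``; the final blob is trimmed (and any
    shortfall painted pixel-by-pixel) so the ground-truth cover equals
    ``round(target_cover * n_pixels) / n_pixels`` exactly.  Reproducible
    under a fixed seed.

    Returns
    -------
    (image, mask)
        ``image`` is (H, W, 3) uint8, ``mask`` (H, W) bool with True on
        canopy pixels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    n_pixels = h * w
    n_target = int(round(config.target_cover * n_pixels))
    mask = np.zeros((h, w), dtype=bool)

    if n_target == n_pixels:
        mask[:] = True
    elif n_target > 0:
        for _ in range(config.n_leaf_blobs * 10):
            n_have = int(mask.sum())
            if n_have >= n_target:
                break
            rr, cc = _ellipse_pixels(rng, w, h)
            if rr.size == 0:
                continue
            new = ~mask[rr, cc]
            rr, cc = rr[new], cc[new]
            n_excess = n_have + rr.size - n_target
            if n_excess > 0:
                keep = rng.permutation(rr.size)[: rr.size - n_excess]
                rr, cc = rr[keep], cc[keep]
            mask[rr, cc] = True
        shortfall = n_target - int(mask.sum())
        if shortfall > 0:  # blobs saturated; paint remaining pixels directly
            flat_bg = np.flatnonzero(~mask.ravel())
            pick = rng.choice(flat_bg, size=shortfall, replace=False)
            mask.ravel()[pick] = True

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = config.soil_color_mean
    img[mask] = config.leaf_color_mean
    if config.color_noise_sd > 0:
        img += rng.normal(0.0, config.color_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def write_image_set(
    out_dir: "str | Path",
    n: int = 10,
    cover_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    width: int = 320,
    height: int = 240,
) -> pd.DataFrame:
    """Write ``n`` synthetic scenes as PNGs plus a ground-truth CSV.

    Target covers are evenly spaced over ``cover_range``.  Returns the
    ground-truth table (``image_path, target_cover, true_cover``) which is
    also written as ``ground_truth.csv`` in ``out_dir``.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covers = np.linspace(cover_range[0], cover_range[1], n)
    rows = []
    for i, cover in enumerate(covers):
        cfg = ImageSceneConfig(
            width=width, height=height,
            target_cover=float(cover), seed=seed + i,
        )
        img, mask = generate_canopy_image(cfg)
        path = out / f"scene_{i:03d}.png"
        Image.fromarray(img).save(path)
        rows.append({
            "image_path": str(path),
            "target_cover": float(cover),
            "true_cover": float(mask.mean()),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out / "ground_truth.csv", index=False)
    return table


@dataclass(frozen=True)
class CultivarParams:
    """Power-law parameters linking CC to growth indices for one cultivar.

    ``a_d, b_d`` drive SDM = a_d * CC**b_d (t/ha); ``a_l, b_l`` drive LAI;
    ``a_n, b_n`` drive SNA (kg/ha).  ``a`` is the index value at full
    cover (CC = 1); ``b`` the allometric exponent.
    """

    a_d: float
    b_d: float
    a_l: float
    b_l: float
    a_n: float
    b_n: float


# four winter-wheat cultivars with contrasting architecture: WM28 grows
# fastest at low cover (high a, low b), AK58 the opposite
DEFAULT_CULTIVARS: Mapping[str, CultivarParams] = {
    "AK58": CultivarParams(4.87, 1.92, 3.66, 1.63, 134.37, 1.73),
    "YM58": CultivarParams(5.05, 1.76, 3.68, 1.46, 134.77, 1.56),
    "BN207": CultivarParams(5.79, 1.79, 4.27, 1.52, 176.77, 1.67),
    "WM28": CultivarParams(6.72, 1.54, 4.95, 1.36, 185.24, 1.50),
}

#: reference per-stage SNC = a_s * CC**b_s parameters (% of dry matter)
DEFAULT_SNC_STAGE_PARAMS: Mapping[str, tuple[float, float]] = {
    "Feekes 3": (11.97, 1.03),
    "Feekes 5": (3.81, 0.50),
    "Feekes 6": (3.46, 0.86),
}

#: CC trajectory endpoints (first stage, last stage) at the extreme N rates
DEFAULT_CC_ENDPOINTS: Mapping[int, tuple[float, float]] = {
    0: (0.18, 0.61),
    300: (0.30, 0.88),
}


@dataclass(frozen=True)
class TrialConfig:
    """Design and stochastic structure of a synthetic N-response trial.

    The default design mirrors a 2-site x 2-season x 4-cultivar x
    5-N-rate x 3-replicate x 3-stage field experiment (720 records).
    ``cc_range_per_n_rate`` gives (first-stage, last-stage) mean CC per N
    rate; rates without an entry are linearly interpolated between the
    lowest and highest specified rates.  ``noise_cv`` is the coefficient
    of variation of the multiplicative lognormal noise on each growth
    index; ``cc_jitter_sd`` the Gaussian plot-to-plot scatter of CC.
    """

    sites: Sequence[str] = ("Xinxiang", "Qinyang")
    seasons: Sequence[str] = ("2016-2017", "2017-2018")
    cultivars: Mapping[str, CultivarParams] = field(
        default_factory=lambda: dict(DEFAULT_CULTIVARS)
    )
    n_rates: Sequence[int] = (0, 75, 150, 225, 300)
    replicates: int = 3
    stages: Sequence[str] = ("Feekes 3", "Feekes 5", "Feekes 6")
    cc_range_per_n_rate: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CC_ENDPOINTS)
    )
    cc_jitter_sd: float = 0.05
    noise_cv: float = 0.1
    snc_stage_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SNC_STAGE_PARAMS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.cc_jitter_sd < 0:
            raise ValueError("cc_jitter_sd must be >= 0")
        for rate, (lo, hi) in self.cc_range_per_n_rate.items():
            if not (0 < lo < 1 and 0 < hi < 1):
                raise ValueError(
                    f"CC endpoints for N rate {rate} must lie in (0, 1)"
                )
        if not self.cultivars:
            raise ValueError("at least one cultivar is required")
        if len(self.stages) < 1:
            raise ValueError("at least one stage is required")

    def cc_endpoints(self, n_rate: float) -> tuple[float, float]:
        """(first-stage, last-stage) mean CC at a given N rate."""
        table = dict(self.cc_range_per_n_rate)
        if n_rate in table:
            return table[n_rate]
        rates = sorted(table)
        lo_r, hi_r = rates[0], rates[-1]
        if hi_r == lo_r:
            return table[lo_r]
        t = np.clip((n_rate - lo_r) / (hi_r - lo_r), 0.0, 1.0)
        lo = table[lo_r][0] + t * (table[hi_r][0] - table[lo_r][0])
        hi = table[lo_r][1] + t * (table[hi_r][1] - table[lo_r][1])
        return float(lo), float(hi)


def generate_trial(config: TrialConfig | None = None) -> pd.DataFrame:
    """Simulate destructive-sampling records for the configured trial.

    For each site x season x cultivar x N rate x replicate x stage the
    mean CC is interpolated along the stage axis between that N rate's
    endpoints, jittered with Gaussian noise and clipped to (0.02, 0.98);
    SDM, LAI and SNA then follow the cultivar power laws with independent
    median-one lognormal noise (CV = ``noise_cv``), and
    SNC = SNA / (10 * SDM).

    Returns a DataFrame with columns ``site, season, cultivar,
    n_rate_kg_ha, replicate, stage, cc, sdm_t_ha, lai, snc_pct,
    sna_kg_ha``.  Deterministic for a fixed ``config.seed``.
    """
    if config is None:
        config = TrialConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    # sigma of ln(eps) for a lognormal with the requested CV and median 1
    sigma = float(np.sqrt(np.log1p(config.noise_cv ** 2)))
    n_stages = len(config.stages)
    rows = []
    for site in config.sites:
        for season in config.seasons:
            for cultivar, p in config.cultivars.items():
                for n_rate in config.n_rates:
                    lo, hi = config.cc_endpoints(n_rate)
                    for rep in range(1, config.replicates + 1):
                        for i, stage in enumerate(config.stages):
                            frac = i / (n_stages - 1) if n_stages > 1 else 0.5
                            cc_mean = lo + frac * (hi - lo)
                            cc = cc_mean + rng.normal(0.0, config.cc_jitter_sd)
                            cc = float(np.clip(cc, 0.02, 0.98))
                            eps = np.exp(rng.normal(0.0, sigma, size=3))
                            sdm = p.a_d * cc ** p.b_d * eps[0]
                            lai = p.a_l * cc ** p.b_l * eps[1]
                            sna = p.a_n * cc ** p.b_n * eps[2]
                            snc = sna / (10.0 * sdm)
                            rows.append({
                                "site": site,
                                "season": season,
                                "cultivar": cultivar,
                                "n_rate_kg_ha": n_rate,
                                "replicate": rep,
                                "stage": stage,
                                "cc": cc,
                                "sdm_t_ha": sdm,
                                "lai": lai,
                                "snc_pct": snc,
                                "sna_kg_ha": sna,
                            })
    return pd.DataFrame(rows)
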