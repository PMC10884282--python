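"""Seeded generator of colonoscopy-like scenes with polyp-shaped blobs.

Real colonoscopy frames are dominated by a smoothly varying pink-red mucosal
background with strong vignetting and occasional specular highlights; polyps
appear as roughly elliptical raised regions whose contrast against the
surrounding mucosa can be very low. This module emulates exactly those gross
features — and nothing subtler — so the detector, loss and evaluation code can
be exercised end to end at desk scale:

* background: base mucosa colour + smooth directional gradient + radial
  vignette + a few bright specular dots + low-frequency texture noise;
* polyps: rotated soft-edged ellipses, intensity-offset from the local
  background by a controllable contrast Δ, non-overlapping by rejection
  sampling; the emitted label is the ellipse's axis-aligned bounding box.

Three named scenario presets mirror the hard cases a polyp detector faces:
``low_contrast`` (Δ near zero), ``small`` (boxes capped at 0.08 of the image),
and ``multi`` (3–5 polyps per frame); ``typical`` is the unstressed default.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .data import write_yolo_labels

__all__ = ["SceneParams", "SCENARIOS", "generate_scene", "generate_dataset", "polyp_mask"]

# Base mucosa colour (RGB) and the warm tint applied to polyp interiors.
_MUCOSA = np.array([176.0, 108.0, 96.0])
_POLYP_TINT = np.array([1.0, 0.78, 0.68])


@dataclass(frozen=True)
class SceneParams:
    """Knobs of one synthetic scene; defaults are the 'typical' condition."""

    size: int = 256                      # square canvas, pixels
    base_color: tuple = (176.0, 108.0, 96.0)  # mean background RGB
    gradient_amplitude: float = 25.0     # smooth directional shading, intensity units
    vignette_strength: float = 0.35      # radial darkening at the corners, 0..1
    specular_count: int = 3              # bright highlight dots
    polyp_count: tuple = (1, 2)          # inclusive range of polyps per scene
    radius_range: tuple = (0.05, 0.14)   # normalized ellipse semi-axis range
    contrast: float = 35.0               # Δ: mean foreground−background intensity
    noise_sd: float = 5.0                # per-pixel texture noise
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(f"radius_range must lie within (0, 0.5), got {self.radius_range}")
        if self.polyp_count[0] < 0 or self.polyp_count[0] > self.polyp_count[1]:
            raise ValueError(f"invalid polyp_count range {self.polyp_count}")
        if self.size < 16:
            raise ValueError("canvas size must be at least 16 px")


# Scenario presets mirroring the hard detection cases (fixed study conditions).
SCENARIOS: dict[str, dict] = {
    "typical": {},
    "low_contrast": {"contrast": 10.0},
    "small": {"radius_range": (0.015, 0.035), "polyp_count": (1, 2)},
    "multi": {"polyp_count": (3, 5)},
}

SMALL_BOX_CAP = 0.08  # max normalized box side in the 'small' scenario


def scenario_params(name: str, size: int = 256, seed: int = 0, **overrides) -> SceneParams:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kw = dict(SCENARIOS[name])
    kw.update(overrides)
    return SceneParams(size=size, seed=seed, **kw)


def _background(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    s = p.size
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
    img = np.empty((s, s, 3))
    img[:] = np.asarray(p.base_color)
    # smooth directional gradient
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (xx - 0.5) * np.cos(theta) + (yy - 0.5) * np.sin(theta)
    img += (p.gradient_amplitude * ramp)[:, :, None]
    # radial vignette
    r2 = (xx - 0.5) ** 2 + (yy - 0.5) ** 2
    img *= (1.0 - p.vignette_strength * (r2 / 0.5))[:, :, None]
    # specular highlights: small bright Gaussian dots
    for _ in range(p.specular_count):
        cx, cy = rng.uniform(0.1, 0.9, size=2)
        sig = rng.uniform(0.008, 0.02)
        blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2)))
        img += (rng.uniform(40, 80) * blob)[:, :, None]
    # texture noise (correlated + white)
    img += rng.normal(0.0, p.noise_sd, size=(s, s, 1))
    return img


def polyp_mask(size: int, cx: float, cy: float, a: float, b: float,
               theta: float, softness: float = 0.15) -> np.ndarray:
    """Soft [0,1] mask of a rotated ellipse; 0.5 level set is the ellipse."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    q = (u / a) ** 2 + (v / b) ** 2
    from scipy.special import expit
    return expit(-(q - 1.0) / softness)


def _ellipse_aabb(a: float, b: float, theta: float) -> tuple[float, float]:
    """Half-extents of the axis-aligned bounding box of a rotated ellipse."""
    ex = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    ey = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    return float(ex), float(ey)


def generate_scene(p: SceneParams, max_retries: int = 200):
    """Render one scene; returns (uint8 RGB image, [(class, box), ...])."""
    rng = np.random.default_rng(p.seed)
    img = _background(p, rng)
    n_target = int(rng.integers(p.polyp_count[0], p.polyp_count[1] + 1))
    boxes: list[np.ndarray] = []
    placed = 0
    tries = 0
    while placed < n_target:
        if tries >= max_retries:
            raise RuntimeError(
                f"could not place {n_target} non-overlapping polyps after "
                f"{max_retries} retries (placed {placed})")
        tries += 1
        a = rng.uniform(*p.radius_range)
        b = a * rng.uniform(0.6, 1.0)   # bounded aspect keeps box-to-mask IoU high
        theta = rng.uniform(0, np.pi)
        ex, ey = _ellipse_aabb(a, b, theta)
        cx = rng.uniform(ex + 0.02, 1.0 - ex - 0.02)
        cy = rng.uniform(ey + 0.02, 1.0 - ey - 0.02)
        box = np.array([cx, cy, 2 * ex, 2 * ey])
        # non-overlap: keep axis-aligned boxes disjoint with a small gap
        clear = all(
            abs(cx - q[0]) > (box[2] + q[2]) / 2 + 0.01
            or abs(cy - q[1]) > (box[3] + q[3]) / 2 + 0.01
            for q in boxes)
        if not clear:
            continue
        mask = polyp_mask(p.size, cx, cy, a, b, theta)
        bump = p.contrast * _POLYP_TINT
        img += mask[:, :, None] * bump
        # gentle interior texture so polyps are not flat discs
        img += (mask * rng.normal(0.0, p.noise_sd * 0.5, size=mask.shape))[:, :, None]
        boxes.append(box)
        placed += 1
    labels = [(0, b) for b in boxes]
    return np.clip(img, 0, 255).astype(np.uint8), labels


def _plain(obj):
    """Recursively convert numpy scalars/sequences to YAML-safe python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def generate_dataset(n: int, scenario_mix: dict[str, float], out_dir,
                     seed: int = 0, size: int = 256) -> dict:
    """Write n scenes (images/, labels/, manifest.yaml) with a scenario mix.

    Scenario counts follow largest-remainder apportionment of the mix over n;
    scene order is a seeded shuffle. Deterministic: the same (n, mix, seed,
    size) produce byte-identical files.
    """
    if abs(sum(scenario_mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"scenario mix must sum to 1, got {sum(scenario_mix.values())}")
    for name in scenario_mix:
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}")
    out = Path(out_dir)
    img_dir, lbl_dir = out / "images", out / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)

    names = sorted(scenario_mix)
    shares = np.array([scenario_mix[s] for s in names]) * n
    counts = np.floor(shares).astype(int)
    order = sorted(range(len(names)), key=lambda i: (-(shares[i] - counts[i]), i))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    roster = [s for s, c in zip(names, counts) for _ in range(int(c))]
    rng = np.random.default_rng(seed)
    roster = [roster[i] for i in rng.permutation(n)]

    records = []
    for i, scen in enumerate(roster):
        p = scenario_params(scen, size=size, seed=int(seed) * 1_000_003 % (2**31) + i)
        img, labels = generate_scene(p)
        stem = f"scene_{i:05d}"
        Image.fromarray(img).save(img_dir / f"{stem}.png")
        write_yolo_labels(lbl_dir / f"{stem}.txt", labels)
        records.append({"stem": stem, "scenario": scen, "objects": len(labels)})

    manifest = {
        "images": "images",
        "labels": "labels",
        "names": ["polyp"],
        "n": int(n),
        "size": int(size),
        "seed": int(seed),
        "scenario_mix": {k: float(v) for k, v in scenario_mix.items()},
        "scenes": records,
        "scene_params": {k: _plain(dataclasses.asdict(scenario_params(k))) for k in names},
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
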