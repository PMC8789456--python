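"""Synthetic CT-like slices with class-dependent haemorrhage geometry.

Every pipeline stage is testable without any download: this module draws
cartoon axial head slices — a skull ellipse, brain parenchyma, and one
bright (hyperdense) lesion whose geometry depends on the haemorrhage
subtype — plus Gaussian and salt-and-pepper noise, and returns the exact
lesion mask alongside each image.

Subtype geometries are cartoon proxies motivated by radiological
descriptions, not anatomical simulation:

* EPI — biconvex lens pressed against the inner skull margin;
* SBD — thin crescent hugging the skull;
* IPC — compact blob inside the parenchyma;
* IVT — small flattened blob at the ventricle (image centre);
* SAD — thin curvilinear streaks in the subarachnoid zone.

Intensities keep background/brain/skull in a tight dark band and the
lesion well above it, so single-threshold Otsu isolates the lesion; the
default class balance mirrors the 341-image benchmark distribution
(EPI 171, IVT 24, IPC 72, SBD 56, SAD 18), scalable by a factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import add_gaussian_noise, add_salt_pepper_noise, save_grayscale

__all__ = [
    "SyntheticConfig",
    "SyntheticSample",
    "generate_dataset",
    "skull_geometry",
    "shape_descriptors",
    "linearly_separable_features",
    "write_dataset",
    "load_manifest",
]

DEFAULT_COUNTS = {"EPI": 171, "IVT": 24, "IPC": 72, "SBD": 56, "SAD": 18}


@dataclass(frozen=True)
class SyntheticConfig:
    size: int = 64
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    scale: float = 1.0                      # multiplies every class count
    background_intensity: int = 60
    brain_intensity: int = 80
    skull_intensity: int = 90
    lesion_intensity: tuple[int, int] = (200, 235)
    gaussian_sigma: float = 4.0
    salt_pepper_rate: float = 0.02
    levels: int = 256
    seed: int = 0

    def validate(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32 for lesions to fit the skull")
        if not 0.0 <= self.salt_pepper_rate < 0.5:
            raise ValueError("salt-pepper rate must be in [0, 0.5)")
        for cls, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for class {cls!r} must be >= 1")
        if self.lesion_intensity[0] <= self.skull_intensity:
            raise ValueError("lesion floor must exceed the skull intensity")

    def scaled_counts(self) -> dict:
        return {c: max(1, int(round(n * self.scale))) for c, n in self.counts.items()}


@dataclass
class SyntheticSample:
    image: np.ndarray       # uint8 (size, size)
    label: str
    mask: np.ndarray        # bool ground-truth lesion mask


def skull_geometry(size: int) -> dict:
    """Skull ellipse ring and brain-interior mask shared by all samples."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    ay, ax = 0.44 * size, 0.40 * size
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    ring_w = max(1.5, size / 40.0) / min(ay, ax)
    return {
        "center": (cy, cx),
        "axes": (ay, ax),
        "rho": rho,
        "skull": (rho >= 1.0 - ring_w) & (rho <= 1.0),
        "brain": rho < 1.0 - ring_w,
        "angle": np.arctan2(yy - cy, xx - cx),
    }


def _disc(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(size, center, semi_axes, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _segment_mask(size, p0, p1, width) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L2 = float(d @ d)
    t = np.clip(((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / max(L2, 1e-9), 0, 1)
    dist2 = (yy - p0[0] - t * d[0]) ** 2 + (xx - p0[1] - t * d[1]) ** 2
    return dist2 <= width**2


def _margin_point(geom: dict, phi: float, rho: float) -> tuple[float, float]:
    cy, cx = geom["center"]
    ay, ax = geom["axes"]
    return cy + rho * ay * np.sin(phi), cx + rho * ax * np.cos(phi)


def _lesion_mask(cls: str, size: int, geom: dict, rng: np.random.Generator) -> np.ndarray:
    brain = geom["brain"]
    phi = rng.uniform(0.0, 2.0 * np.pi)
    if cls == "EPI":
        # biconvex lens: intersection of two discs straddling the margin
        p = _margin_point(geom, phi, 0.86)
        r = 0.22 * size
        off = 0.165 * size
        n = np.array([np.sin(phi), np.cos(phi)])  # outward normal (y, x)
        c1 = np.asarray(p) + off * n
        c2 = np.asarray(p) - off * n
        lesion = _disc(size, tuple(c1), r) & _disc(size, tuple(c2), r)
    elif cls == "SBD":
        # crescent along the inner skull table
        width = rng.uniform(0.55, 0.75)
        rho, ang = geom["rho"], geom["angle"]
        dphi = np.angle(np.exp(1j * (ang - phi)))
        lesion = (rho >= 0.78) & (rho <= 0.90) & (np.abs(dphi) <= width)
    elif cls == "IPC":
        rad = rng.uniform(0.095, 0.125) * size
        rr = rng.uniform(0.25, 0.45)
        p = _margin_point(geom, phi, rr)
        lesion = _ellipse(size, p, (rad, rad * rng.uniform(0.75, 0.95)),
                          rng.uniform(0, np.pi))
    elif cls == "IVT":
        cy, cx = geom["center"]
        jit = 0.03 * size
        center = (cy + rng.uniform(-jit, jit), cx + rng.uniform(-jit, jit))
        lesion = _ellipse(size, center, (0.10 * size, 0.042 * size),
                          rng.uniform(-0.4, 0.4))
    elif cls == "SAD":
        lesion = np.zeros((size, size), dtype=bool)
        n_streaks = rng.integers(2, 4)
        for _ in range(n_streaks):
            a = rng.uniform(0.0, 2.0 * np.pi)
            p0 = _margin_point(geom, a, rng.uniform(0.60, 0.78))
            direction = a + np.pi + rng.uniform(-0.5, 0.5)
            length = rng.uniform(0.18, 0.28) * size
            p1 = (p0[0] + length * np.sin(direction),
                  p0[1] + length * np.cos(direction))
            lesion |= _segment_mask(size, p0, p1, width=max(1.0, size / 55.0))
    else:
        raise ValueError(f"unknown class {cls!r}")
    lesion &= brain
    return lesion


def generate_dataset(cfg: SyntheticConfig | None = None) -> list[SyntheticSample]:
    """Deterministic-given-seed labelled samples with exact lesion masks."""
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    geom = skull_geometry(cfg.size)
    lo, hi = cfg.lesion_intensity

    samples = []
    for cls, n in cfg.scaled_counts().items():
        for _ in range(n):
            mask = _lesion_mask(cls, cfg.size, geom, rng)
            for _ in range(20):  # retry until the lesion fits in the skull
                if mask.sum() >= max(8, 0.004 * cfg.size**2):
                    break
                mask = _lesion_mask(cls, cfg.size, geom, rng)
            else:
                raise RuntimeError(f"lesion for {cls} cannot fit in the skull")
            img = np.full((cfg.size, cfg.size), cfg.background_intensity, dtype=float)
            img[geom["brain"]] = cfg.brain_intensity
            img[geom["skull"]] = cfg.skull_intensity
            img[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
            img = img.astype(np.uint8)
            if cfg.gaussian_sigma > 0:
                img = add_gaussian_noise(img, cfg.gaussian_sigma, rng, cfg.levels)
            if cfg.salt_pepper_rate > 0:
                img = add_salt_pepper_noise(img, cfg.salt_pepper_rate, rng, cfg.levels)
            samples.append(SyntheticSample(image=img, label=cls, mask=mask))
    return samples


# ---------------------------------------------------------------------------
# shape descriptors (used to verify the classes are geometrically separable)

def shape_descriptors(mask: np.ndarray, geom: dict) -> np.ndarray:
    """(area fraction, eccentricity, skull-contact fraction, elongation).

    Moments are computed on the full (possibly multi-component) mask.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.sum()
    if n == 0:
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    cov = np.cov(np.vstack([ys - cy, xs - cx])) if n > 1 else np.eye(2)
    ev = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    lam1, lam2 = max(ev[0], 1e-9), max(ev[-1], 1e-9)
    eccentricity = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    elongation = float(np.sqrt(lam1 / lam2))
    near_skull = geom["rho"] >= 0.74
    contact = float(np.mean(near_skull[mask]))
    return np.array([n / mask.size, eccentricity, contact, np.log(elongation)])


# ---------------------------------------------------------------------------
# feature-space fixture for the classifier

def linearly_separable_features(
    n_per_class: int, dims: int, separation: float, seed: int = 0, n_classes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance Gaussian blobs at centres ``separation`` apart."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_classes > dims and separation > 0:
        raise ValueError("need dims >= n_classes for orthogonal centres")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(dims)
        if separation > 0:
            center[c] = separation / np.sqrt(2.0)  # pairwise distance = separation
        X.append(center + rng.normal(size=(n_per_class, dims)))
        y.append(np.full(n_per_class, c))
    return np.vstack(X), np.concatenate(y)


# ---------------------------------------------------------------------------
# on-disk form: PNG images + CSV manifest (same schema a PhysioNet loader
# would emit, so downstream stages are source-agnostic)

def write_dataset(samples, out_dir) -> pd.DataFrame:
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_path = out / "images" / f"slice_{i:04d}.png"
        mask_path = out / "masks" / f"slice_{i:04d}.png"
        save_grayscale(img_path, s.image)
        save_grayscale(mask_path, s.mask.astype(np.uint8) * 255)
        rows.append(
            {"filename": str(img_path), "label": s.label, "mask": str(mask_path)}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(manifest_path) -> list[SyntheticSample]:
    from .preprocessing import load_grayscale

    df = pd.read_csv(manifest_path)
    samples = []
    for _, row in df.iterrows():
        image = load_grayscale(row["filename"])
        mask = load_grayscale(row["mask"]) > 127 if isinstance(row.get("mask"), str) else np.zeros_like(image, bool)
        samples.append(SyntheticSample(image=image, label=row["label"], mask=mask))
    return samples
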