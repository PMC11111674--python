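"""Seeded synthetic leaf images with factorized plant/disease/severity cues.

Real leaf-disease photographs are not redistributable, so tests and examples
run on rendered images in which each label group owns one independent visual
factor:

* **plant** — background hue and the leaf silhouette's aspect ratio,
* **disease** — the lesion motif (filled spot / ring / streak) and lesion hue,
* **severity** — the fraction of image area covered by lesions: Healthy is
  exactly zero, and the General and Serious coverage bands are disjoint.

Because the factors are independently decodable from pixel statistics, a
small network trained on these images can reach near-perfect triple accuracy,
which makes end-to-end learnability a meaningful test surface.  The renderer
is fully deterministic given (spec, triple, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .label_space import (
    HEALTHY,
    SEVERITY_NAMES,
    LabelSpace,
    ManifestRecord,
    TripleLabel,
    build_label_space,
    write_manifest,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "synthetic_label_space",
    "render_sample",
    "generate_dataset",
    "table_ratio_counts",
    "balanced_counts",
]

# Severity → lesion-area fraction band (fraction of total image pixels).
DEFAULT_COVERAGE_BANDS = {
    "Healthy": (0.0, 0.0),
    "General": (0.04, 0.10),
    "Serious": (0.15, 0.30),
}


class GenerationError(RuntimeError):
    """Unsatisfiable rendering constraints (e.g. lesion radius vs band width)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic image population."""

    n_plants: int = 3
    n_diseases: int = 2
    image_size: int = 64
    lesion_radius_range: tuple[int, int] = (3, 6)
    coverage_bands: dict = field(default_factory=lambda: dict(DEFAULT_COVERAGE_BANDS))
    noise_sd: float = 0.02
    class_counts: dict | None = None  # TripleLabel -> int; None = balanced
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_plants <= 12:
            raise ValueError("n_plants must be in [1, 12]")
        if not 1 <= self.n_diseases <= 19:
            raise ValueError("n_diseases must be in [1, 19]")
        if self.image_size % 16 or self.image_size % 32:
            raise ValueError("image_size must be divisible by 16 and 32")
        bands = [tuple(self.coverage_bands[s]) for s in SEVERITY_NAMES]
        for (lo, hi) in bands:
            if lo > hi or lo < 0:
                raise ValueError(f"invalid coverage band ({lo}, {hi})")
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if b >= c and not (b == c == 0.0):
                raise ValueError("coverage bands must be disjoint and ascending")
        if self.class_counts is not None and any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = {
            "n_plants": self.n_plants,
            "n_diseases": self.n_diseases,
            "image_size": self.image_size,
            "lesion_radius_range": list(self.lesion_radius_range),
            "coverage_bands": {k: list(v) for k, v in self.coverage_bands.items()},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        if self.class_counts is not None:
            d["class_counts"] = {
                f"{t.plant}|{t.disease or ''}|{t.severity}": n
                for t, n in self.class_counts.items()
            }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "class_counts" in d:
            counts = {}
            for key, n in d.pop("class_counts").items():
                plant, disease, severity = key.split("|")
                counts[TripleLabel(plant, disease or None, severity)] = int(n)
            d["class_counts"] = counts
        if "lesion_radius_range" in d:
            d["lesion_radius_range"] = tuple(d["lesion_radius_range"])
        if "coverage_bands" in d:
            d["coverage_bands"] = {k: tuple(v) for k, v in d["coverage_bands"].items()}
        return cls(**d)


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray       # H×W×3 float in [0, 1]
    triple: TripleLabel
    lesion_mask: np.ndarray  # H×W uint8


def synthetic_label_space(spec: SyntheticSpec) -> LabelSpace:
    """Generic vocabulary (plant_00…, disease_00…) sized to the spec."""
    plants = [f"plant_{i:02d}" for i in range(spec.n_plants)]
    diseases = [f"disease_{i:02d}" for i in range(spec.n_diseases)]
    return build_label_space(plants, diseases, SEVERITY_NAMES)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _plant_style(plant_idx: int, n_plants: int):
    """Background hue, leaf hue and silhouette aspect for one plant identity."""
    bg_hue = plant_idx / max(n_plants, 1)
    leaf_hue = 0.25 + 0.08 * ((plant_idx % 3) - 1)  # greens
    aspect = 0.55 + 0.35 * plant_idx / max(n_plants - 1, 1)
    return bg_hue, leaf_hue, aspect


def _disease_style(disease_idx: int, n_diseases: int):
    """Lesion motif index (spot/ring/streak) and lesion hue."""
    motif = disease_idx % 3
    hue = 0.02 + 0.12 * disease_idx / max(n_diseases, 1)  # browns/oranges
    return motif, hue


def _stamp_lesion(mask: np.ndarray, cy: int, cx: int, r: int, motif: int,
                  angle: float) -> None:
    """Draw one lesion of the given motif into the boolean mask, in place."""
    h, w = mask.shape
    yy, xx = np.ogrid[:h, :w]
    dy, dx = yy - cy, xx - cx
    if motif == 0:      # filled spot
        mask |= dy * dy + dx * dx <= r * r
    elif motif == 1:    # ring
        d2 = dy * dy + dx * dx
        inner = max(r - 2, 1)
        mask |= (d2 <= r * r) & (d2 >= inner * inner)
    else:               # streak
        c, s = np.cos(angle), np.sin(angle)
        along = dy * s + dx * c
        across = -dy * c + dx * s
        mask |= (np.abs(along) <= 2 * r) & (np.abs(across) <= max(r // 2, 1))


def render_sample(spec: SyntheticSpec, triple: TripleLabel, seed: int) -> SyntheticSample:
    """Render one image; lesion area fraction falls inside the severity band."""
    space = synthetic_label_space(spec)
    plant_idx = space.plants.index(triple.plant)
    rng = np.random.default_rng(seed)
    n = spec.image_size

    bg_hue, leaf_hue, aspect = _plant_style(plant_idx, spec.n_plants)
    img = np.empty((n, n, 3))
    img[:] = _hsv_to_rgb(bg_hue, 0.45, 0.55)

    # leaf silhouette: centered ellipse, plant-dependent aspect ratio
    yy, xx = np.ogrid[:n, :n]
    cy = cx = (n - 1) / 2.0
    ry, rx = 0.42 * n, 0.42 * n * aspect
    leaf = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img[leaf] = _hsv_to_rgb(leaf_hue, 0.7, 0.65)

    mask = np.zeros((n, n), dtype=bool)
    if triple.severity != HEALTHY:
        lo, hi = spec.coverage_bands[triple.severity]
        disease_idx = space.diseases.index(triple.disease)
        motif, lesion_hue = _disease_style(disease_idx, spec.n_diseases)
        target = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
        r_lo, r_hi = spec.lesion_radius_range
        if (r_hi * 2 + 1) ** 2 / (n * n) > hi:
            raise GenerationError(
                f"lesion radius up to {r_hi} cannot stay below coverage {hi} "
                f"on a {n}×{n} image")
        ys, xs = np.nonzero(leaf)
        for _ in range(10_000):
            frac = mask.sum() / mask.size
            if lo <= frac <= hi and frac >= target:
                break
            r = int(rng.integers(r_lo, r_hi + 1))
            k = int(rng.integers(0, len(ys)))
            _stamp_lesion(mask, int(ys[k]), int(xs[k]), r, motif,
                          float(rng.uniform(0, np.pi)))
            if mask.sum() / mask.size > hi:  # overshoot: restart accumulation
                mask[:] = False
        frac = mask.sum() / mask.size
        if not lo <= frac <= hi:
            raise GenerationError(
                f"could not reach coverage band [{lo}, {hi}] (got {frac:.4f})")
        img[mask] = _hsv_to_rgb(lesion_hue, 0.85, 0.45)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return SyntheticSample(img, triple, mask.astype(np.uint8))


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

def balanced_counts(spec: SyntheticSpec, per_class: int) -> dict:
    """Equal counts for every valid triple of the spec's label space."""
    space = synthetic_label_space(spec)
    counts = {}
    for plant in space.plants:
        counts[TripleLabel(plant, None, HEALTHY)] = per_class
        for disease in space.diseases:
            for severity in ("General", "Serious"):
                counts[TripleLabel(plant, disease, severity)] = per_class
    return counts


def table_ratio_counts(spec: SyntheticSpec, total: int) -> dict:
    """Counts whose severity histogram mimics the reference dataset's
    Healthy:General:Serious ≈ 5582:7600:10977 imbalance, scaled to `total`."""
    space = synthetic_label_space(spec)
    ratios = {"Healthy": 5582, "General": 7600, "Serious": 10977}
    denom = sum(ratios.values())
    sev_totals = {s: int(round(total * ratios[s] / denom)) for s in SEVERITY_NAMES}
    sev_totals["Serious"] += total - sum(sev_totals.values())  # rounding drift

    counts: dict = {}
    healthy_cells = [TripleLabel(p, None, HEALTHY) for p in space.plants]
    for i, t in enumerate(healthy_cells):
        n = sev_totals[HEALTHY] // len(healthy_cells)
        if i < sev_totals[HEALTHY] % len(healthy_cells):
            n += 1
        if n:
            counts[t] = n
    for severity in ("General", "Serious"):
        cells = [TripleLabel(p, d, severity)
                 for p in space.plants for d in space.diseases]
        for i, t in enumerate(cells):
            n = sev_totals[severity] // len(cells)
            if i < sev_totals[severity] % len(cells):
                n += 1
            if n:
                counts[t] = n
    return counts


def _sample_seed(master_seed: int, triple: TripleLabel, k: int) -> int:
    """Stable per-sample seed below 2**31, derived from the master seed."""
    key = f"{master_seed}|{triple.plant}|{triple.disease or ''}|{triple.severity}|{k}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def generate_dataset(spec: SyntheticSpec, out_dir) -> Path:
    """Write PNG images plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    counts = spec.class_counts or balanced_counts(spec, 2)

    records = []
    order = sorted(counts, key=lambda t: (t.plant, t.disease or "", t.severity))
    for triple in order:
        tag = f"{triple.plant}_{(triple.disease or 'none')}_{triple.severity}".lower()
        for k in range(counts[triple]):
            sample = render_sample(spec, triple, _sample_seed(spec.seed, triple, k))
            fname = f"{tag}_{k:04d}.png"
            arr = np.round(sample.image * 255.0).astype(np.uint8)
            Image.fromarray(arr).save(img_dir / fname)
            records.append(ManifestRecord(f"images/{fname}", triple))
    manifest_path = out_dir / "manifest.csv"
    write_manifest(records, manifest_path)
    return manifest_path
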