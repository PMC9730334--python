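"""Synthetic vein phantoms with exact ground truth.

A phantom is a capsule: all pixels within half the band thickness of a
centerline polyline.  That rasterization is parameter-free and exactly
analyzable — the centerline arc length and the thickness are the ground
truth against which the repair / refinement / measurement loop is
checked.  Degradation emulates what segmentation of a creased leaf
produces: transverse occlusion gaps that fragment the band, interior
pinholes, and isolated background specks.

Also here: the geometric augmentation ops (scale, translate, mirror,
rotate) applied identically to image and mask, and a PASCAL-VOC-layout
dataset writer with a seeded 8:1:1 train/val/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .imagecore import as_mask, as_rgb

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "degrade",
    "augment",
    "write_voc_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    canvas: tuple[int, int] = (220, 560)  # (height, width)
    centerline: tuple[tuple[float, float], ...] = ((60.0, 110.0), (500.0, 110.0))
    thickness: int = 20  # full band thickness T, px
    n_gaps: int = 2
    gap_len_px: int = 8
    n_holes: int = 5
    speckle_density: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness < 3:
            raise ValueError("thickness must be >= 3")
        if self.n_gaps < 0 or self.n_holes < 0 or self.speckle_density < 0:
            raise ValueError("gaps, holes and speckle density must be non-negative")


@dataclass(frozen=True)
class PhantomTruth:
    centerline_len_px: float
    thickness_px: int
    half_width_px: float
    centerline: tuple[tuple[float, float], ...]
    gap_spans: list[tuple[float, float]] = field(default_factory=list)
    clean_mask: np.ndarray | None = None


def _arc_length(pts: np.ndarray) -> float:
    return float(np.sqrt(np.diff(pts, axis=0) ** 2 @ np.ones(2)).sum())


def _dist_to_polyline(h: int, w: int, pts: np.ndarray) -> np.ndarray:
    """Distance from every pixel center (x, y) to the polyline."""
    ys, xs = np.mgrid[0:h, 0:w]
    p = np.stack([xs, ys], axis=-1).astype(float)
    best = np.full((h, w), np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.sqrt(((p - a) ** 2).sum(axis=-1))
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.sqrt(((p - proj) ** 2).sum(axis=-1))
        np.minimum(best, d, out=best)
    return best


def generate_phantom(spec: PhantomSpec):
    """Rasterize the capsule band.  Returns ``(rgb, mask, truth)``.

    For an even thickness the centerline is shifted down by half a pixel
    so a horizontal band covers exactly T rows of pixel centers; the
    strict ``d < T/2`` test then gives row extent T for both parities.
    Identical specs (same seed) produce bit-identical output.
    """
    h, w = spec.canvas
    pts = np.asarray(spec.centerline, dtype=float)
    if len(pts) < 2 or _arc_length(pts) == 0:
        raise ValueError("centerline must have positive length")
    margin = spec.thickness
    if (pts[:, 0].min() < margin or pts[:, 0].max() > w - margin
            or pts[:, 1].min() < margin or pts[:, 1].max() > h - margin):
        raise ValueError(f"centerline closer than {margin} px to the border")
    draw_pts = pts.copy()
    if spec.thickness % 2 == 0:
        draw_pts[:, 1] += 0.5
    d = _dist_to_polyline(h, w, draw_pts)
    mask = (d < spec.thickness / 2.0).astype(np.uint8)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[..., 0] = mask * np.uint8(255)
    truth = PhantomTruth(
        centerline_len_px=_arc_length(pts),
        thickness_px=spec.thickness,
        half_width_px=spec.thickness / 2.0,
        centerline=tuple(map(tuple, pts)),
        clean_mask=mask.copy(),
    )
    return rgb, mask, truth


def degrade(mask: np.ndarray, spec: PhantomSpec, truth: PhantomTruth | None = None):
    """Cut gaps, punch pinholes and sprinkle specks.  Returns
    ``(degraded_mask, gap_spans)``; spans are arc-length intervals.

    Gaps are transverse slabs perpendicular to the local centerline
    direction.  Holes are 1-2 px interior cavities; specks are isolated
    single background pixels (removable by a 3x3 opening).
    """
    m = as_mask(mask).copy()
    rng = np.random.default_rng(spec.seed)
    pts = np.asarray(truth.centerline if truth is not None else spec.centerline, float)
    seg_len = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    total = seg_len.sum()
    if spec.n_gaps and spec.gap_len_px >= total:
        raise ValueError("gap length exceeds band length")
    h, w = m.shape
    ys, xs = np.mgrid[0:h, 0:w]

    gap_spans = []
    if spec.n_gaps:
        # evenly spread gap centers with seeded jitter, away from the ends
        frac = (np.arange(spec.n_gaps) + 1) / (spec.n_gaps + 1)
        frac = np.clip(frac + rng.uniform(-0.05, 0.05, spec.n_gaps), 0.1, 0.9)
        for f in frac:
            s = f * total
            cum = np.concatenate([[0], np.cumsum(seg_len)])
            i = int(np.searchsorted(cum, s, side="right")) - 1
            i = min(i, len(seg_len) - 1)
            t = (s - cum[i]) / seg_len[i]
            c = pts[i] + t * (pts[i + 1] - pts[i])
            u = (pts[i + 1] - pts[i]) / seg_len[i]  # unit tangent
            along = (xs - c[0]) * u[0] + (ys - c[1]) * u[1]
            m[np.abs(along) < spec.gap_len_px / 2.0] = 0
            gap_spans.append((s - spec.gap_len_px / 2.0, s + spec.gap_len_px / 2.0))

    if spec.n_holes:
        interior = ndimage.binary_erosion(m.astype(bool), iterations=3)
        iy, ix = np.nonzero(interior)
        chosen: list[tuple[int, int]] = []
        order = rng.permutation(len(iy))
        for j in order:
            y, x = int(iy[j]), int(ix[j])
            # keep holes >= 5 px apart so each stays a distinct cavity
            if all(abs(y - cy) + abs(x - cx) >= 5 for cy, cx in chosen):
                chosen.append((y, x))
                if len(chosen) == spec.n_holes:
                    break
        for y, x in chosen:
            size = int(rng.integers(1, 3))
            m[y : y + size, x : x + size] = 0

    if spec.speckle_density > 0:
        far_bg = ~ndimage.binary_dilation(m.astype(bool), iterations=2)
        by, bx = np.nonzero(far_bg)
        n_spk = int(round(spec.speckle_density * m.size))
        if len(by) and n_spk:
            pick = rng.choice(len(by), size=min(n_spk, len(by)), replace=False)
            cand = np.zeros_like(m)
            cand[by[pick], bx[pick]] = 1
            # keep only isolated specks: no 8-neighbor among candidates
            lone = ndimage.convolve(cand.astype(int), np.ones((3, 3), int), mode="constant") == 1
            m[(cand == 1) & lone] = 1

    return m, gap_spans


def augment(img: np.ndarray, mask: np.ndarray, op: str, **params):
    """Apply one geometric augmentation identically to image and mask.

    op is one of ``scale`` (factor), ``translate`` (dx, dy), ``mirror``
    (axis: "horizontal"|"vertical"), ``rotate`` (angle_deg).  The mask is
    resampled nearest-neighbor so it stays binary.
    """
    rgb = as_rgb(img)
    m = as_mask(mask)
    if op == "scale":
        f = float(params["factor"])
        rgb2 = ndimage.zoom(rgb, (f, f, 1), order=1)
        m2 = ndimage.zoom(m, (f, f), order=0)
    elif op == "translate":
        dx, dy = int(params["dx"]), int(params["dy"])
        rgb2 = ndimage.shift(rgb, (dy, dx, 0), order=0, cval=0)
        m2 = ndimage.shift(m, (dy, dx), order=0, cval=0)
    elif op == "mirror":
        axis = 1 if params.get("axis", "horizontal") == "horizontal" else 0
        rgb2 = np.flip(rgb, axis=axis).copy()
        m2 = np.flip(m, axis=axis).copy()
    elif op == "rotate":
        ang = float(params["angle_deg"])
        if ang % 90 == 0:  # quarter turns are exact permutations
            k = int(ang // 90) % 4
            rgb2 = np.rot90(rgb, k=k, axes=(0, 1)).copy()
            m2 = np.rot90(m, k=k).copy()
        else:
            rgb2 = ndimage.rotate(rgb, ang, axes=(0, 1), reshape=True, order=0, cval=0)
            m2 = ndimage.rotate(m, ang, reshape=True, order=0, cval=0)
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return as_rgb(rgb2), as_mask(m2)


def write_voc_dataset(items, out_dir: str | Path, split_ratio=(0.8, 0.1, 0.1), seed: int = 0):
    """Write (image, mask) pairs as a PASCAL-VOC segmentation tree.

    Creates ``JPEGImages/``, ``SegmentationClass/`` and
    ``ImageSets/Segmentation/{train,val,test}.txt``.  Split sizes follow
    the largest-remainder rounding of the ratios over a seeded shuffle.
    Returns a manifest dict listing every file written.
    """
    items = list(items)
    if not items:
        raise ValueError("no items to write")
    if not math.isclose(sum(split_ratio), 1.0):
        raise ValueError("split ratios must sum to 1")
    out = Path(out_dir)
    img_dir = out / "JPEGImages"
    seg_dir = out / "SegmentationClass"
    set_dir = out / "ImageSets" / "Segmentation"
    for d in (img_dir, seg_dir, set_dir):
        d.mkdir(parents=True, exist_ok=True)

    names = []
    for i, (img, mask) in enumerate(items):
        name = f"vein_{i:04d}"
        Image.fromarray(as_rgb(img)).save(img_dir / f"{name}.jpg", quality=95)
        Image.fromarray(as_mask(mask), mode="L").save(seg_dir / f"{name}.png")
        names.append(name)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    n = len(names)
    sizes = [int(n * r) for r in split_ratio]
    rema = sorted(range(3), key=lambda k: n * split_ratio[k] - sizes[k], reverse=True)
    for k in rema:
        if sum(sizes) == n:
            break
        sizes[k] += 1
    splits = {}
    start = 0
    for split, size in zip(("train", "val", "test"), sizes):
        chosen = sorted(names[j] for j in order[start : start + size])
        (set_dir / f"{split}.txt").write_text("\n".join(chosen) + "\n")
        splits[split] = chosen
        start += size
    return {
        "root": str(out),
        "images": [f"JPEGImages/{n_}.jpg" for n_ in names],
        "masks": [f"SegmentationClass/{n_}.png" for n_ in names],
        "splits": splits,
    }
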