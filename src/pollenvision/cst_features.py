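"""Color / shape / texture (CST) features for segmented pollen grains.

One fixed-length vector per image, concatenating:

* color — arithmetic means of the hue, saturation, brightness and red
  channels over the foreground, each on the [0, 1] scale (green and blue
  are deliberately dropped);
* shape — the shape factor (object area over the area of its minimum
  enclosing circle), the circularity factor ``4 A / (pi * length^2)`` with
  ``length`` the maximum Feret (caliper) diameter, and a k-curvature
  histogram of contour angles;
* texture — gray-level co-occurrence matrix (GLCM) contrast and entropy,
  one pair per (distance, angle) offset, computed only over pixel pairs
  whose both ends lie inside the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.color import rgb2gray, rgb2hsv

from .dataset_io import SegmentedPollenImage, ValidationError

__all__ = [
    "CSTConfig",
    "Contour",
    "ShapeDescriptors",
    "CSTFeatureVector",
    "color_means",
    "extract_contour",
    "shape_descriptors",
    "k_curvature_histogram",
    "glcm",
    "glcm_contrast_entropy",
    "glcm_features",
    "quantize_gray",
    "extract_cst",
    "minimum_enclosing_circle",
]


@dataclass(frozen=True)
class CSTConfig:
    """Tunable parameters of the CST extractor.

    ``curvature_k`` is the contour-sample offset of the k-curvature
    algorithm (how far along the boundary the two angle legs reach);
    ``curvature_bin_edges`` partition [0 deg, 180 deg]; each
    (distance, angle) pair yields one GLCM and one (contrast, entropy)
    feature pair; ``gray_levels`` is the GLCM quantization n_g.
    """

    curvature_k: int = 15
    curvature_bin_edges: tuple[float, ...] = tuple(range(0, 181, 20))
    glcm_distances: tuple[int, ...] = (1, 2)
    glcm_angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gray_levels: int = 256
    entropy_log_base: str = "natural"  # or "base-2"
    circularity_mode: str = "feret"  # or "perimeter"

    def __post_init__(self) -> None:
        if self.curvature_k < 1:
            raise ValidationError("curvature_k must be >= 1")
        edges = np.asarray(self.curvature_bin_edges, dtype=float)
        if len(edges) < 2 or not (np.diff(edges) > 0).all():
            raise ValidationError("curvature_bin_edges must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 180.0:
            raise ValidationError("curvature_bin_edges must cover [0, 180] degrees")
        if any(d < 1 for d in self.glcm_distances):
            raise ValidationError("glcm_distances must be >= 1")
        if self.gray_levels < 2:
            raise ValidationError("gray_levels must be >= 2")
        if self.entropy_log_base not in ("natural", "base-2"):
            raise ValidationError("entropy_log_base must be 'natural' or 'base-2'")
        if self.circularity_mode not in ("feret", "perimeter"):
            raise ValidationError("circularity_mode must be 'feret' or 'perimeter'")

    @property
    def n_curvature_bins(self) -> int:
        return len(self.curvature_bin_edges) - 1

    @property
    def n_features(self) -> int:
        return 4 + 2 + self.n_curvature_bins + 2 * (
            len(self.glcm_distances) * len(self.glcm_angles)
        )

    def feature_names(self) -> list[str]:
        names = ["hue_mean", "saturation_mean", "brightness_mean", "red_mean",
                 "shape_factor", "circularity"]
        edges = self.curvature_bin_edges
        names += [
            f"curv_{edges[i]:g}_{edges[i + 1]:g}" for i in range(self.n_curvature_bins)
        ]
        for d in self.glcm_distances:
            for a in self.glcm_angles:
                names += [f"glcm_d{d}_a{a:g}_contrast", f"glcm_d{d}_a{a:g}_entropy"]
        return names


@dataclass
class Contour:
    """Closed, counter-clockwise outer boundary as ordered (row, col) points.

    The point list does not repeat the start; adjacency wraps around, and
    consecutive points (including last-to-first) are 8-adjacent.
    """

    points: np.ndarray  # (n, 2) int, (row, col)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("contour points must be (n, 2)")
        if len(self.points) < 4:
            raise ValidationError(
                f"contour has {len(self.points)} points; at least 4 required"
            )
        steps = np.abs(np.diff(np.vstack([self.points, self.points[:1]]), axis=0))
        if (steps.max(axis=1) > 1).any():
            raise ValidationError("consecutive contour points must be 8-adjacent")

    def __len__(self) -> int:
        return len(self.points)

    def perimeter(self) -> float:
        """Boundary length under the 8-connectivity metric (diagonal = sqrt 2)."""
        closed = np.vstack([self.points, self.points[:1]])
        d = np.abs(np.diff(closed, axis=0))
        return float(np.where(d.sum(axis=1) == 2, math.sqrt(2.0), 1.0).sum())


@dataclass
class ShapeDescriptors:
    object_area: float
    enclosing_circle_area: float
    feret_length: float
    shape_factor: float
    circularity: float


@dataclass
class CSTFeatureVector:
    """The full CST block for one image, in fixed concatenation order."""

    hue_mean: float
    saturation_mean: float
    brightness_mean: float
    red_mean: float
    shape_factor: float
    circularity: float
    curvature_histogram: np.ndarray
    texture_features: np.ndarray  # flat (contrast, entropy) per (distance, angle)
    config: CSTConfig = field(default_factory=CSTConfig)

    def to_array(self) -> np.ndarray:
        vec = np.concatenate([
            [self.hue_mean, self.saturation_mean, self.brightness_mean,
             self.red_mean, self.shape_factor, self.circularity],
            np.asarray(self.curvature_histogram, dtype=float),
            np.asarray(self.texture_features, dtype=float),
        ])
        if not np.isfinite(vec).all():
            raise ValidationError("CST feature vector contains non-finite entries")
        return vec


# ---------------------------------------------------------------------------
# Color

def color_means(image: SegmentedPollenImage) -> tuple[float, float, float, float]:
    """Arithmetic means of H, S, B (= V) and R over foreground pixels.

    RGB is converted to hue/saturation/brightness; each mean is on [0, 1].
    Hue is averaged arithmetically on the [0, 1] scale (undefined hue of
    achromatic pixels is 0 by convention); green and blue are not emitted.
    """
    if not image.mask.any():
        raise ValidationError("empty mask")
    rgb = image.pixels.astype(float) / 255.0
    hsv = rgb2hsv(rgb)
    m = image.mask
    return (
        float(hsv[..., 0][m].mean()),
        float(hsv[..., 1][m].mean()),
        float(hsv[..., 2][m].mean()),
        float(rgb[..., 0][m].mean()),
    )


# ---------------------------------------------------------------------------
# Contour extraction (Moore boundary tracing)

# Moore neighborhood in clockwise order starting north
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_OFFSET_INDEX = {tuple(o): i for i, o in enumerate(_MOORE)}


def extract_contour(mask: np.ndarray) -> Contour:
    """Ordered counter-clockwise outer boundary of a single-component mask.

    Moore-neighbor tracing with Jacob's stopping criterion; the start point
    is the topmost-then-leftmost boundary pixel, and orientation is
    normalized to counter-clockwise as displayed (shoelace on x = col,
    y = -row).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # row-major scan: topmost, then leftmost
    # conceptually entered heading east: backtrack is the background west neighbor
    current = start
    backtrack = (start[0], start[1] - 1)
    points: list[tuple[int, int]] = []
    first_move: tuple[int, int] | None = None
    max_iter = 8 * padded.size
    for _ in range(max_iter):
        k = _OFFSET_INDEX[(backtrack[0] - current[0], backtrack[1] - current[1])]
        nxt = None
        nb = backtrack
        for j in range(1, 9):
            off = _MOORE[(k + j) % 8]
            cand = (current[0] + int(off[0]), current[1] + int(off[1]))
            if padded[cand]:
                nxt = cand
                break
            nb = cand
        if nxt is None:  # isolated single pixel
            points = [current]
            break
        if current == start:
            if first_move is None:
                first_move = nxt
            elif nxt == first_move:
                break  # Jacob's criterion: re-entered start with the same exit
        points.append(current)
        current, backtrack = nxt, nb
    else:
        raise RuntimeError("contour tracing failed to terminate")
    pts = np.array(points) - 1  # undo padding
    if len(pts) < 4:
        raise ValidationError(
            f"contour has {len(pts)} points; at least 4 required"
        )
    # shoelace signed area in display coordinates (x=col, y=-row):
    # positive = counter-clockwise on screen
    x, y = pts[:, 1].astype(float), -pts[:, 0].astype(float)
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        pts = np.roll(pts[::-1], 1, axis=0)  # reverse, keep start point first
    return Contour(points=pts)


# ---------------------------------------------------------------------------
# Shape

def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(a, b, c) -> tuple[np.ndarray, float] | None:
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _in_circle(p, center, radius) -> bool:
    return np.linalg.norm(p - center) <= radius * (1 + 1e-10) + 1e-10


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle (Welzl's randomized incremental form)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValidationError("no points")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    rng = np.random.default_rng(0)  # shuffle only affects runtime, not result
    pts = pts[rng.permutation(len(pts))]
    center, radius = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(pts[i], center, radius):
            continue
        # pts[i] on boundary
        center, radius = _circle_two(pts[0], pts[i])
        for j in range(1, i):
            if _in_circle(pts[j], center, radius):
                continue
            # pts[i], pts[j] on boundary
            center, radius = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], center, radius):
                    continue
                res = _circle_three(pts[i], pts[j], pts[k])
                if res is not None:
                    center, radius = res
    return center, radius


def _hull_points(points: np.ndarray) -> np.ndarray:
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 4:
        return pts
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:  # collinear points
        return pts


def _feret_diameter(points: np.ndarray) -> float:
    hull = _hull_points(points)
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape_descriptors(
    mask: np.ndarray, circularity_mode: str = "feret"
) -> ShapeDescriptors:
    """Shape factor and circularity of a single-component foreground mask.

    shape_factor = object area / area of the minimum enclosing circle of the
    foreground.  circularity = 4 A / (pi * length^2); with the default
    ``feret`` mode, ``length`` is the maximum caliper diameter of the
    contour so a perfect disk scores exactly 1; ``perimeter`` mode uses the
    classical isoperimetric quotient 4 pi A / P^2 instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    contour = extract_contour(mask)
    area = float(mask.sum())
    hull = _hull_points(contour.points.astype(float))
    _, radius = minimum_enclosing_circle(hull)
    circle_area = math.pi * radius**2 if radius > 0 else float(area)
    feret = _feret_diameter(contour.points.astype(float))
    if circularity_mode == "perimeter":
        perim = contour.perimeter()
        circ = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
    else:
        circ = 4.0 * area / (math.pi * feret**2) if feret > 0 else 0.0
    return ShapeDescriptors(
        object_area=area,
        enclosing_circle_area=circle_area,
        feret_length=feret,
        shape_factor=area / circle_area if circle_area > 0 else 1.0,
        circularity=circ,
    )


def k_curvature_histogram(contour: Contour, config: CSTConfig) -> np.ndarray:
    """Histogram of k-curvature angles along a closed contour.

    At each contour point P_i the angle (in degrees, [0, 180]) between the
    vectors P_i -> P_{i-k} and P_i -> P_{i+k} (cyclic indices) is binned by
    ``curvature_bin_edges``; raw counts are returned, so the histogram sums
    to the number of contour points.
    """
    pts = contour.points.astype(float)
    n = len(pts)
    k = config.curvature_k
    if n <= 2 * k:
        raise ValidationError(
            f"contour of {n} points too short for curvature_k={k}"
        )
    prev = np.roll(pts, k, axis=0) - pts
    nxt = np.roll(pts, -k, axis=0) - pts
    nu = np.linalg.norm(prev, axis=1)
    nv = np.linalg.norm(nxt, axis=1)
    denom = nu * nv
    cosang = np.ones(n)  # zero-length leg -> angle 0 by convention
    ok = denom > 0
    cosang[ok] = np.clip((prev[ok] * nxt[ok]).sum(axis=1) / denom[ok], -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    counts, _ = np.histogram(angles, bins=np.asarray(config.curvature_bin_edges))
    return counts


# ---------------------------------------------------------------------------
# Texture (GLCM)

def quantize_gray(pixels: np.ndarray, gray_levels: int) -> np.ndarray:
    """Luma grayscale conversion followed by uniform quantization.

    Returns an integer raster with values in [0, gray_levels).
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        gray = rgb2gray(pixels.astype(float) / 255.0)
    else:
        gray = pixels.astype(float) / 255.0
    q = np.floor(gray * gray_levels).astype(np.int64)
    return np.clip(q, 0, gray_levels - 1)


_ANGLE_OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


def _offset_for(angle: float, distance: int) -> tuple[int, int]:
    if angle in _ANGLE_OFFSETS:
        dr, dc = _ANGLE_OFFSETS[angle]
        return dr * distance, dc * distance
    theta = math.radians(angle)
    return (-int(round(distance * math.sin(theta))),
            int(round(distance * math.cos(theta))))


def glcm(
    quantized: np.ndarray,
    mask: np.ndarray,
    distance: int,
    angle: float,
    gray_levels: int,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one (distance, angle).

    Only pixel pairs with both ends inside the mask are counted.
    """
    q = np.asarray(quantized, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    dr, dc = _offset_for(angle, distance)
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValidationError(
            f"no valid pixel pair for offset (distance={distance}, angle={angle})"
        )
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if not valid.any():
        raise ValidationError(
            f"no valid pixel pair for offset (distance={distance}, angle={angle})"
        )
    idx = a[valid] * gray_levels + b[valid]
    counts = np.bincount(idx, minlength=gray_levels**2).astype(float)
    mat = counts.reshape(gray_levels, gray_levels)
    mat = mat + mat.T  # symmetrize
    return mat / mat.sum()


def glcm_contrast_entropy(p: np.ndarray, log_base: str = "natural") -> tuple[float, float]:
    """Contrast sum_n n^2 sum_{|i-j|=n} p(i,j) and entropy -sum p log p."""
    n_g = p.shape[0]
    i, j = np.indices((n_g, n_g))
    contrast = float((p * (i - j) ** 2).sum())
    pos = p[p > 0]
    log = np.log2 if log_base == "base-2" else np.log
    entropy = float(-(pos * log(pos)).sum())
    return contrast, entropy


def glcm_features(
    quantized: np.ndarray, mask: np.ndarray, config: CSTConfig
) -> list[tuple[int, float, float, float]]:
    """(distance, angle, contrast, entropy) for every configured offset."""
    out = []
    for d in config.glcm_distances:
        for a in config.glcm_angles:
            p = glcm(quantized, mask, d, a, config.gray_levels)
            contrast, entropy = glcm_contrast_entropy(p, config.entropy_log_base)
            out.append((d, a, contrast, entropy))
    return out


# ---------------------------------------------------------------------------
# Full CST vector

def extract_cst(
    image: SegmentedPollenImage, config: CSTConfig | None = None
) -> CSTFeatureVector:
    """The full CST feature block for one image (deterministic)."""
    config = config or CSTConfig()
    h, s, v, r = color_means(image)
    shape = shape_descriptors(image.mask, config.circularity_mode)
    contour = extract_contour(image.mask)
    curv = k_curvature_histogram(contour, config)
    q = quantize_gray(image.pixels, config.gray_levels)
    tex = glcm_features(q, image.mask, config)
    tex_flat = np.array([x for row in tex for x in row[2:]])
    return CSTFeatureVector(
        hue_mean=h, saturation_mean=s, brightness_mean=v, red_mean=r,
        shape_factor=shape.shape_factor, circularity=shape.circularity,
        curvature_histogram=curv, texture_features=tex_flat, config=config,
    )
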