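"""Visual prompts: derivation from masks and rasterized overlay onto images.

A prompt is plain geometry — a point, a scribble polyline, or a bounding
box — burned directly into the RGB frame as a predefined colour code.  The
network never sees the geometry in any other form; overlaying the cue on the
pixels is what removes the need for a separate prompt encoder.

Derivation (the training path) synthesizes prompts from the annotation mask:

* point  — uniform draw over dissection-zone pixels;
* bbox   — tightest axis-aligned rectangle around the zone;
* scribble — the longest geodesic path of the zone's morphological skeleton,
  standing in for an expert's dissection trajectory: the long variant keeps
  the central 80% of that path, the short variant the central 25%.

All coordinates are 0-based (row, col); rectangles are inclusive on both
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .errors import DerivationError

__all__ = [
    "PromptGeometry", "PromptStyle", "PROMPT_KINDS",
    "derive_point", "derive_bbox", "derive_scribble", "derive_prompt", "overlay",
]

PROMPT_KINDS = ("point", "short_scribble", "long_scribble", "bbox", "none")


@dataclass
class PromptGeometry:
    """One visual prompt; exactly the field matching ``kind`` is populated."""

    kind: str
    point: tuple[int, int] | None = None
    polyline: list[tuple[int, int]] | None = None
    rect: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        if self.kind not in PROMPT_KINDS:
            raise ValueError(f"unknown prompt kind {self.kind!r}")
        populated = {
            "point": self.point is not None,
            "polyline": self.polyline is not None,
            "rect": self.rect is not None,
        }
        expected = {
            "point": "point",
            "short_scribble": "polyline",
            "long_scribble": "polyline",
            "bbox": "rect",
            "none": None,
        }[self.kind]
        for name, is_set in populated.items():
            if name == expected and not is_set:
                raise ValueError(f"kind={self.kind!r} requires field {name!r}")
            if name != expected and is_set:
                raise ValueError(f"kind={self.kind!r} must not populate {name!r}")
        if self.kind == "bbox":
            r0, c0, r1, c1 = self.rect
            if r0 > r1 or c0 > c1:
                raise ValueError(f"invalid rect {self.rect}: min bounds exceed max")
        if self.kind in ("short_scribble", "long_scribble") and len(self.polyline) < 2:
            raise ValueError("a scribble polyline needs at least 2 vertices")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.point is not None:
            d["point"] = [int(v) for v in self.point]
        if self.polyline is not None:
            d["polyline"] = [[int(r), int(c)] for r, c in self.polyline]
        if self.rect is not None:
            d["rect"] = [int(v) for v in self.rect]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PromptGeometry":
        return cls(
            kind=d["kind"],
            point=tuple(d["point"]) if "point" in d else None,
            polyline=[tuple(v) for v in d["polyline"]] if "polyline" in d else None,
            rect=tuple(d["rect"]) if "rect" in d else None,
        )


@dataclass
class PromptStyle:
    """Colour and stroke conventions used to burn prompts into the image.

    ``stroke_thickness`` and ``point_radius`` are given at ``reference_size``
    (the 532 px training resolution) and scale with min(H, W) of the image
    the prompt is drawn on, so footprints stay proportionate across
    resolutions.
    """

    color_per_kind: dict = field(default_factory=lambda: {
        "point": (0, 255, 0),
        "short_scribble": (0, 255, 0),
        "long_scribble": (0, 255, 0),
        "bbox": (255, 0, 0),
    })
    stroke_thickness: int = 3
    point_radius: int = 4
    bbox_outline_only: bool = True
    reference_size: int = 532

    def __post_init__(self):
        for kind, rgb in self.color_per_kind.items():
            if any(not (0 <= v <= 255) for v in rgb):
                raise ValueError(f"colour for {kind!r} out of [0,255]: {rgb}")
        if self.stroke_thickness < 1:
            raise ValueError("stroke_thickness must be >= 1")
        if self.point_radius < 1:
            raise ValueError("point_radius must be >= 1")

    def scaled(self, image_shape: tuple[int, ...]) -> tuple[float, float]:
        """(stroke_thickness, point_radius) in pixels for this image."""
        s = min(image_shape[0], image_shape[1]) / self.reference_size
        return max(1.0, self.stroke_thickness * s), max(1.0, self.point_radius * s)


# ---------------------------------------------------------------------------
# derivation from masks


def _zone_pixels(mask: np.ndarray) -> np.ndarray:
    pix = np.argwhere(mask == 1)
    if pix.size == 0:
        raise DerivationError("mask has no dissection-zone pixels to derive a prompt from")
    return pix


def derive_point(mask: np.ndarray, seed: int) -> PromptGeometry:
    """A point prompt drawn uniformly over the dissection zone."""
    pix = _zone_pixels(mask)
    rng = np.random.default_rng(seed)
    r, c = pix[rng.integers(len(pix))]
    return PromptGeometry(kind="point", point=(int(r), int(c)))


def derive_bbox(mask: np.ndarray) -> PromptGeometry:
    """The tightest axis-aligned rectangle enclosing the dissection zone."""
    pix = _zone_pixels(mask)
    (r0, c0), (r1, c1) = pix.min(axis=0), pix.max(axis=0)
    return PromptGeometry(kind="bbox", rect=(int(r0), int(c0), int(r1), int(c1)))


def _principal_axis_path(mask: np.ndarray) -> list[tuple[int, int]]:
    """In-zone pixel path along the zone's principal axis through its centroid.

    Used when the morphological skeleton degenerates to a point (perfectly
    round zones have no medial *course*).
    """
    pix = np.argwhere(mask == 1).astype(float)
    center = pix.mean(axis=0)
    d = pix - center
    cov = d.T @ d / len(pix)
    _, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    proj = d @ v
    n_steps = max(int(np.ceil(proj.max() - proj.min())) + 1, 2)
    path: list[tuple[int, int]] = []
    for t in np.linspace(proj.min(), proj.max(), n_steps):
        p = np.rint(center + t * v).astype(int)
        if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                and mask[p[0], p[1]] == 1):
            tp = (int(p[0]), int(p[1]))
            if not path or tp != path[-1]:
                path.append(tp)
    return path


def _skeleton_longest_path(mask: np.ndarray) -> list[tuple[int, int]]:
    """Longest geodesic pixel path on the 8-connected morphological skeleton."""
    skel = skeletonize(mask.astype(bool))
    nodes = [tuple(p) for p in np.argwhere(skel)]
    if len(nodes) < 2:
        path = _principal_axis_path(mask)
        if len(path) < 2:
            raise DerivationError(
                "dissection zone too thin to skeletonize into a trajectory "
                f"(skeleton has {len(nodes)} pixel(s))")
        return path
    index = {p: i for i, p in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    adj[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(nodes), -1, dtype=int)
        parent = np.full(len(nodes), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    # double-sweep: exact on trees, a good heuristic on the rare cyclic skeleton
    d0, _ = bfs(0)
    a = int(np.argmax(d0))
    d1, parent = bfs(a)
    b = int(np.argmax(d1))
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return [nodes[i] for i in reversed(path)]


def _central_window(n: int, fraction: float) -> tuple[int, int]:
    lo = int(round((1.0 - fraction) / 2.0 * (n - 1)))
    hi = int(round((1.0 + fraction) / 2.0 * (n - 1)))
    return lo, max(hi, lo + 1)


def derive_scribble(mask: np.ndarray, kind: str, seed: int,
                    jitter: float = 0.0) -> PromptGeometry:
    """A scribble along the zone's medial course.

    The polyline is the central 80% (long) or central 25% (short) of the
    skeleton's longest path, so the short scribble's vertices are a subset of
    the long one's for the same mask.  Optional seeded jitter perturbs
    vertices and snaps them back inside the zone; it is off by default so the
    geometry is a pure function of the mask.
    """
    if kind not in ("long_scribble", "short_scribble"):
        raise ValueError(f"kind must be long_scribble or short_scribble, got {kind!r}")
    _zone_pixels(mask)
    path = _skeleton_longest_path(mask)
    frac = 0.80 if kind == "long_scribble" else 0.25
    lo, hi = _central_window(len(path), frac)
    verts = path[lo:hi + 1]
    if len(verts) < 2:
        verts = path[max(0, lo - 1):lo + 1] or path[:2]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        arr = np.array(verts, dtype=float)
        arr += rng.normal(0.0, jitter, size=arr.shape)
        arr = np.clip(np.rint(arr), 0, np.array(mask.shape) - 1).astype(int)
        # snap any vertex that left the zone to its nearest zone pixel
        _, (ir, ic) = distance_transform_edt(mask == 0, return_indices=True)
        verts = [(int(ir[r, c]), int(ic[r, c])) if mask[r, c] == 0 else (int(r), int(c))
                 for r, c in arr]
    return PromptGeometry(kind=kind, polyline=[(int(r), int(c)) for r, c in verts])


def derive_prompt(mask: np.ndarray, kind: str, seed: int) -> PromptGeometry:
    """Dispatch on prompt kind; ``none`` yields an empty prompt."""
    if kind == "none":
        return PromptGeometry(kind="none")
    if kind == "point":
        return derive_point(mask, seed)
    if kind == "bbox":
        return derive_bbox(mask)
    return derive_scribble(mask, kind, seed)


# ---------------------------------------------------------------------------
# rasterized overlay


def _segment_footprint(shape: tuple[int, int], p0, p1, radius: float) -> np.ndarray:
    """Boolean mask of pixels within Euclidean ``radius`` of segment p0-p1."""
    h, w = shape
    r0 = max(0, int(np.floor(min(p0[0], p1[0]) - radius)))
    r1 = min(h - 1, int(np.ceil(max(p0[0], p1[0]) + radius)))
    c0 = max(0, int(np.floor(min(p0[1], p1[1]) - radius)))
    c1 = min(w - 1, int(np.ceil(max(p0[1], p1[1]) + radius)))
    out = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return out
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1].astype(float)
    v = np.array(p1, dtype=float) - np.array(p0, dtype=float)
    lv2 = float(v @ v)
    dr, dc = rr - p0[0], cc - p0[1]
    if lv2 == 0.0:
        dist = np.hypot(dr, dc)
    else:
        t = np.clip((dr * v[0] + dc * v[1]) / lv2, 0.0, 1.0)
        dist = np.hypot(dr - t * v[0], dc - t * v[1])
    out[r0:r1 + 1, c0:c1 + 1] = dist <= radius
    return out


def prompt_footprint(shape: tuple[int, int], prompt: PromptGeometry,
                     style: PromptStyle) -> np.ndarray:
    """Boolean footprint of the rasterized prompt on an image of ``shape``."""
    h, w = shape
    thickness, radius = style.scaled(shape)
    stroke_r = (thickness - 1.0) / 2.0
    foot = np.zeros(shape, dtype=bool)
    if prompt.kind == "none":
        return foot
    if prompt.kind == "point":
        r, c = prompt.point
        _check_bounds([(r, c)], shape)
        foot |= _segment_footprint(shape, (r, c), (r, c), radius)
    elif prompt.kind in ("short_scribble", "long_scribble"):
        _check_bounds(prompt.polyline, shape)
        for p0, p1 in zip(prompt.polyline[:-1], prompt.polyline[1:]):
            foot |= _segment_footprint(shape, p0, p1, stroke_r)
    elif prompt.kind == "bbox":
        r0, c0, r1, c1 = prompt.rect
        _check_bounds([(r0, c0), (r1, c1)], shape)
        if style.bbox_outline_only:
            corners = [(r0, c0), (r0, c1), (r1, c1), (r1, c0), (r0, c0)]
            for p0, p1 in zip(corners[:-1], corners[1:]):
                foot |= _segment_footprint(shape, p0, p1, stroke_r)
        else:
            foot[r0:r1 + 1, c0:c1 + 1] = True
    return foot


def _check_bounds(points, shape: tuple[int, int]) -> None:
    for r, c in points:
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(
                f"prompt coordinate ({r}, {c}) outside image of shape {shape}")


def overlay(image: np.ndarray, prompt: PromptGeometry,
            style: PromptStyle | None = None) -> np.ndarray:
    """Burn the prompt into a copy of ``image`` as its kind's colour code.

    Pixels in the rasterized footprint are set exactly to the colour; every
    other pixel is byte-identical to the input.  ``kind='none'`` returns an
    unchanged copy.
    """
    if style is None:
        style = PromptStyle()
    out = np.array(image, dtype=np.uint8, copy=True)
    if prompt.kind == "none":
        return out
    foot = prompt_footprint(image.shape[:2], prompt, style)
    out[foot] = np.asarray(style.color_per_kind[prompt.kind], dtype=np.uint8)
    return out
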