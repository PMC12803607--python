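"""Synthetic stained-biopsy image generation.

Endomyocardial biopsy fragments stained with Masson's trichrome or AFOG show
three pixel populations: cardiomyocytes (red/orange), fibrous collagen (blue)
and near-white background.  This module plants fragments with a *known*
collagen volume fraction (CVF) so the downstream quantification pipeline can
be validated against ground truth.

The fragment geometry is a smooth random blob; the interstitial fibrosis
pattern is a thresholded Gaussian-filtered noise field, which produces
spatially correlated collagen strands without attempting anatomical realism —
the pixel classifier only sees colour statistics and connectedness.

Default working resolution is 4 um/px (a 1-2 mm^2 fragment is then ~1e5
pixels); physical areas are always reported in mm^2 so results are
resolution-independent.  The palette colour statistics are package
conventions: the colours of real Tri/AFOG scans vary by lab and scanner and
no canonical values exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "BACKGROUND",
    "MUSCLE",
    "FIBROSIS",
    "StainPalette",
    "SyntheticSlide",
    "PixelTrainingSet",
    "default_palette",
    "generate_fragment",
    "add_artifacts",
    "sample_training_pixels",
    "write_slide",
    "read_slide",
]

# Fixed label order; also the classifier's tie-break order.
BACKGROUND, MUSCLE, FIBROSIS = 0, 1, 2
CLASS_NAMES = ("background", "muscle", "fibrosis")

DEFAULT_RESOLUTION_UM_PER_PX = 4.0
#: Scanner resolution of the NanoZoomer whole-slide scans the pipeline models.
SCAN_RESOLUTION_UM_PER_PX = 0.46


@dataclass(frozen=True)
class StainPalette:
    """Per-class RGB colour model for one staining protocol.

    ``mean_colors`` maps class name -> length-3 mean in [0, 255];
    ``covariances`` maps class name -> 3x3 symmetric positive-definite
    colour covariance.
    """

    stain_name: str
    mean_colors: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.mean_colors) != set(CLASS_NAMES) or set(self.covariances) != set(CLASS_NAMES):
            raise ValueError("palette must define all of " + ", ".join(CLASS_NAMES))
        means = {}
        covs = {}
        for name in CLASS_NAMES:
            m = np.asarray(self.mean_colors[name], dtype=float)
            c = np.asarray(self.covariances[name], dtype=float)
            if m.shape != (3,):
                raise ValueError(f"mean colour of {name!r} must be a 3-vector")
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError(f"covariance of {name!r} must be symmetric 3x3")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValueError(f"covariance of {name!r} must be positive-definite")
            means[name] = m
            covs[name] = c
        for i, a in enumerate(CLASS_NAMES):
            for b in CLASS_NAMES[i + 1:]:
                if np.linalg.norm(means[a] - means[b]) == 0:
                    raise ValueError(f"classes {a!r} and {b!r} share a mean colour")
        object.__setattr__(self, "mean_colors", means)
        object.__setattr__(self, "covariances", covs)


def default_palette(stain_name: str = "trichrome") -> StainPalette:
    """Built-in colour conventions for the two supported stains.

    These are package conventions chosen to resemble typical scans (muscle
    red/orange, collagen blue, background near-white), not measured values.
    """
    sigma = 12.0
    cov = {name: np.eye(3) * sigma**2 for name in CLASS_NAMES}
    if stain_name == "trichrome":
        means = {
            "muscle": np.array([180.0, 60.0, 70.0]),
            "fibrosis": np.array([70.0, 90.0, 170.0]),
            "background": np.array([245.0, 245.0, 245.0]),
        }
    elif stain_name == "afog":
        means = {
            "muscle": np.array([200.0, 110.0, 50.0]),
            "fibrosis": np.array([60.0, 80.0, 180.0]),
            "background": np.array([240.0, 240.0, 238.0]),
        }
    else:
        raise ValueError(f"unknown stain {stain_name!r} (expected 'trichrome' or 'afog')")
    return StainPalette(stain_name=stain_name, mean_colors=means, covariances=cov)


@dataclass
class SyntheticSlide:
    """One synthetic biopsy fragment: raster, ground truth and metadata."""

    pixels: np.ndarray  # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W uint8 in {0, 1, 2}
    resolution_um_per_px: float
    fragment_id: str
    true_cvf_percent: float

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.truth_mask.shape:
            raise ValueError("pixels and truth_mask dimensions differ")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")
        if not 0.0 <= self.true_cvf_percent <= 100.0:
            raise ValueError("true_cvf_percent must lie in [0, 100]")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticSlide):
            return NotImplemented
        return (
            np.array_equal(self.pixels, other.pixels)
            and np.array_equal(self.truth_mask, other.truth_mask)
            and self.resolution_um_per_px == other.resolution_um_per_px
            and self.fragment_id == other.fragment_id
            and self.true_cvf_percent == other.true_cvf_percent
        )


@dataclass
class PixelTrainingSet:
    """Labelled colour samples used to train the pixel classifier."""

    colors: np.ndarray  # n x 3 float
    labels: np.ndarray  # n int, values in {0, 1, 2}
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.colors.ndim != 2 or self.colors.shape[1] != 3:
            raise ValueError("colors must be n x 3")
        if self.labels.shape != (self.colors.shape[0],):
            raise ValueError("labels must align with colors")
        present, counts = np.unique(self.labels, return_counts=True)
        if len(present) < 2:
            raise ValueError("training set needs at least two classes")
        if counts.min() < 10:
            small = CLASS_NAMES[present[np.argmin(counts)]]
            raise ValueError(f"class {small!r} has fewer than 10 training samples")


def _smooth_noise(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")


def _draw_colors(n: int, mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    samples = mean + rng.standard_normal((n, 3)) @ chol.T
    return np.clip(np.rint(samples), 0, 255).astype(np.uint8)


def generate_fragment(
    area_mm2: float,
    target_cvf_percent: float,
    palette: StainPalette | None = None,
    blob_scale: float = 60.0,
    seed: int = 0,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    fragment_id: str | None = None,
) -> SyntheticSlide:
    """Plant one biopsy fragment with a known collagen volume fraction.

    Parameters
    ----------
    area_mm2
        Tissue area of the fragment (clinical samples are 1-2 mm^2).
    target_cvf_percent
        Planted CVF, 100 * fibrosis / (fibrosis + muscle) pixels.
    palette
        Colour model; defaults to the trichrome convention.
    blob_scale
        Correlation length of the fibrosis pattern in micrometres; larger
        values give coarser collagen strands.
    seed
        Seed for the generator; identical arguments give identical slides.
    resolution_um_per_px
        Working pixel size.  The physical area is preserved regardless.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    if not 0.0 <= target_cvf_percent <= 100.0:
        raise ValueError("target_cvf_percent must lie in [0, 100]")
    if blob_scale <= 0:
        raise ValueError("blob_scale must be positive")
    if palette is None:
        palette = default_palette()

    rng = np.random.default_rng(seed)
    res = float(resolution_um_per_px)
    n_tissue = int(round(area_mm2 * 1e6 / res**2))
    if n_tissue < 1:
        raise ValueError("fragment area is below one pixel at this resolution")

    # Canvas sized so the blob occupies roughly half, with a background margin.
    side = int(np.ceil(np.sqrt(n_tissue / 0.5)))
    h = w = max(side, 8)

    # Fragment shape: radial ramp + smooth noise, thresholded at the value
    # that yields exactly n_tissue pixels.
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot((yy - cy) / h, (xx - cx) / w)  # 0 at centre, ~0.7 at corners
    shape_field = -r + 0.15 * _smooth_noise((h, w), sigma_px=h / 10.0, rng=rng)
    if n_tissue > h * w:
        raise ValueError("fragment does not fit the canvas")  # unreachable by construction
    flat = shape_field.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    tissue_idx = order[:n_tissue]
    tissue = np.zeros(h * w, dtype=bool)
    tissue[tissue_idx] = True
    tissue = tissue.reshape(h, w)

    # Fibrosis: top-k pixels of a smoothed noise field inside the tissue.
    n_fib = int(round(n_tissue * target_cvf_percent / 100.0))
    sigma_px = blob_scale / res
    fib_field = _smooth_noise((h, w), sigma_px=sigma_px, rng=rng)
    tvals = fib_field.ravel()[tissue_idx]
    fib_order = np.argsort(tvals, kind="stable")[::-1]
    fib_idx = tissue_idx[fib_order[:n_fib]]

    mask = np.zeros(h * w, dtype=np.uint8)
    mask[tissue_idx] = MUSCLE
    mask[fib_idx] = FIBROSIS
    mask = mask.reshape(h, w)

    pixels = np.empty((h, w, 3), dtype=np.uint8)
    for label, name in enumerate(CLASS_NAMES):
        sel = mask == label
        n = int(sel.sum())
        if n:
            pixels[sel] = _draw_colors(n, palette.mean_colors[name], palette.covariances[name], rng)

    true_cvf = 100.0 * n_fib / n_tissue
    if fragment_id is None:
        fragment_id = f"synth-{seed}"
    return SyntheticSlide(
        pixels=pixels,
        truth_mask=mask,
        resolution_um_per_px=res,
        fragment_id=fragment_id,
        true_cvf_percent=true_cvf,
    )


def _place_speck(
    canvas_free: np.ndarray, radius: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Find a disk of `radius` whose dilation-by-1 fits inside `canvas_free`.

    Returns the boolean disk mask, or None if no position was found.  The
    one-pixel guard ring keeps planted specks 8-disconnected from tissue and
    from each other so component counts are exact.
    """
    h, w = canvas_free.shape
    yy, xx = np.mgrid[-radius - 1 : radius + 2, -radius - 1 : radius + 2]
    disk = yy**2 + xx**2 <= radius**2
    guard = yy**2 + xx**2 <= (radius + 1.5) ** 2
    for _ in range(200):
        cy = int(rng.integers(radius + 1, h - radius - 1)) if h > 2 * radius + 2 else None
        cx = int(rng.integers(radius + 1, w - radius - 1)) if w > 2 * radius + 2 else None
        if cy is None or cx is None:
            return None
        win = canvas_free[cy - radius - 1 : cy + radius + 2, cx - radius - 1 : cx + radius + 2]
        if win.shape != guard.shape or not win[guard].all():
            continue
        out = np.zeros((h, w), dtype=bool)
        out[cy - radius - 1 : cy + radius + 2, cx - radius - 1 : cx + radius + 2] = disk
        return out
    return None


def add_artifacts(
    slide: SyntheticSlide,
    n_dust: int = 0,
    n_micro_fragments: int = 0,
    seed: int = 0,
) -> SyntheticSlide:
    """Overlay dust specks and detached micro-fragments on the background.

    Dust is rendered as small dark blobs, micro-fragments as tissue-coloured
    specks below any sensible minimum-fragment area.  Both are labelled
    background in the ground truth: they are contamination the morphological
    post-processing step is expected to remove.  Existing tissue pixels are
    never altered.
    """
    if n_dust < 0 or n_micro_fragments < 0:
        raise ValueError("artifact counts must be non-negative")
    if n_dust == 0 and n_micro_fragments == 0:
        return slide

    rng = np.random.default_rng(seed)
    pixels = slide.pixels.copy()
    free = slide.truth_mask == BACKGROUND
    # guard ring keeps artifacts off tissue borders
    free &= ~ndimage.binary_dilation(~free, iterations=2)

    def _paint(n: int, color_fn, radii: tuple[int, int]) -> None:
        nonlocal free
        placed = 0
        while placed < n:
            radius = int(rng.integers(radii[0], radii[1] + 1))
            speck = _place_speck(free, radius, rng)
            if speck is None:
                raise RuntimeError("no background room left for artifacts")
            m = int(speck.sum())
            pixels[speck] = color_fn(m)
            free &= ~ndimage.binary_dilation(speck, iterations=2)
            placed += 1

    def _dust_color(n: int) -> np.ndarray:
        base = np.array([45.0, 40.0, 40.0])
        return np.clip(base + rng.normal(0, 8, size=(n, 3)), 0, 255).astype(np.uint8)

    def _micro_color(n: int) -> np.ndarray:
        # detached tissue: muscle-coloured speck
        pal = default_palette()
        return _draw_colors(n, pal.mean_colors["muscle"], pal.covariances["muscle"], rng)

    _paint(n_dust, _dust_color, radii=(1, 3))
    _paint(n_micro_fragments, _micro_color, radii=(1, 2))

    return replace(slide, pixels=pixels, truth_mask=slide.truth_mask.copy())


def sample_training_pixels(
    slide: SyntheticSlide, n_per_class: int, seed: int = 0
) -> PixelTrainingSet:
    """Simulate an annotator: draw labelled pixels uniformly from the truth mask."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    colors = []
    labels = []
    flat_mask = slide.truth_mask.ravel()
    flat_pix = slide.pixels.reshape(-1, 3)
    for label, name in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(flat_mask == label)
        if idx.size < n_per_class:
            raise ValueError(
                f"class {name!r} has only {idx.size} pixels, need {n_per_class}"
            )
        chosen = rng.choice(idx, size=n_per_class, replace=False)
        colors.append(flat_pix[chosen].astype(float))
        labels.append(np.full(n_per_class, label))
    return PixelTrainingSet(
        colors=np.concatenate(colors),
        labels=np.concatenate(labels),
        provenance=(slide.fragment_id,),
    )


def write_slide(path: str | Path, slide: SyntheticSlide) -> None:
    """Write raster (PNG/TIFF), mask (single-channel PNG) and JSON sidecar.

    `path` is the raster path; the mask gets a ``.mask.png`` suffix and the
    sidecar ``.json``.  The round trip is bit-exact.
    """
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError("raster path must end in .png, .tif or .tiff")
    Image.fromarray(slide.pixels, mode="RGB").save(path)
    Image.fromarray(slide.truth_mask, mode="L").save(path.with_suffix(".mask.png"))
    meta = {
        "fragment_id": slide.fragment_id,
        "resolution_um_per_px": slide.resolution_um_per_px,
        "true_cvf_percent": slide.true_cvf_percent,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_slide(path: str | Path) -> SyntheticSlide:
    """Inverse of :func:`write_slide`; validates mask labels and metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = np.asarray(Image.open(path).convert("RGB"))
    mask_path = path.with_suffix(".mask.png")
    if not mask_path.exists():
        raise FileNotFoundError(f"mask file missing: {mask_path}")
    mask = np.asarray(Image.open(mask_path))
    if mask.ndim != 2:
        raise ValueError("mask must be single-channel")
    if mask.shape != pixels.shape[:2]:
        raise ValueError("raster and mask dimensions differ")
    bad = np.setdiff1d(np.unique(mask), [BACKGROUND, MUSCLE, FIBROSIS])
    if bad.size:
        raise ValueError(f"mask contains unknown label values {bad.tolist()}")
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fragment_id", "resolution_um_per_px", "true_cvf_percent"):
        if key not in meta:
            raise ValueError(f"metadata sidecar lacks {key!r}")
    return SyntheticSlide(
        pixels=pixels.astype(np.uint8),
        truth_mask=mask.astype(np.uint8),
        resolution_um_per_px=float(meta["resolution_um_per_px"]),
        fragment_id=str(meta["fragment_id"]),
        true_cvf_percent=float(meta["true_cvf_percent"]),
    )
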