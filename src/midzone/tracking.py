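"""Spindle pole / chromosome tracking on two-channel embryo movies.

The pipeline mirrors a standard mitosis-tracking workflow for C. elegans
one-cell embryos: convert each channel to 8-bit with a global min-max
mapping, segment embryo outlines by watershed on a temporal median
projection of the tubulin channel, detect spindle poles (top-25% band,
191-255) and chromatin (top-50% band, 127-255) after a 3x3 Gaussian blur,
report chromatid leading edges relative to the pole midpoint (the
midzone), call anaphase onset as the last frame before persistent visible
chromosome segregation, compute segregation/elongation rates from the
displacement during the first 40 s after onset, and build rotation-aligned
kymographs by band-summing +/- 5 px around the pole-pole axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError

__all__ = [
    "EmbryoMovie",
    "SpindleTrace",
    "Kymograph",
    "to_eight_bit",
    "top_fraction_band",
    "segment_embryo",
    "embryo_long_axis",
    "detect_poles",
    "detect_chromatids",
    "ChromatidFrame",
    "track_movie",
    "detect_anaphase_onset",
    "segregation_rate",
    "pole_separation_rate",
    "build_kymograph",
    "enhance_kymograph",
    "pole_oscillation",
    "trace_to_csv",
]

#: default sigma (px) of the 3x3 Gaussian blur; the kernel size is fixed,
#: the sigma is a documented choice
BLUR_SIGMA = 0.8


@dataclass(frozen=True)
class EmbryoMovie:
    """8-bit multi-channel time lapse, axes (T, C, Y, X)."""

    frames: np.ndarray
    channels: dict  # role -> channel index, e.g. {"spindle": 0, "dna": 1}
    pixel_size: float  # um/px
    frame_interval: float  # s
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames)
        if fr.ndim != 4:
            raise ValueError("frames must be (T, C, Y, X)")
        if fr.shape[0] < 2:
            raise ValueError("movie needs >= 2 frames")
        if fr.dtype != np.uint8:
            raise ValueError("frames must be 8-bit; use to_eight_bit()")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        roles = list(self.channels.values())
        if len(set(roles)) != len(roles):
            raise ValueError("channel roles must map to distinct indices")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel(self, role: str) -> np.ndarray:
        return self.frames[:, self.channels[role]]


def to_eight_bit(raw: np.ndarray, channels: dict, pixel_size: float,
                 frame_interval: float) -> EmbryoMovie:
    """Convert a raw stack to 8-bit per channel.

    The global (whole-movie) min-max of each channel is mapped linearly to
    0-255 and rounded half away from zero.  Global rather than per-frame
    scaling keeps the fixed 191/127 threshold bands stationary in time.
    A constant channel maps to zeros and sets a warning flag.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 3:  # single channel convenience
        arr = arr[:, None]
    if np.any(arr < 0):
        raise ValueError("raw intensities must be non-negative")
    out = np.zeros(arr.shape, dtype=np.uint8)
    warnings = []
    for c in range(arr.shape[1]):
        lo = arr[:, c].min()
        hi = arr[:, c].max()
        if hi == lo:
            warnings.append(f"channel {c} is constant; mapped to 0")
            continue
        scaled = (arr[:, c] - lo) * (255.0 / (hi - lo))
        out[:, c] = np.floor(scaled + 0.5).astype(np.uint8)
    return EmbryoMovie(frames=out, channels=dict(channels), pixel_size=pixel_size,
                       frame_interval=frame_interval, warnings=tuple(warnings))


def top_fraction_band(p: float) -> tuple[int, int]:
    """8-bit band covering the top fraction ``p`` of the intensity range.

    ``p=0.25`` gives (191, 255) and ``p=0.5`` gives (127, 255).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    return int(np.floor((1.0 - p) * 255.0)), 255


def _blur(img: np.ndarray, sigma: float = BLUR_SIGMA) -> np.ndarray:
    """3x3 discrete Gaussian blur (kernel radius 1)."""
    return ndimage.gaussian_filter(img.astype(float), sigma=sigma, radius=1)


# ---------------------------------------------------------------------------
# Embryo segmentation
# ---------------------------------------------------------------------------

def segment_embryo(movie: EmbryoMovie, smooth_sigma: float = 2.0,
                   min_area_fraction: float = 0.005) -> np.ndarray:
    """Label embryo outlines from the low-background tubulin signal.

    A temporal median projection of the spindle channel is smoothed and
    segmented by watershed on its gradient, seeded from background and
    eroded-interior markers.  Returns a labeled 2D mask (one label per
    embryo); raises :class:`EmptyMaskError` when no foreground is found.
    """
    from skimage import filters, measure, morphology, segmentation

    proj = np.median(movie.channel("spindle").astype(float), axis=0)
    sm = ndimage.gaussian_filter(proj, smooth_sigma)
    if sm.max() <= sm.min():
        raise EmptyMaskError("blank movie: no embryo foreground")
    thr = filters.threshold_otsu(sm)
    fg = sm > thr
    if not fg.any():
        raise EmptyMaskError("no embryo foreground above threshold")
    interior = morphology.erosion(fg, morphology.disk(3))
    if not interior.any():
        interior = fg
    markers = measure.label(interior)
    markers[sm < 0.5 * thr] = markers.max() + 1  # background seed
    bg_label = markers.max()
    grad = filters.sobel(sm)
    labels = segmentation.watershed(grad, markers)
    labels[labels == bg_label] = 0
    # drop specks
    min_area = min_area_fraction * labels.size
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        raise EmptyMaskError("no embryo-sized region found")
    return out


def embryo_long_axis(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit direction (x, y) of the largest region's long axis."""
    labels, counts = np.unique(mask[mask > 0], return_counts=True)
    if labels.size == 0:
        raise EmptyMaskError("mask is empty")
    sel = mask == labels[np.argmax(counts)]
    ys, xs = np.nonzero(sel)
    pts = np.column_stack([xs, ys]).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    if direction[0] < 0:  # canonical orientation: +x component
        direction = -direction
    return centroid, direction


# ---------------------------------------------------------------------------
# Per-frame detection
# ---------------------------------------------------------------------------

def detect_poles(frame: np.ndarray, mask: np.ndarray,
                 band: tuple[int, int] | None = None,
                 sigma: float = BLUR_SIGMA,
                 axis_dir=(1.0, 0.0)) -> np.ndarray | None:
    """Detect the two spindle poles in an 8-bit spindle-channel frame.

    Blur, threshold with the top-25% band, keep the two largest connected
    components inside the mask, report intensity-weighted centroids as
    (x, y) pixel positions.  The pole with the smaller coordinate along
    ``axis_dir`` is returned first (anterior by default convention).
    Returns ``None`` when fewer than two components are found (the frame
    is flagged invalid by the caller, not an exception).
    """
    lo, hi = band if band is not None else top_fraction_band(0.25)
    bl = _blur(frame, sigma)
    binary = (bl >= lo) & (bl <= hi) & (mask > 0)
    labels, n = ndimage.label(binary)
    if n < 2:
        return None
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(areas)[-2:] + 1
    centers = []
    for lab in keep:
        sel = labels == lab
        w = bl * sel
        total = w.sum()
        ys, xs = np.nonzero(sel)
        cx = (xs * w[ys, xs]).sum() / total
        cy = (ys * w[ys, xs]).sum() / total
        centers.append((cx, cy))
    centers = np.array(centers)
    u = np.asarray(axis_dir, dtype=float)
    order = np.argsort(centers @ u)
    return centers[order]


@dataclass(frozen=True)
class ChromatidFrame:
    """Per-frame chromatin measurement in pixel units along the pole axis.

    ``edge_a``/``edge_b`` are leading-edge distances from the midzone
    toward each pole (px, positive); ``gap`` is the axial gap between the
    two largest chromatin masses (0 when a single mass).
    """

    edge_a: float
    edge_b: float
    n_components: int
    gap: float


def detect_chromatids(frame: np.ndarray, mask: np.ndarray, poles: np.ndarray,
                      band: tuple[int, int] | None = None,
                      sigma: float = BLUR_SIGMA,
                      band_halfheight: int = 8) -> ChromatidFrame | None:
    """Measure chromatid leading edges in an 8-bit DNA-channel frame.

    Thresholds with the top-50% band and reports, for each pole, the
    extreme extent of the thresholded chromatin along the pole-pole axis
    relative to the midzone (pole midpoint).  Edges are refined to
    sub-pixel by taking the maximum blurred intensity across a
    ``+/- band_halfheight`` px band perpendicular to the axis and linearly
    interpolating the outermost crossing of the threshold.  Returns
    ``None`` when no chromatin is above threshold.
    """
    lo, hi = band if band is not None else top_fraction_band(0.5)
    bl = _blur(frame, sigma)
    binary = (bl >= lo) & (bl <= hi) & (mask > 0)
    labels, n = ndimage.label(binary)
    if n == 0:
        return None
    mid = poles.mean(axis=0)
    u = poles[1] - poles[0]
    u = u / np.linalg.norm(u)
    nvec = np.array([-u[1], u[0]])
    ys, xs = np.nonzero(binary)
    s_px = (xs - mid[0]) * u[0] + (ys - mid[1]) * u[1]

    # axial band-maximum profile at 0.25 px resolution around the chromatin
    step = 0.25
    s_grid = np.arange(s_px.min() - 3.0, s_px.max() + 3.0 + step, step)
    offs = np.arange(-band_halfheight, band_halfheight + 1)
    gx = mid[0] + s_grid[None, :] * u[0] + offs[:, None] * nvec[0]
    gy = mid[1] + s_grid[None, :] * u[1] + offs[:, None] * nvec[1]
    prof = ndimage.map_coordinates(bl, [gy, gx], order=1, cval=0.0).max(axis=0)
    above = prof >= lo

    def _outer_crossing(indices) -> float:
        i = indices[-1] if indices.size else None
        if i is None:
            return float("nan")
        if i == s_grid.size - 1 or not above[i]:
            return float(s_grid[i])
        j = i + 1 if i + 1 < s_grid.size else i
        if prof[i] == prof[j]:
            return float(s_grid[i])
        frac = (prof[i] - lo) / (prof[i] - prof[j])
        return float(s_grid[i] + frac * step)

    idx_above = np.flatnonzero(above)
    if idx_above.size == 0:
        edge_a = float(-s_px.min())
        edge_b = float(s_px.max())
    else:
        right = _outer_crossing(idx_above)
        # mirror for the left side
        i0 = idx_above[0]
        if i0 == 0:
            left = float(s_grid[0])
        else:
            j = i0 - 1
            frac = (prof[i0] - lo) / (prof[i0] - prof[j]) if prof[i0] != prof[j] else 0.0
            left = float(s_grid[i0] - frac * step)
        edge_a = float(-left)
        edge_b = float(right)

    gap = 0.0
    if n >= 2:
        areas = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        big = np.argsort(areas)[-2:] + 1
        intervals = []
        for lab in big:
            yy, xx = np.nonzero(labels == lab)
            ss = (xx - mid[0]) * u[0] + (yy - mid[1]) * u[1]
            intervals.append((ss.min(), ss.max()))
        intervals.sort()
        gap = max(0.0, float(intervals[1][0] - intervals[0][1]))
    return ChromatidFrame(edge_a=edge_a, edge_b=edge_b, n_components=int(n), gap=gap)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpindleTrace:
    """Per-frame spindle measurements in physical units (um, s).

    Positions are (x, y) in um; invalid frames are flagged in ``valid`` and
    carry NaN, never silently interpolated.
    """

    pole_a: np.ndarray          # (T, 2) um
    pole_b: np.ndarray          # (T, 2) um
    chrom_edge_a: np.ndarray    # (T,) um from midzone toward pole A
    chrom_edge_b: np.ndarray    # (T,) um from midzone toward pole B
    n_chrom_components: np.ndarray  # (T,) int
    chrom_gap: np.ndarray       # (T,) um between the two largest masses
    valid: np.ndarray           # (T,) bool
    pixel_size: float
    frame_interval: float
    onset_frame: int | None = None

    @property
    def n_frames(self) -> int:
        return self.pole_a.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def midzone(self) -> np.ndarray:
        return 0.5 * (self.pole_a + self.pole_b)

    @property
    def pole_distance(self) -> np.ndarray:
        return np.linalg.norm(self.pole_b - self.pole_a, axis=1)

    @property
    def chrom_separation(self) -> np.ndarray:
        """Leading-edge to leading-edge chromatid separation (um)."""
        return self.chrom_edge_a + self.chrom_edge_b


def track_movie(movie: EmbryoMovie, mask: np.ndarray | None = None,
                axis_dir=None) -> SpindleTrace:
    """Run segmentation + per-frame pole/chromatid detection on a movie."""
    if mask is None:
        mask = segment_embryo(movie)
    if axis_dir is None:
        _, axis_dir = embryo_long_axis(mask)
    T = movie.n_frames
    px = movie.pixel_size
    pole_a = np.full((T, 2), np.nan)
    pole_b = np.full((T, 2), np.nan)
    edge_a = np.full(T, np.nan)
    edge_b = np.full(T, np.nan)
    ncomp = np.zeros(T, dtype=int)
    gap = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    spindle = movie.channel("spindle")
    dna = movie.channel("dna")
    for t in range(T):
        poles = detect_poles(spindle[t], mask, axis_dir=axis_dir)
        if poles is None:
            continue
        chrom = detect_chromatids(dna[t], mask, poles)
        if chrom is None:
            continue
        pole_a[t] = poles[0] * px
        pole_b[t] = poles[1] * px
        edge_a[t] = chrom.edge_a * px
        edge_b[t] = chrom.edge_b * px
        ncomp[t] = chrom.n_components
        gap[t] = chrom.gap * px
        valid[t] = True
    trace = SpindleTrace(pole_a=pole_a, pole_b=pole_b, chrom_edge_a=edge_a,
                         chrom_edge_b=edge_b, n_chrom_components=ncomp,
                         chrom_gap=gap, valid=valid, pixel_size=px,
                         frame_interval=movie.frame_interval)
    onset = detect_anaphase_onset(trace)
    return replace(trace, onset_frame=onset)


def detect_anaphase_onset(trace: SpindleTrace, gap_min: float = 1.0,
                          persist: int = 3) -> int | None:
    """Anaphase onset: last frame before visible chromosome segregation.

    Segregation is visible when the chromatin splits into >= 2 masses whose
    axial gap exceeds ``gap_min`` um, sustained for ``persist`` consecutive
    valid frames.  Returns the frame before the first such run, or ``None``
    when segregation is never seen (or visible from the very first frame,
    in which case no pre-segregation frame exists).
    """
    ok = trace.valid & (trace.n_chrom_components >= 2) & (trace.chrom_gap > gap_min)
    T = ok.size
    for i in range(T - persist + 1):
        if ok[i:i + persist].all():
            return i - 1 if i >= 1 else None
    return None


def _rate(series: np.ndarray, trace: SpindleTrace, window: float) -> float:
    if trace.onset_frame is None:
        raise ValueError("trace has no anaphase onset")
    o = trace.onset_frame
    n_after = int(round(window / trace.frame_interval))
    j = o + n_after
    if j >= trace.n_frames:
        missing = j - trace.n_frames + 1
        raise ValueError(f"need {missing} more frames to cover {window} s after onset")
    if not (trace.valid[o] and trace.valid[j]):
        raise ValueError("onset or onset+window frame is invalid")
    return float((series[j] - series[o]) / window)


def segregation_rate(trace: SpindleTrace, window: float = 40.0) -> float:
    """Chromosome segregation rate (um/s): leading-edge separation
    displacement over the first ``window`` seconds after anaphase onset."""
    return _rate(trace.chrom_separation, trace, window)


def pole_separation_rate(trace: SpindleTrace, window: float = 40.0) -> float:
    """Spindle elongation rate (um/s) over the same window as
    :func:`segregation_rate`."""
    return _rate(trace.pole_distance, trace, window)


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kymograph:
    """Space-time image: one row per frame along the pole-pole axis."""

    image: np.ndarray            # (T, L)
    band_halfwidth: int
    pixel_size: float
    frame_interval: float
    valid_rows: np.ndarray       # (T,) bool
    axis_per_frame: np.ndarray | None = None   # (T, 2) unit axis used


def build_kymograph(movie: EmbryoMovie, trace: SpindleTrace,
                    channel: str = "spindle", band_halfwidth: int = 5,
                    length_px: int | None = None) -> Kymograph:
    """Rotation-aligned kymograph around the midzone.

    Each frame is resampled (bilinear) on a grid aligned with that frame's
    pole-pole axis, centered on the midzone; intensities are summed over
    2*band_halfwidth+1 rows.  Equivalent to rotating the frame about the
    midzone so the axis is horizontal and band-summing around the axis row.
    Invalid frames produce NaN sentinel rows.
    """
    stack = movie.channel(channel).astype(float)
    T = movie.n_frames
    L = length_px if length_px is not None else stack.shape[2]
    cols = np.arange(L) - (L - 1) / 2.0
    offs = np.arange(-band_halfwidth, band_halfwidth + 1)
    img = np.full((T, L), np.nan)
    axes = np.full((T, 2), np.nan)
    for t in range(T):
        if not trace.valid[t]:
            continue
        u = (trace.pole_b[t] - trace.pole_a[t])
        u = u / np.linalg.norm(u)
        n = np.array([-u[1], u[0]])
        c = trace.midzone[t] / movie.pixel_size  # px
        xs = c[0] + cols[None, :] * u[0] + offs[:, None] * n[0]
        ys = c[1] + cols[None, :] * u[1] + offs[:, None] * n[1]
        band = ndimage.map_coordinates(stack[t], [ys, xs], order=1, cval=0.0)
        img[t] = band.sum(axis=0)
        axes[t] = u
    return Kymograph(image=img, band_halfwidth=band_halfwidth,
                     pixel_size=movie.pixel_size,
                     frame_interval=movie.frame_interval,
                     valid_rows=trace.valid.copy(), axis_per_frame=axes)


def enhance_kymograph(k: Kymograph, block_size: int = 15,
                      offset_fraction: float = 0.05) -> np.ndarray:
    """Adaptive (local-mean) threshold + skeletonization of a kymograph.

    A pixel is foreground when it exceeds its local mean by
    ``offset_fraction`` of the kymograph's dynamic range; the offset keeps
    background noise from thresholding as speckle.
    """
    from skimage.filters import threshold_local
    from skimage.morphology import skeletonize

    img = np.nan_to_num(k.image, nan=0.0)
    if img.max() == img.min():
        return np.zeros_like(img, dtype=bool)
    if block_size % 2 == 0:
        block_size += 1
    local = threshold_local(img, block_size, method="mean",
                            offset=-offset_fraction * (img.max() - img.min()))
    binary = img > local
    return skeletonize(binary)


def pole_oscillation(trace: SpindleTrace, axis_point, axis_dir) -> np.ndarray:
    """Signed perpendicular displacement (um) of each pole to a fixed axis.

    Returns a (T, 2) array (pole A, pole B); the sign follows the left
    normal of ``axis_dir``.  By convention the axis is the embryo long axis
    (see :func:`embryo_long_axis`), but any reference axis may be supplied.
    """
    p0 = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis_dir, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("reference axis direction is degenerate")
    u = u / nrm
    n = np.array([-u[1], u[0]])
    out = np.full((trace.n_frames, 2), np.nan)
    out[:, 0] = (trace.pole_a - p0) @ n
    out[:, 1] = (trace.pole_b - p0) @ n
    out[~trace.valid] = np.nan
    return out


def trace_to_csv(trace: SpindleTrace, path: str | Path) -> None:
    """Export per-frame trace columns (um, s)."""
    rows = ["frame,time_s,poleA_x,poleA_y,poleB_x,poleB_y,"
            "pole_dist_um,chrom_sep_um,n_chrom,chrom_gap_um,valid"]
    pd_ = trace.pole_distance
    cs = trace.chrom_separation
    for t in range(trace.n_frames):
        rows.append(
            f"{t},{trace.times[t]:.3f},"
            f"{trace.pole_a[t, 0]:.4f},{trace.pole_a[t, 1]:.4f},"
            f"{trace.pole_b[t, 0]:.4f},{trace.pole_b[t, 1]:.4f},"
            f"{pd_[t]:.4f},{cs[t]:.4f},{trace.n_chrom_components[t]},"
            f"{trace.chrom_gap[t]:.4f},{int(trace.valid[t])}"
        )
    Path(path).write_text("\n".join(rows) + "\n")
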