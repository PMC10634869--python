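"""Microtubule polarity: ground truth, SHG/TP imaging model, profiles.

Polarity of a microtubule array is |n+ - n-| / (n+ + n-) over the plus-end
orientations in a focal region: 1 for a parallel array, 0 for a balanced
antiparallel array.  Second-harmonic generation (SHG) reports a coherent
signal that depends on both polarity P and microtubule density rho, while
two-photon fluorescence (TP) reads density alone.  The forward model used
here is the minimal one consistent with that:

    TP  = alpha * rho + noise
    SHG = beta * (rho * P)**2 + noise

so that P = sqrt(SHG / (kappa * TP**2)) with kappa = beta / alpha**2.  SHG
is coherent, hence quadratic in the net aligned dipole density rho*P.  The
model is declared and isolated; a different imaging law can be substituted
without touching the inversion interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoDipError
from .filaments import BoundingBox, FilamentNetwork

__all__ = [
    "PolarityProfile",
    "ShgTpPair",
    "network_polarity",
    "shg_tp_forward",
    "polarity_from_images",
    "calibrate_kappa",
    "axial_profile",
    "overlap_width",
]


@dataclass(frozen=True)
class PolarityProfile:
    """Polarity along the spindle axis; positions in um, 0 = spindle center."""

    positions: np.ndarray
    polarity: np.ndarray  # masked where undefined (NaN)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        pol = np.asarray(self.polarity, dtype=float)
        if pos.shape != pol.shape or pos.ndim != 1:
            raise ValueError("positions and polarity must be matching 1D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        valid = np.isfinite(pol)
        if np.any((pol[valid] < -1e-9) | (pol[valid] > 1 + 1e-9)):
            raise ValueError("polarity values must lie in [0, 1]")
        pos.setflags(write=False)
        pol.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "polarity", pol)


@dataclass(frozen=True)
class ShgTpPair:
    """Co-registered SHG and two-photon images with calibration kappa."""

    shg: np.ndarray
    tp: np.ndarray
    pixel_size: float  # um/px
    kappa: float | None = None

    def __post_init__(self) -> None:
        shg = np.asarray(self.shg, dtype=float)
        tp = np.asarray(self.tp, dtype=float)
        if shg.shape != tp.shape or shg.ndim != 2:
            raise ValueError("shg and tp must be 2D images of the same shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        object.__setattr__(self, "shg", shg)
        object.__setattr__(self, "tp", tp)


def network_polarity(network: FilamentNetwork, region: BoundingBox | None = None,
                     axis=(1.0, 0.0, 0.0)) -> float:
    """Polarity |n+ - n-|/(n+ + n-) of plus-end orientations in a region.

    A filament counts as plus if its plus-end direction has a positive dot
    product with ``axis``.  Filaments are selected by having any point
    inside ``region`` (whole network if ``None``).  Returns NaN (undefined)
    when the region contains no filaments.
    """
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if n == 0:
        raise ValueError("axis must be non-zero")
    ax = ax / n
    n_plus = n_minus = 0
    for f in network:
        if region is not None and not np.any(
            np.all((f.points >= region.lo) & (f.points <= region.hi), axis=1)
        ):
            continue
        if float(np.dot(f.plus_direction, ax)) > 0:
            n_plus += 1
        else:
            n_minus += 1
    total = n_plus + n_minus
    if total == 0:
        return float("nan")
    return abs(n_plus - n_minus) / total


def shg_tp_forward(density_map: np.ndarray, polarity_map: np.ndarray,
                   alpha: float, beta: float, noise_sd: float = 0.0,
                   seed: int | None = None, pixel_size: float = 1.0) -> ShgTpPair:
    """Render an SHG/TP image pair from density and polarity fields."""
    rho = np.asarray(density_map, dtype=float)
    pol = np.asarray(polarity_map, dtype=float)
    if rho.shape != pol.shape:
        raise ValueError("density and polarity maps must have the same shape")
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    rng = np.random.default_rng(seed)
    tp = alpha * rho
    shg = beta * (rho * pol) ** 2
    if noise_sd > 0:
        tp = tp + rng.normal(0.0, noise_sd, rho.shape)
        shg = shg + rng.normal(0.0, noise_sd, rho.shape)
    return ShgTpPair(shg=shg, tp=tp, pixel_size=pixel_size, kappa=beta / alpha ** 2)


def polarity_from_images(pair: ShgTpPair, tp_floor: float,
                         kappa: float | None = None) -> np.ndarray:
    """Invert the SHG/TP model to a polarity map.

    ``P = clip(sqrt(SHG / (kappa * TP^2)), 0, 1)`` where TP exceeds
    ``tp_floor``; NaN (masked) elsewhere, so pixels at the density noise
    floor never produce spurious polarity.
    """
    k = kappa if kappa is not None else pair.kappa
    if k is None or k <= 0:
        raise ValueError("kappa must be known and > 0")
    if tp_floor <= 0:
        raise ValueError("tp_floor must be > 0")
    valid = pair.tp > tp_floor
    out = np.full(pair.tp.shape, np.nan)
    with np.errstate(invalid="ignore"):
        ratio = np.clip(pair.shg[valid], 0.0, None) / (k * pair.tp[valid] ** 2)
    out[valid] = np.clip(np.sqrt(ratio), 0.0, 1.0)
    return out


def calibrate_kappa(pair: ShgTpPair, reference_region: tuple[slice, slice],
                    tp_floor: float = 0.0) -> float:
    """Estimate kappa from a reference region assumed fully parallel (P=1).

    kappa = median over the region of SHG / TP^2, computed over pixels with
    TP above ``tp_floor`` only; the median is robust to outliers.
    """
    shg = pair.shg[reference_region]
    tp = pair.tp[reference_region]
    valid = tp > tp_floor
    if not np.any(valid):
        raise ValueError("reference region contains no valid pixels")
    return float(np.median(shg[valid] / tp[valid] ** 2))


def axial_profile(polarity_map: np.ndarray, axis_start, axis_end, center,
                  bin_um: float, pixel_size: float) -> PolarityProfile:
    """Average a polarity map in slabs perpendicular to the spindle axis.

    ``axis_start``/``axis_end`` and ``center`` are (x, y) pixel coordinates;
    positions are reported in um relative to ``center``.  NaN pixels are
    excluded; empty slabs stay masked.
    """
    a = np.asarray(axis_start, dtype=float)
    b = np.asarray(axis_end, dtype=float)
    if np.allclose(a, b):
        raise ValueError("axis is degenerate")
    if bin_um <= 0:
        raise ValueError("bin must be > 0")
    u = (b - a) / np.linalg.norm(b - a)
    yy, xx = np.mgrid[0:polarity_map.shape[0], 0:polarity_map.shape[1]]
    cx, cy = np.asarray(center, dtype=float)
    s = ((xx - cx) * u[0] + (yy - cy) * u[1]) * pixel_size  # axial um
    valid = np.isfinite(polarity_map)
    if not valid.any():
        raise ValueError("polarity map is fully masked")
    smin, smax = s[valid].min(), s[valid].max()
    edges = np.arange(np.floor(smin / bin_um) * bin_um, smax + bin_um, bin_um)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.digitize(s[valid], edges) - 1
    idx = np.clip(idx, 0, len(centers) - 1)
    sums = np.bincount(idx, weights=polarity_map[valid], minlength=len(centers))
    counts = np.bincount(idx, minlength=len(centers))
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PolarityProfile(positions=centers, polarity=prof)


def overlap_width(profile: PolarityProfile, level: float = 0.5) -> float:
    """Full width (um) of the central polarity dip at fractional depth ``level``.

    The dip marks the antiparallel overlap zone.  The width is measured at
    ``minimum + level * (plateau - minimum)`` where the plateau is the mean
    of the two flank maxima, with linear interpolation between samples.
    Invariant under uniform scaling of the polarity values and translation
    of the positions.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pos = profile.positions
    pol = profile.polarity
    valid = np.isfinite(pol)
    pos, pol = pos[valid], pol[valid]
    if pos.size < 3:
        raise NoDipError("profile too short to contain a dip")
    imin = int(np.argmin(pol))
    if imin == 0 or imin == pos.size - 1:
        raise NoDipError("profile is monotone: minimum on the domain edge")
    left_plateau = float(pol[:imin].max())
    right_plateau = float(pol[imin + 1:].max())
    vmin = float(pol[imin])
    plateau = 0.5 * (left_plateau + right_plateau)
    if plateau - vmin <= 1e-12 * max(abs(plateau), 1.0):
        raise NoDipError("profile has no dip")
    thr = vmin + level * (plateau - vmin)

    def _cross(indices, reverse: bool) -> float:
        # walk outward from the minimum to the first sample above thr
        prev_i = imin
        rng = indices[::-1] if reverse else indices
        for i in rng:
            if pol[i] >= thr:
                # interpolate between prev (below) and i (above)
                p0, p1 = pol[prev_i], pol[i]
                x0, x1 = pos[prev_i], pos[i]
                if p1 == p0:
                    return float(x1)
                return float(x0 + (thr - p0) / (p1 - p0) * (x1 - x0))
            prev_i = i
        raise NoDipError("dip does not recover to the requested level on one side")

    left = _cross(np.arange(0, imin), reverse=True)
    right = _cross(np.arange(imin + 1, pos.size), reverse=False)
    return right - left
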