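"""Seeded synthetic-data generators with attached ground truth.

Every input the analysis stages consume can be generated here with known
truth, so each stage is testable without raw microscopy or tomography
data: filament networks with controllable spacing/overlap/polarity,
two-channel mitosis movies with prescribed pole and chromatid kinematics,
SHG/TP image pairs rendered through the declared imaging model, EB-comet
kymographs, FRAP curves, single-particle track tables and bait-prey
co-appearance logs.

All generators are deterministic functions of (parameters, seed); calling
one twice with the same arguments returns bit-identical data.  The noise
model throughout is Gaussian read noise plus a Gaussian approximation to
Poisson shot noise (variance proportional to signal), the standard
fluorescence camera model.

Default parameter scales follow the biology they emulate (a ~50 um
C. elegans zygote, 0.09 um/s spindle elongation and 0.13 um/s chromosome
segregation in controls, ~0.9 um mean midzone microtubule length, ~70 nm
neighbor spacing, FRAP mobile fraction ~0.34, single-molecule speeds
~0.2 um/s with ~2 um run lengths); these presets are documented
conditions, not fitted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .filaments import BoundingBox, Filament, FilamentNetwork
from .polarity import ShgTpPair, shg_tp_forward
from .tracking import EmbryoMovie, Kymograph, to_eight_bit

__all__ = [
    "SyntheticGroundTruth",
    "make_filament_network",
    "make_overlap_pairs",
    "make_random_network",
    "make_mitosis_movie",
    "make_shg_tp_pair",
    "make_comet_kymograph",
    "make_frap_curve",
    "make_track_table",
    "make_coappearance_log",
    "GENERATORS",
]


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Generator name, seed, full parameter map and per-object truth."""

    name: str
    seed: int
    parameters: dict
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating, np.bool_)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps({"name": self.name, "seed": self.seed,
                           "parameters": self.parameters, "truth": self.truth},
                          default=_default, indent=1)


# ---------------------------------------------------------------------------
# Filament networks
# ---------------------------------------------------------------------------

def _straight_filament(fid: int, center: np.ndarray, length: float,
                       direction_sign: int, point_step: float = 100.0) -> Filament:
    n_pts = max(2, int(np.ceil(length / point_step)) + 1)
    xs = np.linspace(-length / 2.0, length / 2.0, n_pts)
    if direction_sign < 0:
        xs = xs[::-1]
    pts = np.column_stack([center[0] + xs,
                           np.full(n_pts, center[1]),
                           np.full(n_pts, center[2])])
    return Filament(id=fid, points=pts, plus_end="end")


def make_filament_network(n: int = 20, length_mean: float = 880.0,
                          length_sd: float = 140.0, spacing: float = 70.0,
                          overlap_zone: tuple[float, float] = (0.0, 2000.0),
                          antiparallel_fraction: float = 0.5,
                          volume: BoundingBox | None = None,
                          jitter: float = 5.0, axial_spread: float = 0.0,
                          seed: int = 0
                          ) -> tuple[FilamentNetwork, SyntheticGroundTruth]:
    """Lattice network of near-axial filaments with an antiparallel zone.

    Filaments run along +/- x on a jittered (y, z) lattice with the given
    nearest-neighbor ``spacing`` (nm).  Axial centers are spread uniformly
    over ``axial_spread`` nm; filaments whose center falls inside
    ``overlap_zone = (center, half_width)`` are assigned the minus
    orientation with probability mass ``antiparallel_fraction`` (exact
    count, chosen by seeded permutation); filaments outside the zone are
    all plus.  Truth records every orientation.
    """
    if spacing <= 0 or length_mean <= 0:
        raise ValueError("spacing and lengths must be > 0")
    rng = np.random.default_rng(seed)
    k = int(np.ceil(np.sqrt(n)))
    if volume is not None:
        ext = volume.extent
        if (k - 1) * spacing > ext[1] or (k - 1) * spacing > ext[2]:
            raise ValueError(
                f"volume too small for {n} filaments at {spacing} nm spacing")
    zone_center, zone_half = overlap_zone

    lengths = np.clip(rng.normal(length_mean, length_sd, n), 150.0, None)
    x_centers = (zone_center + rng.uniform(-axial_spread / 2, axial_spread / 2, n)
                 if axial_spread > 0 else np.full(n, float(zone_center)))
    in_zone = np.abs(x_centers - zone_center) <= zone_half
    signs = np.ones(n, dtype=int)
    zone_idx = np.flatnonzero(in_zone)
    n_minus = int(round(antiparallel_fraction * zone_idx.size))
    minus_idx = rng.permutation(zone_idx)[:n_minus]
    signs[minus_idx] = -1

    filaments = []
    for i in range(n):
        gy, gz = i % k, i // k
        center = np.array([
            x_centers[i],
            gy * spacing + rng.uniform(-jitter, jitter),
            gz * spacing + rng.uniform(-jitter, jitter),
        ])
        filaments.append(_straight_filament(i, center, float(lengths[i]),
                                            int(signs[i])))
    net = FilamentNetwork(filaments=tuple(filaments), volume=volume,
                          label="synthetic-lattice")
    truth = SyntheticGroundTruth(
        name="filament_network", seed=seed,
        parameters=dict(n=n, length_mean=length_mean, length_sd=length_sd,
                        spacing=spacing, overlap_zone=list(overlap_zone),
                        antiparallel_fraction=antiparallel_fraction,
                        jitter=jitter, axial_spread=axial_spread),
        truth=dict(directions=signs.tolist(), in_zone=in_zone.tolist(),
                   lengths_nm=lengths.tolist(), x_centers=x_centers.tolist(),
                   n_minus=n_minus),
    )
    return net, truth


def make_overlap_pairs(n_pairs: int = 5, spacing: float = 50.0,
                       overlap_length: float = 500.0,
                       pair_pitch: float | None = None,
                       antiparallel: bool = True, point_step: float = 100.0,
                       seed: int = 0
                       ) -> tuple[FilamentNetwork, SyntheticGroundTruth]:
    """Isolated antiparallel pairs with full designed overlap.

    Each pair is two coaxial filaments spanning the same axial interval of
    length ``overlap_length`` nm at lateral distance ``spacing`` nm, so the
    designed interaction length equals the filament length and the designed
    minimum distance equals the spacing.  Pairs are separated by
    ``pair_pitch`` (default: well beyond the 100 nm interaction threshold)
    so they do not interact with each other.
    """
    if spacing <= 0 or overlap_length <= 0:
        raise ValueError("spacing and overlap_length must be > 0")
    pitch = pair_pitch if pair_pitch is not None else max(400.0, 4.0 * spacing)
    filaments = []
    for p in range(n_pairs):
        base = np.array([0.0, p * pitch, 0.0])
        filaments.append(_straight_filament(2 * p, base, overlap_length, +1,
                                            point_step))
        filaments.append(_straight_filament(
            2 * p + 1, base + np.array([0.0, 0.0, spacing]), overlap_length,
            -1 if antiparallel else +1, point_step))
    net = FilamentNetwork(filaments=tuple(filaments), label="synthetic-pairs")
    truth = SyntheticGroundTruth(
        name="overlap_pairs", seed=seed,
        parameters=dict(n_pairs=n_pairs, spacing=spacing,
                        overlap_length=overlap_length, pair_pitch=pitch,
                        antiparallel=antiparallel),
        truth=dict(spacing_nm=spacing, overlap_length_nm=overlap_length),
    )
    return net, truth


def make_random_network(n: int = 12, box_nm=(1500.0, 1000.0, 1000.0),
                        length_mean: float = 700.0, length_sd: float = 150.0,
                        direction_sd_deg: float = 12.0, n_points: int = 8,
                        waviness: float = 4.0, seed: int = 0
                        ) -> tuple[FilamentNetwork, SyntheticGroundTruth]:
    """Random near-parallel wavy polylines, midzone-like geometry.

    Start points are uniform in the box, directions scatter around +x with
    ``direction_sd_deg`` of angular jitter, and each polyline carries small
    transverse waviness; about half the filaments are laid antiparallel.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box_nm, dtype=float)
    filaments = []
    signs = []
    for i in range(n):
        length = float(np.clip(rng.normal(length_mean, length_sd), 200.0, None))
        start = rng.uniform(0.1, 0.9, 3) * box
        theta = np.radians(rng.normal(0.0, direction_sd_deg))
        phi = rng.uniform(0, 2 * np.pi)
        sign = 1 if rng.random() < 0.5 else -1
        d = np.array([np.cos(theta),
                      np.sin(theta) * np.cos(phi),
                      np.sin(theta) * np.sin(phi)]) * sign
        ts = np.linspace(0.0, length, n_points)
        pts = start[None, :] + ts[:, None] * d[None, :]
        wob = rng.normal(0.0, waviness, (n_points, 3))
        wob[0] = wob[-1] = 0.0
        filaments.append(Filament(id=i, points=pts + wob, plus_end="end"))
        signs.append(sign)
    net = FilamentNetwork(filaments=tuple(filaments), label="synthetic-random")
    truth = SyntheticGroundTruth(
        name="random_network", seed=seed,
        parameters=dict(n=n, box_nm=list(box), length_mean=length_mean,
                        length_sd=length_sd, direction_sd_deg=direction_sd_deg,
                        n_points=n_points, waviness=waviness),
        truth=dict(directions=signs),
    )
    return net, truth


# ---------------------------------------------------------------------------
# Mitosis movies
# ---------------------------------------------------------------------------

def _coverage_1d(coords: np.ndarray, lo: float, hi: float, px: float) -> np.ndarray:
    """Fraction of each pixel (centered at coords, width px) inside [lo, hi]."""
    return np.clip((np.minimum(hi, coords + px / 2)
                    - np.maximum(lo, coords - px / 2)) / px, 0.0, 1.0)


def make_mitosis_movie(T: int = 80, dt: float = 1.0, px: float = 0.25,
                       shape: tuple[int, int] = (128, 224),
                       pole_distance0: float = 14.0,
                       elongation_rate: float = 0.09,
                       chrom_edge0: float = 1.5,
                       segregation_rate: float = 0.13,
                       onset_t: float = 30.0,
                       mass_width: float = 0.9, mass_height: float = 3.0,
                       oscillation_amplitude: float = 0.2,
                       oscillation_period: float = 30.0,
                       pole_sigma: float = 0.75, pole_amplitude: float = 220.0,
                       embryo_amplitude: float = 25.0,
                       chrom_amplitude: float = 200.0,
                       embryo_semi_axes: tuple[float, float] = (24.0, 11.0),
                       embryo_offsets=((0.0, 0.0),),
                       psf_sd: float = 1.0, noise_sd: float = 2.0,
                       shot_gain: float = 0.02, seed: int = 0
                       ) -> tuple[EmbryoMovie, SyntheticGroundTruth]:
    """Two-channel embryo movie with prescribed anaphase kinematics.

    Spindle channel: a dim embryo ellipse plus two Gaussian pole blobs whose
    distance follows ``pole_distance0 + elongation_rate * max(0, t - onset_t)``
    with optional anti-phase transverse oscillation.  DNA channel: a single
    compact chromatin plate spanning the region between the future leading
    edges before onset; from ``onset_t`` on, two masses of axial width
    ``mass_width`` whose outer (leading) edges separate continuously at
    ``segregation_rate``, opening an immediately visible inner gap of
    ``2 * (chrom_edge0 - mass_width)`` um.  All lengths um, times s.

    Truth records per-frame pole positions, leading-edge positions, the
    kinematic rates, and the onset frame under the last-frame-before-visible-
    segregation convention.
    """
    if mass_width >= chrom_edge0:
        raise ValueError("mass_width must be smaller than chrom_edge0 "
                         "(the split must open a visible gap)")
    rng = np.random.default_rng(seed)
    Y, X = shape
    cx, cy = (X - 1) / 2.0 * px, (Y - 1) / 2.0 * px
    xs = np.arange(X) * px
    ys = np.arange(Y) * px
    XX, YY = np.meshgrid(xs, ys)

    embryo = np.zeros((Y, X))
    for ox, oy in embryo_offsets:
        ex, ey = embryo_semi_axes
        embryo = np.maximum(
            embryo,
            embryo_amplitude * (((XX - cx - ox) / ex) ** 2
                                + ((YY - cy - oy) / ey) ** 2 <= 1.0))

    times = np.arange(T) * dt
    post = np.maximum(0.0, times - onset_t)
    D = pole_distance0 + elongation_rate * post
    E = chrom_edge0 + 0.5 * segregation_rate * post
    osc = oscillation_amplitude * np.sin(2 * np.pi * times / oscillation_period)

    pole_a = np.column_stack([cx - D / 2, cy + osc])
    pole_b = np.column_stack([cx + D / 2, cy - osc])
    margin = 3 * pole_sigma
    for p in (pole_a, pole_b):
        if (np.any(p[:, 0] < margin) or np.any(p[:, 0] > xs[-1] - margin)
                or np.any(p[:, 1] < margin) or np.any(p[:, 1] > ys[-1] - margin)):
            raise ValueError("pole trajectory leaves the field of view")

    separated = times >= onset_t
    raw = np.zeros((T, 2, Y, X))
    ylo, yhi = cy - mass_height / 2, cy + mass_height / 2
    cov_y = _coverage_1d(ys, ylo, yhi, px)
    for t in range(T):
        sp = embryo.copy()
        for p in (pole_a[t], pole_b[t]):
            sp += pole_amplitude * np.exp(
                -((XX - p[0]) ** 2 + (YY - p[1]) ** 2) / (2 * pole_sigma ** 2))
        if separated[t]:
            cov_x = (_coverage_1d(xs, cx - E[t], cx - E[t] + mass_width, px)
                     + _coverage_1d(xs, cx + E[t] - mass_width, cx + E[t], px))
        else:
            cov_x = _coverage_1d(xs, cx - E[t], cx + E[t], px)
        dna = 0.4 * embryo + chrom_amplitude * np.outer(cov_y, cov_x)
        sp = ndimage.gaussian_filter(sp, psf_sd)
        dna = ndimage.gaussian_filter(dna, psf_sd)
        for c, img in enumerate((sp, dna)):
            sdev = np.sqrt(noise_sd ** 2 + shot_gain * img)
            raw[t, c] = np.clip(img + rng.normal(0.0, 1.0, img.shape) * sdev,
                                0.0, None)

    movie = to_eight_bit(raw, channels={"spindle": 0, "dna": 1},
                         pixel_size=px, frame_interval=dt)
    i0 = int(np.argmax(separated)) if separated.any() else None
    onset_frame = (i0 - 1) if (i0 is not None and i0 >= 1) else None
    truth = SyntheticGroundTruth(
        name="mitosis_movie", seed=seed,
        parameters=dict(T=T, dt=dt, px=px, shape=list(shape),
                        pole_distance0=pole_distance0,
                        elongation_rate=elongation_rate,
                        chrom_edge0=chrom_edge0,
                        segregation_rate=segregation_rate, onset_t=onset_t,
                        mass_width=mass_width, mass_height=mass_height,
                        oscillation_amplitude=oscillation_amplitude,
                        oscillation_period=oscillation_period,
                        pole_sigma=pole_sigma, psf_sd=psf_sd,
                        noise_sd=noise_sd, shot_gain=shot_gain),
        truth=dict(pole_a=pole_a, pole_b=pole_b,
                   pole_distance=D, chrom_edge=E, chrom_separation=2 * E,
                   onset_frame=onset_frame,
                   segregation_rate=segregation_rate,
                   elongation_rate=elongation_rate,
                   oscillation=osc,
                   embryo_center=(cx, cy), embryo_semi_axes=embryo_semi_axes),
    )
    return movie, truth


# ---------------------------------------------------------------------------
# SHG / TP pairs
# ---------------------------------------------------------------------------

def make_shg_tp_pair(shape: tuple[int, int] = (96, 192), px: float = 0.2,
                     density_peak: float = 100.0, sigma_axial: float = 5.0,
                     sigma_lateral: float = 1.5, dip_width: float = 4.0,
                     dip_depth: float = 1.0, alpha: float = 1.0,
                     beta: float = 0.01, noise_sd: float = 0.0, seed: int = 0
                     ) -> tuple[ShgTpPair, SyntheticGroundTruth]:
    """SHG/TP image pair of a spindle-like density with a polarity dip.

    Density: anisotropic Gaussian ridge (um scales).  Polarity: 1 on the
    flanks with a central Gaussian dip of FWHM ``dip_width`` um and depth
    ``dip_depth`` marking the antiparallel overlap zone.
    """
    Y, X = shape
    cx, cy = (X - 1) / 2.0 * px, (Y - 1) / 2.0 * px
    xs = np.arange(X) * px - cx
    ys = np.arange(Y) * px - cy
    XXg, YYg = np.meshgrid(xs, ys)
    rho = density_peak * np.exp(-XXg ** 2 / (2 * sigma_axial ** 2)
                                - YYg ** 2 / (2 * sigma_lateral ** 2))
    sigma_dip = dip_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pol = 1.0 - dip_depth * np.exp(-XXg ** 2 / (2 * sigma_dip ** 2))
    pair = shg_tp_forward(rho, pol, alpha=alpha, beta=beta,
                          noise_sd=noise_sd, seed=seed, pixel_size=px)
    truth = SyntheticGroundTruth(
        name="shg_tp_pair", seed=seed,
        parameters=dict(shape=list(shape), px=px, density_peak=density_peak,
                        sigma_axial=sigma_axial, sigma_lateral=sigma_lateral,
                        dip_width=dip_width, dip_depth=dip_depth,
                        alpha=alpha, beta=beta, noise_sd=noise_sd),
        truth=dict(density=rho, polarity=pol, kappa=beta / alpha ** 2,
                   dip_width_um=dip_width, center_px=((X - 1) / 2.0, (Y - 1) / 2.0)),
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Comet kymographs, FRAP, tracks, co-appearance
# ---------------------------------------------------------------------------

def make_comet_kymograph(n_comets: int = 7, shape: tuple[int, int] = (100, 45),
                         px: float = 0.1, dt: float = 1.0,
                         comet_speed: float = 0.5, comet_duration: float = 4.0,
                         min_separation_px: int = 5, amplitude: float = 100.0,
                         background: float = 10.0, noise_sd: float = 0.0,
                         seed: int = 0
                         ) -> tuple[Kymograph, SyntheticGroundTruth]:
    """Kymograph with diagonal EB-comet trajectories at known count.

    Comets appear at seeded (time, position) origins with Chebyshev
    separation of at least ``min_separation_px`` between trajectory
    bounding boxes, and trace lines of slope ``comet_speed`` (um/s) for
    ``comet_duration`` s.  The default canvas (100 rows at 1 s, 45 columns
    at 0.1 um) matches the standard counting window (100 s, 4.5 um) so the
    designed count is the count within the analyzed segment.  Raises when
    the requested count cannot be placed at the requested separation.
    """
    from skimage.draw import line as _line

    rng = np.random.default_rng(seed)
    T, L = shape
    img = np.full((T, L), background, dtype=float)
    slope_px = comet_speed * dt / px
    n_rows = max(2, int(round(comet_duration / dt)))
    boxes: list[tuple[float, float, float, float]] = []
    placed = []
    attempts = 0
    while len(placed) < n_comets:
        attempts += 1
        if attempts > 2000:
            raise ValueError(
                f"cannot place {n_comets} comets at separation "
                f"{min_separation_px} px in a {shape} kymograph")
        t0 = rng.integers(0, T - n_rows)
        x0 = rng.integers(2, max(3, L - int(slope_px * n_rows) - 2))
        t1 = t0 + n_rows - 1
        x1 = min(L - 1, int(round(x0 + slope_px * (n_rows - 1))))
        box = (t0, t1, min(x0, x1), max(x0, x1))
        ok = all(not (box[0] - min_separation_px <= b[1]
                      and b[0] - min_separation_px <= box[1]
                      and box[2] - min_separation_px <= b[3]
                      and b[2] - min_separation_px <= box[3])
                 for b in boxes)
        if not ok:
            continue
        boxes.append(box)
        rr, cc = _line(int(t0), int(x0), int(t1), int(x1))
        img[rr, cc] = background + amplitude
        placed.append((int(t0), int(x0)))
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    kymo = Kymograph(image=img, band_halfwidth=0, pixel_size=px,
                     frame_interval=dt, valid_rows=np.ones(T, dtype=bool))
    truth = SyntheticGroundTruth(
        name="comet_kymograph", seed=seed,
        parameters=dict(n_comets=n_comets, shape=list(shape), px=px, dt=dt,
                        comet_speed=comet_speed, comet_duration=comet_duration,
                        min_separation_px=min_separation_px,
                        amplitude=amplitude, background=background,
                        noise_sd=noise_sd),
        truth=dict(n_comets=n_comets, origins=placed),
    )
    return kymo, truth


def make_frap_curve(fraction: float = 0.34, k: float = 0.05,
                    prebleach: float = 1.0, bleach_level: float = 0.3,
                    dt: float = 2.0, duration: float = 120.0,
                    noise_sd: float = 0.0, seed: int = 0):
    """FRAP recovery curve from the single-exponential model.

    ``F(t) = F0 + (Finf - F0)(1 - exp(-k t))`` with
    ``Finf = F0 + fraction * (prebleach - F0)``.
    """
    from .dynamics import FrapCurve

    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    f0 = bleach_level
    finf = f0 + fraction * (prebleach - f0)
    y = f0 + (finf - f0) * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    curve = FrapCurve(times=t, intensities=y, prebleach=prebleach)
    truth = SyntheticGroundTruth(
        name="frap_curve", seed=seed,
        parameters=dict(fraction=fraction, k=k, prebleach=prebleach,
                        bleach_level=bleach_level, dt=dt, duration=duration,
                        noise_sd=noise_sd),
        truth=dict(fraction=fraction, k=k, f0=f0, finf=finf),
    )
    return curve, truth


def make_track_table(n_tracks: int = 200, mean_speed: float = 0.2,
                     speed_sd: float = 0.03, run_length_mean: float = 2.0,
                     dt: float = 0.25, loc_noise: float = 0.005,
                     intensity_mean: float = 100.0, intensity_sd: float = 15.0,
                     seed: int = 0) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Processive single-particle tracks with independent brightness.

    Speeds are truncated-normal around ``mean_speed`` um/s, run lengths
    exponential with mean ``run_length_mean`` um, directions uniform;
    per-track brightness is drawn independently of speed so the
    brightness-speed correlation is zero by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    speeds, runs = [], []
    for tid in range(n_tracks):
        s = float(np.clip(rng.normal(mean_speed, speed_sd), 0.02, None))
        L = float(rng.exponential(run_length_mean))
        n_frames = max(2, int(round(L / s / dt)) + 1)
        theta = rng.uniform(0, 2 * np.pi)
        d = np.array([np.cos(theta), np.sin(theta)])
        origin = rng.uniform(0, 50, 2)
        brightness = float(np.clip(rng.normal(intensity_mean, intensity_sd),
                                   5.0, None))
        tt = np.arange(n_frames) * dt
        xy = origin[None, :] + (s * tt)[:, None] * d[None, :]
        xy = xy + rng.normal(0.0, loc_noise, xy.shape)
        inten = brightness + rng.normal(0.0, 2.0, n_frames)
        for j in range(n_frames):
            rows.append((tid, j, tt[j], xy[j, 0], xy[j, 1], inten[j]))
        speeds.append(s)
        runs.append(float(np.linalg.norm(xy[-1] - xy[0])))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_s",
                                     "x_um", "y_um", "intensity"])
    truth = SyntheticGroundTruth(
        name="track_table", seed=seed,
        parameters=dict(n_tracks=n_tracks, mean_speed=mean_speed,
                        speed_sd=speed_sd, run_length_mean=run_length_mean,
                        dt=dt, loc_noise=loc_noise,
                        intensity_mean=intensity_mean,
                        intensity_sd=intensity_sd),
        truth=dict(speeds=speeds, run_lengths=runs),
    )
    return df, truth


def make_coappearance_log(n_bait: int = 20000, fraction: float = 0.0005,
                          seed: int = 0
                          ) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Bait-event log with Bernoulli prey co-appearance at a true fraction."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    has_prey = rng.random(n_bait) < fraction
    df = pd.DataFrame({"bait_event_id": np.arange(n_bait),
                       "has_prey": has_prey})
    truth = SyntheticGroundTruth(
        name="coappearance_log", seed=seed,
        parameters=dict(n_bait=n_bait, fraction=fraction),
        truth=dict(fraction=fraction, n_coappear=int(has_prey.sum())),
    )
    return df, truth


GENERATORS = {
    "filament-network": make_filament_network,
    "overlap-pairs": make_overlap_pairs,
    "random-network": make_random_network,
    "mitosis-movie": make_mitosis_movie,
    "shg-tp-pair": make_shg_tp_pair,
    "comet-kymograph": make_comet_kymograph,
    "frap-curve": make_frap_curve,
    "track-table": make_track_table,
    "coappearance-log": make_coappearance_log,
}
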