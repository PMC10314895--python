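"""Synthetic high-content microscopy fields with planted cilia.

Renders a four-channel field (DNA, ARL13B, gamma-tubulin, signal)
imitating the stains used to quantify ciliary GLI trafficking: nuclei
as filled ellipses in the DNA channel, cilia as curved rods (quadratic
Bezier centerlines with Gaussian cross-section) in the ARL13B channel,
one gamma-tubulin punctum at each cilium base, and a signal channel
whose distal-half share of each cilium's deposited intensity equals the
planted ``tip_fraction``.  Constant background and additive Gaussian
noise are applied last.

These fields are deliberately idealized fixtures: no out-of-focus
light, no flatfield gradients, no cytoplasmic signal — see the methods
note for what that implies about the recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..hcquant import ChannelStack

__all__ = [
    "SimImageConfig",
    "CiliumTruth",
    "NucleusTruth",
    "PlacementError",
    "simulate_microscopy_field",
]


class PlacementError(RuntimeError):
    """Field too small to place the requested objects without overlap."""


@dataclass(frozen=True)
class SimImageConfig:
    shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 20
    n_cilia: int = 15
    cilium_length_range: tuple[float, float] = (40.0, 80.0)
    cilium_width: float = 1.6          # Gaussian cross-section sigma, px
    curvature: float = 0.12            # perpendicular control-point offset / chord
    nucleus_radius_range: tuple[float, float] = (12.0, 18.0)
    nucleus_amplitude: float = 200.0
    arl13b_density: float = 200.0      # ARL13B intensity per px of arc length
    signal_total: float = 20000.0      # signal intensity deposited per cilium
    gtub_amplitude: float = 400.0
    gtub_sigma: float = 1.5
    tip_fraction: float | tuple[float, ...] = 0.7
    tip_fraction_range: tuple[float, float] | None = None
    noise_sd: float = 2.0
    background: float = 100.0
    margin: int = 12
    seed: int = 0

    def __post_init__(self):
        tf = self.tip_fraction
        vals = tf if isinstance(tf, tuple) else (tf,)
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("tip_fraction must be in [0, 1]")
        if isinstance(tf, tuple) and len(tf) != self.n_cilia:
            raise ValueError("per-cilium tip_fraction must have length n_cilia")
        if self.noise_sd < 0 or self.background < 0:
            raise ValueError("noise_sd and background must be >= 0")


@dataclass
class NucleusTruth:
    center: tuple[float, float]
    axes: tuple[float, float]
    angle: float


@dataclass
class CiliumTruth:
    base: tuple[float, float]
    tip: tuple[float, float]
    tip_fraction: float
    total_signal: float
    length: float


def _splat(image: np.ndarray, r: float, c: float, amplitude: float, sigma: float) -> None:
    """Add a normalized Gaussian of integrated intensity ``amplitude``."""
    rad = int(np.ceil(4 * sigma))
    r0, r1 = int(np.floor(r)) - rad, int(np.floor(r)) + rad + 1
    c0, c1 = int(np.floor(c)) - rad, int(np.floor(c)) + rad + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, image.shape[0]), min(c1, image.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rows = np.arange(r0c, r1c)[:, None]
    cols = np.arange(c0c, c1c)[None, :]
    kernel = np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sigma**2))
    kernel *= amplitude / (2 * np.pi * sigma**2)
    image[r0c:r1c, c0c:c1c] += kernel


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _resample_equal_arc(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at equal arc-length steps; returns (points, s)."""
    seg = np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    s_new = np.arange(0.0, total + step / 2, step)
    rows = np.interp(s_new, s, points[:, 0])
    cols = np.interp(s_new, s, points[:, 1])
    return np.stack([rows, cols], axis=1), s_new


def simulate_microscopy_field(
    config: SimImageConfig = SimImageConfig(),
) -> tuple[ChannelStack, list[CiliumTruth], list[NucleusTruth]]:
    """Render a field: (ChannelStack, cilium truths, nucleus truths)."""
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    m = config.margin
    max_len = config.cilium_length_range[1]
    if h - 2 * m < 2 * config.nucleus_radius_range[1] or w - 2 * m < max_len / 2:
        raise PlacementError("field too small for requested objects")

    dna = np.zeros((h, w))
    arl = np.zeros((h, w))
    gtub = np.zeros((h, w))
    signal = np.zeros((h, w))

    # nuclei: rejection-sampled non-overlapping ellipse centers
    nuclei: list[NucleusTruth] = []
    centers: list[np.ndarray] = []
    r_max = config.nucleus_radius_range[1]
    min_sep = 2 * r_max + 4
    tries = 0
    while len(nuclei) < config.n_nuclei:
        tries += 1
        if tries > 400 * max(config.n_nuclei, 1):
            raise PlacementError("could not place all nuclei without overlap")
        center = rng.uniform([m + r_max, m + r_max], [h - m - r_max, w - m - r_max])
        if centers and np.min(np.sqrt(((np.array(centers) - center) ** 2).sum(1))) < min_sep:
            continue
        a, b = rng.uniform(*config.nucleus_radius_range, size=2)
        angle = rng.uniform(0, np.pi)
        centers.append(center)
        nuclei.append(NucleusTruth(tuple(center), (a, b), angle))
        rows, cols = np.mgrid[0:h, 0:w]
        dr, dc = rows - center[0], cols - center[1]
        u = dr * np.cos(angle) + dc * np.sin(angle)
        v = -dr * np.sin(angle) + dc * np.cos(angle)
        dna[(u / a) ** 2 + (v / b) ** 2 <= 1.0] += config.nucleus_amplitude

    # planted per-cilium tip fractions
    if config.tip_fraction_range is not None:
        fractions = rng.uniform(*config.tip_fraction_range, size=config.n_cilia)
    elif isinstance(config.tip_fraction, tuple):
        fractions = np.asarray(config.tip_fraction, dtype=float)
    else:
        fractions = np.full(config.n_cilia, float(config.tip_fraction))

    # cilia: curved rods, rejection-sampled to stay separated
    cilia: list[CiliumTruth] = []
    occupied: list[np.ndarray] = []   # coarse centerline samples of accepted cilia
    clearance = 8.0 * config.cilium_width + 4.0
    tries = 0
    k = 0
    while k < config.n_cilia:
        tries += 1
        if tries > 400 * max(config.n_cilia, 1):
            raise PlacementError("could not place all cilia without overlap")
        chord = rng.uniform(*config.cilium_length_range)
        theta = rng.uniform(0, 2 * np.pi)
        base = rng.uniform([m, m], [h - m, w - m])
        tip = base + chord * np.array([np.sin(theta), np.cos(theta)])
        if not (m <= tip[0] < h - m and m <= tip[1] < w - m):
            continue
        mid = (base + tip) / 2
        perp = np.array([-np.cos(theta), np.sin(theta)])
        ctrl = mid + rng.uniform(-1, 1) * config.curvature * chord * perp
        dense = _bezier(base, ctrl, tip, max(int(4 * chord), 32))
        coarse = dense[:: max(len(dense) // 20, 1)]
        ok = True
        for other in occupied:
            d = np.sqrt(((coarse[:, None, :] - other[None, :, :]) ** 2).sum(-1))
            if d.min() < clearance:
                ok = False
                break
        if not ok:
            continue
        pts, s = _resample_equal_arc(dense, 0.25)
        length = s[-1]
        ds = np.gradient(s)
        tf = float(fractions[k])
        # piecewise-constant linear density: proximal half carries (1 - tf)
        # of the signal, distal half carries tf
        density = np.where(s < length / 2, 2 * (1 - tf) / length, 2 * tf / length)
        sig_weights = config.signal_total * density * ds
        for (r, c), wgt, dstep in zip(pts, sig_weights, ds):
            _splat(arl, r, c, config.arl13b_density * dstep, config.cilium_width)
            if wgt > 0:
                _splat(signal, r, c, wgt, config.cilium_width)
        _splat(gtub, base[0], base[1], config.gtub_amplitude, config.gtub_sigma)
        occupied.append(coarse)
        cilia.append(CiliumTruth(tuple(base), tuple(tip), tf,
                                 config.signal_total, float(length)))
        k += 1

    channels = {}
    for role, img in [("dna", dna), ("arl13b", arl), ("gtub", gtub), ("signal", signal)]:
        noisy = img + config.background
        if config.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.noise_sd, size=img.shape)
        channels[role] = np.clip(noisy, 0.0, None)
    return ChannelStack(channels), cilia, nuclei
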