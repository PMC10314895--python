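"""High-content image quantification.

Quantifies two read-outs from multi-channel fluorescence fields of
ciliated fibroblasts: per-nucleus signal intensity (DNA stain mask) and
the base-to-tip distribution of a signal along primary cilia (ARL13B
ciliary mask, gamma-tubulin centriole marker for orientation).

The ciliary read-out follows the tip-accumulation convention for GLI
transcription factors: each cilium's skeleton is divided into 10 equal
arc-length bins from base to tip, every mask pixel is assigned to the
bin of its nearest skeleton point, and the tip signal is the summed
fluorescence of the final five bins regardless of cilium length.

Coordinates are pixel-centered, row-major (row, col), 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage
from skimage import feature, filters, measure, morphology
import tifffile

__all__ = [
    "ChannelStack",
    "NucleusMeasurement",
    "CiliumMeasurement",
    "read_channel_stack",
    "write_channel_stack",
    "subtract_background",
    "segment_nuclei",
    "nuclear_intensity",
    "segment_cilia",
    "detect_puncta",
    "orient_cilium",
    "bin_cilium",
    "tip_signal",
    "measure_cilia",
]


@dataclass
class ChannelStack:
    """2D images keyed by channel role (``dna``, ``arl13b``, ``gtub``, ...)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self):
        shapes = {role: img.shape for role, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> list[str]:
        return list(self.channels)


def write_channel_stack(stack: ChannelStack, tiff_path, yaml_path) -> None:
    """Multi-page TIFF (one page per channel) + YAML sidecar with roles."""
    roles = stack.roles
    pages = np.stack([stack[r].astype(np.float32) for r in roles])
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    meta = {"channels": {i: r for i, r in enumerate(roles)}}
    if stack.pixel_size_um is not None:
        meta["pixel_size_um"] = stack.pixel_size_um
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh)


def read_channel_stack(tiff_path, yaml_path) -> ChannelStack:
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    channels = {role: np.asarray(pages[int(i)], dtype=float)
                for i, role in meta["channels"].items()}
    return ChannelStack(channels, pixel_size_um=meta.get("pixel_size_um"))


@dataclass
class NucleusMeasurement:
    label: int
    area: int
    mean_intensity: float
    integrated_intensity: float


@dataclass
class CiliumMeasurement:
    """An oriented cilium with its binned signal profile."""

    label: int
    path: np.ndarray          # (n, 2) skeleton pixels, base -> tip
    length: float             # arc length, px
    bin_sums: np.ndarray      # (n_bins,) summed signal intensity
    tip_sum: float
    tip_fraction: float
    status: str = "ok"        # ok | unoriented | too_short

    @property
    def base(self) -> np.ndarray:
        return self.path[0]

    @property
    def tip(self) -> np.ndarray:
        return self.path[-1]


# ---------------------------------------------------------------------------
# pixel operations

def subtract_background(image: np.ndarray, radius: int) -> np.ndarray:
    """Local background subtraction via grayscale opening (rolling-ball
    equivalent) with a disk of the given radius; negatives clipped to 0.

    The radius must exceed the half-width of the largest foreground
    object, otherwise the object itself is treated as background.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    background = morphology.opening(image, morphology.disk(radius))
    return np.clip(image - background, 0.0, None)


def segment_nuclei(
    dna_channel: np.ndarray,
    threshold: float | None = None,
    min_area: int = 50,
    watershed_split: bool = False,
) -> np.ndarray:
    """Label image of nuclei from a background-subtracted DNA channel.

    Otsu threshold by default (or a fixed one), hole filling, connected
    components, minimum-area filter.  ``watershed_split`` separates
    touching nuclei with a distance-transform watershed.
    """
    if threshold is None:
        if np.all(dna_channel == dna_channel.flat[0]):
            return np.zeros(dna_channel.shape, dtype=np.int32)
        threshold = filters.threshold_otsu(dna_channel)
    mask = dna_channel > threshold
    mask = ndimage.binary_fill_holes(mask)
    mask = _drop_small(mask, min_area)
    if not mask.any():
        return np.zeros(dna_channel.shape, dtype=np.int32)
    if watershed_split:
        from skimage.segmentation import watershed

        distance = ndimage.distance_transform_edt(mask)
        coords = feature.peak_local_max(
            distance, labels=mask, min_distance=int(np.sqrt(min_area) / 2) + 1
        )
        seeds = np.zeros(mask.shape, dtype=np.int32)
        seeds[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-distance, seeds, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    return labels.astype(np.int32)


def nuclear_intensity(labels: np.ndarray, channel: np.ndarray) -> list[NucleusMeasurement]:
    """Per-label mean and integrated intensity of ``channel``."""
    if labels.shape != channel.shape:
        raise ValueError("labels and channel must have the same shape")
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        integrated = float(channel[mask].sum())
        out.append(NucleusMeasurement(int(lab), area, integrated / area, integrated))
    return out


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.concatenate([[False], areas >= min_area])
    return keep[labels]


def _robust_floor(image: np.ndarray, k: float = 6.0) -> float:
    """Noise floor estimate: median + k * 1.4826 * MAD."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + k * 1.4826 * mad


# ---------------------------------------------------------------------------
# cilium segmentation and skeleton handling

def _skeleton_path(skeleton: np.ndarray) -> np.ndarray | None:
    """Longest endpoint-to-endpoint path through a skeleton (tree diameter).

    Returns ordered (n, 2) pixel coordinates, or None for degenerate
    skeletons (cycles with no endpoints, single pixels).
    """
    pts = np.argwhere(skeleton)
    if len(pts) < 2:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    neighbors: list[list[int]] = [[] for _ in pts]
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]
    for i, (r, c) in enumerate(pts):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: -1}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path_idx = [b]
    while parent[path_idx[-1]] != -1:
        path_idx.append(parent[path_idx[-1]])
    return pts[path_idx[::-1]]


def _arc_length(path: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each path point (starts at 0)."""
    steps = np.sqrt((np.diff(path.astype(float), axis=0) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


def segment_cilia(
    arl13b_channel: np.ndarray,
    min_length: float = 10.0,
    max_width: float = 8.0,
    min_elongation: float = 2.5,
    threshold: float | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cilium masks and ordered skeleton paths from the ARL13B channel.

    The default threshold is Otsu's, floored at a robust noise estimate
    (median + 6 MAD) so that a field dominated by background cannot
    fragment into spurious components; then connected components and
    rod-shape filtering: skeleton length in bounds, mean width
    (area / length) below ``max_width``, and elongation (length /
    width) above ``min_elongation``.  Returns a list of (boolean mask,
    (n, 2) path) pairs; the path orientation is arbitrary until
    :func:`orient_cilium`.
    """
    if threshold is None:
        if np.all(arl13b_channel == arl13b_channel.flat[0]):
            return []
        threshold = max(filters.threshold_otsu(arl13b_channel),
                        _robust_floor(arl13b_channel))
        if arl13b_channel.max() <= threshold:
            return []
    mask = arl13b_channel > threshold
    labels, n = ndimage.label(mask)
    out = []
    for lab in range(1, n + 1):
        component = labels == lab
        if component.sum() < 4:
            continue
        skel = morphology.skeletonize(component)
        path = _skeleton_path(skel)
        if path is None:
            continue
        length = _arc_length(path)[-1]
        if length < min_length:
            continue
        width = component.sum() / max(length, 1.0)
        if width > max_width or length / max(width, 1e-9) < min_elongation:
            continue
        out.append((component, path))
    return out


def detect_puncta(
    gtub_channel: np.ndarray,
    min_distance: int = 3,
    threshold_rel: float = 0.2,
) -> np.ndarray:
    """Gamma-tubulin punctum coordinates: local maxima above both a
    relative threshold of the channel maximum and the robust noise
    floor (median + 6 MAD)."""
    if not np.any(gtub_channel > 0):
        return np.empty((0, 2), dtype=int)
    threshold = max(threshold_rel * float(gtub_channel.max()),
                    _robust_floor(gtub_channel))
    return feature.peak_local_max(
        gtub_channel, min_distance=min_distance, threshold_abs=threshold
    )


def orient_cilium(
    path: np.ndarray,
    gtub_channel: np.ndarray | None = None,
    puncta: np.ndarray | None = None,
    max_radius: float = 10.0,
) -> tuple[np.ndarray, str]:
    """Order the skeleton path base -> tip using the centriole marker.

    The endpoint closer to the nearest gamma-tubulin punctum becomes the
    base.  If neither endpoint has a punctum within ``max_radius``
    pixels the cilium cannot be oriented and is flagged ``unoriented``
    (path returned unchanged).
    """
    if puncta is None:
        if gtub_channel is None:
            raise ValueError("provide gtub_channel or puncta")
        puncta = detect_puncta(gtub_channel)
    if len(puncta) == 0:
        return path, "unoriented"
    ends = np.array([path[0], path[-1]], dtype=float)
    d = np.sqrt(((ends[:, None, :] - puncta[None, :, :].astype(float)) ** 2).sum(-1))
    d_start, d_end = d.min(axis=1)
    if min(d_start, d_end) > max_radius:
        return path, "unoriented"
    if d_end < d_start:
        return path[::-1].copy(), "ok"
    return path, "ok"


def bin_cilium(
    mask: np.ndarray,
    path: np.ndarray,
    channel: np.ndarray,
    n_bins: int = 10,
) -> np.ndarray:
    """Summed channel intensity in ``n_bins`` equal arc-length bins.

    The skeleton is cut into equal arc-length segments; each mask pixel
    is assigned to the bin of its nearest skeleton point (ties go to the
    lower bin index, i.e. toward the base).  The bins partition the
    mask, so the bin sums add up to the masked total exactly.
    """
    s = _arc_length(path)
    length = s[-1]
    if len(path) < n_bins or length <= 0:
        raise ValueError("skeleton too short to bin")
    # bin of each skeleton point; the terminal point belongs to the last bin
    point_bins = np.minimum((s / length * n_bins).astype(int), n_bins - 1)
    coords = np.argwhere(mask)
    d2 = ((coords[:, None, :].astype(float) - path[None, :, :].astype(float)) ** 2).sum(-1)
    # argmin takes the first minimum; path is ordered base->tip, so ties
    # resolve to the smaller arc length and hence the lower bin index
    nearest = np.argmin(d2, axis=1)
    pixel_bins = point_bins[nearest]
    values = channel[mask]
    sums = np.zeros(n_bins)
    np.add.at(sums, pixel_bins, values)
    return sums


def tip_signal(bin_sums: Sequence[float], n_bins: int = 10) -> tuple[float, float]:
    """Tip read-out: summed fluorescence of the final five of 10 bins.

    Returns (tip_sum, tip_fraction); tip_fraction is 0 by convention
    when the cilium carries no signal at all.
    """
    bins = np.asarray(bin_sums, dtype=float)
    if bins.shape != (n_bins,):
        raise ValueError(f"expected {n_bins} bins, got shape {bins.shape}")
    tip = float(bins[n_bins // 2:].sum())
    total = float(bins.sum())
    return tip, (tip / total if total > 0 else 0.0)


def measure_cilia(
    stack: ChannelStack,
    signal_role: str = "signal",
    background_radius: int = 15,
    n_bins: int = 10,
    min_length: float = 10.0,
    max_width: float = 8.0,
    max_base_radius: float = 10.0,
) -> list[CiliumMeasurement]:
    """Full ciliary pipeline: background subtraction, segmentation,
    orientation, binning, tip statistics.

    Unorientable or too-short cilia are returned with a non-``ok``
    status and NaN tip statistics rather than dropped.
    """
    arl = subtract_background(stack["arl13b"], background_radius)
    gtub = subtract_background(stack["gtub"], background_radius)
    sig = subtract_background(stack[signal_role], background_radius)
    puncta = detect_puncta(gtub)
    out = []
    for i, (mask, path) in enumerate(
        segment_cilia(arl, min_length=min_length, max_width=max_width), start=1
    ):
        oriented, status = orient_cilium(path, puncta=puncta, max_radius=max_base_radius)
        length = float(_arc_length(oriented)[-1])
        if status != "ok":
            out.append(CiliumMeasurement(i, oriented, length, np.full(n_bins, np.nan),
                                         np.nan, np.nan, status="unoriented"))
            continue
        try:
            sums = bin_cilium(mask, oriented, sig, n_bins=n_bins)
        except ValueError:
            out.append(CiliumMeasurement(i, oriented, length, np.full(n_bins, np.nan),
                                         np.nan, np.nan, status="too_short"))
            continue
        tip, frac = tip_signal(sums, n_bins=n_bins)
        out.append(CiliumMeasurement(i, oriented, length, sums, tip, frac))
    return out
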