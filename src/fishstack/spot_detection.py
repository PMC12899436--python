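"""Gene-spot detection within registered nuclear contours.

FISH probe signals are sub-resolution (< 0.5 µm) fluorescent dots in the
FITC (green) and TRITC (red) channels.  Detection runs plane by plane in
the same focal-first order as nucleus registration:

1. each signal plane is grayscaled (if RGB) and Gaussian-blurred;
2. intensity peaks inside some registered nuclear contour seed candidate
   spots — peaks outside every contour are discarded;
3. each seed is grown into the connected super-threshold region around it,
   clipped to the owning contour and to the maximum physical spot size;
4. the grown spot is registered in a global nucleus-ID → spot-centres
   dictionary, with a non-overlap rule (in image x/y, across planes) that
   keeps each physical spot counted once even when it is visible in
   several adjacent focal planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.morphology import h_maxima

from fishstack.nucleus_registry import NucleusRegistry
from fishstack.stack_io import ZStack

SIGNAL_CHANNELS = ("FITC", "TRITC")


@dataclass
class SpotConfig:
    """Spot detection parameters.

    ``spot_intensity_threshold`` is either an absolute intensity or, when
    None, the ``threshold_percentile`` of intensities inside each nuclear
    contour (per nucleus, per plane).  ``min_peak_prominence`` is either an
    absolute height or, when None, ``prominence_fraction`` of the plane's
    dynamic range.  Spot growth is clipped to ``max_spot_diameter_um``
    because true probe signals are sub-0.5 µm; without the clip a bright
    nucleolus can flood an entire contour.
    """

    blur_sigma_px: float = 1.0
    spot_intensity_threshold: float | None = None
    threshold_percentile: float = 95.0
    min_peak_prominence: float | None = None
    prominence_fraction: float = 0.10
    max_spot_diameter_um: float = 0.5
    min_spot_area_px: int = 1

    def __post_init__(self) -> None:
        if self.spot_intensity_threshold is not None and self.spot_intensity_threshold < 0:
            raise ValueError("spot_intensity_threshold must be >= 0")
        if self.max_spot_diameter_um <= 0:
            raise ValueError("max_spot_diameter_um must be > 0")
        if not 0 < self.threshold_percentile <= 100:
            raise ValueError("threshold_percentile must be in (0, 100]")


@dataclass
class SpotRecord:
    """One detected spot, owned by a registered nucleus."""

    nucleus_id: int
    channel: str
    center: tuple[int, int]              # (row, col) of the peak pixel
    plane_index: int
    area_px: int
    peak_intensity: float
    member_pixels: frozenset = field(repr=False, default_factory=frozenset)


class SpotRegistry:
    """Global nucleus-ID → spot list dictionary, per channel.

    Within one nucleus and channel, member-pixel sets are pairwise
    disjoint in (row, col) space regardless of plane, so a spot seen in
    several focal planes is stored once (at the plane where it was first
    registered, i.e. closest to best focus).
    """

    def __init__(self) -> None:
        self.spots: dict[int, dict[str, list[SpotRecord]]] = {}

    def __len__(self) -> int:
        return sum(len(v) for ch in self.spots.values() for v in ch.values())

    def of(self, nucleus_id: int, channel: str) -> list[SpotRecord]:
        return self.spots.get(nucleus_id, {}).get(channel, [])

    def all_records(self) -> list[SpotRecord]:
        return [s for ch in self.spots.values() for v in ch.values() for s in v]

    def counts_per_nucleus(self, channel: str) -> dict[int, int]:
        return {nid: len(chans.get(channel, [])) for nid, chans in self.spots.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            str(nid): {
                ch: [
                    {
                        "center": [int(s.center[0]), int(s.center[1])],
                        "plane": int(s.plane_index),
                        "area": int(s.area_px),
                        "peak": float(s.peak_intensity),
                    }
                    for s in records
                ]
                for ch, records in chans.items()
            }
            for nid, chans in self.spots.items()
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SpotRegistry":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        registry = cls()
        for nid, chans in payload.items():
            for ch, records in chans.items():
                for s in records:
                    registry.spots.setdefault(int(nid), {}).setdefault(ch, []).append(
                        SpotRecord(
                            nucleus_id=int(nid),
                            channel=ch,
                            center=tuple(s["center"]),
                            plane_index=s["plane"],
                            area_px=s["area"],
                            peak_intensity=s["peak"],
                        )
                    )
        return registry


def preprocess_signal(image: np.ndarray, cfg: SpotConfig, channel: str | None = None) -> np.ndarray:
    """Grayscale (splitting RGB if needed) and Gaussian-blur a signal plane.

    ``blur_sigma_px = 0`` is the identity on an already-gray image.
    """
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        from fishstack.stack_io import CHANNEL_COLOR_PLANE

        image = image[..., CHANNEL_COLOR_PLANE.get(channel or "TRITC", 0)]
    elif image.ndim != 2:
        raise ValueError(f"expected 2-D or RGB plane, got shape {image.shape}")
    image = image.astype(float)
    if cfg.blur_sigma_px > 0:
        image = ndi.gaussian_filter(image, sigma=cfg.blur_sigma_px, mode="reflect")
    return image


def rasterize_ownership(registry: NucleusRegistry, shape: tuple[int, int]) -> np.ndarray:
    """Label image assigning each pixel to the covering registered nucleus.

    Contour polygons are filled onto the pixel grid; where contours from
    different planes overlap, the lower nucleus ID wins (drawn last).
    """
    owner = np.zeros(shape, dtype=np.int32)
    for nid in sorted(registry.records, reverse=True):
        record = registry.records[nid]
        rr, cc = draw_polygon(record.contour[:, 0], record.contour[:, 1], shape=shape)
        owner[rr, cc] = nid
    return owner


def _per_nucleus_threshold(gray: np.ndarray, owner: np.ndarray, cfg: SpotConfig) -> dict[int, float]:
    """Spot threshold per nucleus: absolute, or percentile of in-contour intensities."""
    ids = np.unique(owner[owner > 0])
    if cfg.spot_intensity_threshold is not None:
        return {int(nid): float(cfg.spot_intensity_threshold) for nid in ids}
    return {
        int(nid): float(np.percentile(gray[owner == nid], cfg.threshold_percentile))
        for nid in ids
    }


def find_spot_centers(
    gray: np.ndarray,
    registry: NucleusRegistry,
    cfg: SpotConfig,
    owner: np.ndarray | None = None,
) -> list[tuple[int, tuple[int, int]]]:
    """Candidate spot centres: prominent in-contour intensity peaks.

    Returns ``(nucleus_id, (row, col))`` pairs ordered by decreasing peak
    intensity (ties: lexicographically smaller coordinate first), so that
    when two candidate peaks fall in one super-threshold region the
    brighter / smaller-coordinate one claims it at registration time.
    """
    if owner is None:
        owner = rasterize_ownership(registry, gray.shape)
    thresholds = _per_nucleus_threshold(gray, owner, cfg)
    if not thresholds:
        return []

    prominence = cfg.min_peak_prominence
    if prominence is None:
        span = float(gray.max() - gray.min())
        prominence = cfg.prominence_fraction * span
    prominent = (
        h_maxima(gray, prominence).astype(bool) if prominence > 0 else np.ones_like(gray, dtype=bool)
    )

    floor = min(thresholds.values())
    coords = peak_local_max(gray, min_distance=1, threshold_abs=floor, exclude_border=False)

    candidates = []
    for r, c in coords:
        nid = int(owner[r, c])
        if nid == 0 or not prominent[r, c]:
            continue
        if gray[r, c] < thresholds[nid]:
            continue
        candidates.append((nid, (int(r), int(c)), float(gray[r, c])))
    candidates.sort(key=lambda t: (-t[2], t[1]))
    return [(nid, center) for nid, center, _ in candidates]


def grow_spot(
    center: tuple[int, int],
    gray: np.ndarray,
    cfg: SpotConfig,
    *,
    nucleus_id: int,
    owner: np.ndarray,
    plane_index: int = 0,
    pixel_size_um: float = 0.25,
    threshold: float | None = None,
) -> SpotRecord:
    """Grow a seed into its connected super-threshold region.

    The member set is the connected component of
    ``gray >= threshold`` containing the seed, clipped to the owning
    nucleus and to a disk of ``max_spot_diameter_um`` around the seed.
    """
    r0, c0 = center
    if threshold is None:
        thresholds = _per_nucleus_threshold(gray, owner, cfg)
        threshold = thresholds[nucleus_id]

    radius_px = max(cfg.max_spot_diameter_um / (2.0 * pixel_size_um), 0.5)
    r_lo = max(int(np.floor(r0 - radius_px)), 0)
    r_hi = min(int(np.ceil(r0 + radius_px)) + 1, gray.shape[0])
    c_lo = max(int(np.floor(c0 - radius_px)), 0)
    c_hi = min(int(np.ceil(c0 + radius_px)) + 1, gray.shape[1])

    window = gray[r_lo:r_hi, c_lo:c_hi]
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    eligible = (
        (window >= threshold)
        & (owner[r_lo:r_hi, c_lo:c_hi] == nucleus_id)
        & ((rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2)
    )
    comp, _ = ndi.label(eligible)
    seed_label = comp[r0 - r_lo, c0 - c_lo]
    if seed_label == 0:
        raise RuntimeError("seed pixel below threshold; precondition violated")
    member = comp == seed_label
    pixels = frozenset(zip(rr[member].tolist(), cc[member].tolist()))
    return SpotRecord(
        nucleus_id=nucleus_id,
        channel="",
        center=(int(r0), int(c0)),
        plane_index=plane_index,
        area_px=int(member.sum()),
        peak_intensity=float(gray[r0, c0]),
        member_pixels=pixels,
    )


def register_spot(registry: SpotRegistry, draft: SpotRecord) -> bool:
    """Register a draft unless it overlaps a prior spot of the same nucleus+channel.

    Overlap is tested on member-pixel sets in (row, col) space across all
    planes, so re-detections of one physical spot in adjacent focal planes
    collapse to a single registered spot.  Returns the accepted flag.
    """
    prior = registry.spots.setdefault(draft.nucleus_id, {}).setdefault(draft.channel, [])
    for spot in prior:
        if draft.member_pixels & spot.member_pixels:
            return False
    prior.append(draft)
    return True


def detect_spots(
    stack: ZStack,
    registry: NucleusRegistry,
    cfg: SpotConfig,
    channels: tuple[str, ...] = SIGNAL_CHANNELS,
) -> tuple[SpotRegistry, pd.DataFrame]:
    """Run spot detection over all planes and signal channels.

    Planes are visited focal-first (same order as nucleus registration).
    Returns the cumulative spot registry plus a tidy per-plane count table
    with columns ``plane``, ``channel``, ``n_candidates`` (spots detected
    in that plane, before cross-plane deduplication) and ``n_registered``
    (newly registered unique spots).
    """
    channels = tuple(ch for ch in channels if ch in stack.channel_names)
    spot_registry = SpotRegistry()
    owner = rasterize_ownership(registry, stack.shape_2d)
    rows = []
    counts = {(p, ch): [0, 0] for p in range(stack.n_planes) for ch in channels}
    for plane in stack.plane_order():
        for ch in channels:
            gray = preprocess_signal(stack.channel(ch)[plane], cfg, channel=ch)
            thresholds = _per_nucleus_threshold(gray, owner, cfg)
            candidates = find_spot_centers(gray, registry, cfg, owner=owner)
            for nid, center in candidates:
                draft = grow_spot(
                    center,
                    gray,
                    cfg,
                    nucleus_id=nid,
                    owner=owner,
                    plane_index=plane,
                    pixel_size_um=stack.pixel_size_um,
                    threshold=thresholds[nid],
                )
                if draft.area_px < cfg.min_spot_area_px:
                    continue
                draft.channel = ch
                counts[(plane, ch)][0] += 1
                if register_spot(spot_registry, draft):
                    counts[(plane, ch)][1] += 1
    for plane in range(stack.n_planes):
        for ch in channels:
            n_cand, n_reg = counts[(plane, ch)]
            rows.append({"plane": plane, "channel": ch, "n_candidates": n_cand, "n_registered": n_reg})
    return spot_registry, pd.DataFrame(rows)
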