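"""Cross-plane nucleus registration into a non-redundant ID dictionary.

Nuclei span several focal planes, so segmenting each plane independently
counts the same nucleus repeatedly.  This module accumulates per-plane
nuclear contours into a global *nucleus registry*: a candidate contour from
a new plane is admitted only if it does not conflict with an already
registered nucleus, where "conflict" means a registered centre falls inside
(or on the edge of) the new contour, or the new centre falls inside a
registered contour.  Planes are processed focal-plane-first, so the
best-focused contour of each nucleus is the one that claims its ID.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.measure import find_contours, regionprops

from fishstack.nucleus_segmentation import LabelMask
from fishstack.stack_io import ZStack


@dataclass
class NucleusRecord:
    """One registered nucleus: centre, outer contour and provenance."""

    nucleus_id: int
    center: tuple[float, float]          # (row, col), px
    contour: np.ndarray                  # closed (N, 2) pixel polygon, (row, col)
    area_px: float
    plane_index: int
    hierarchy_level: int = 0             # 0 = outermost contour

    def polygon(self) -> Polygon:
        return Polygon([(r, c) for r, c in self.contour])


@dataclass
class RegistrationReport:
    """Outcome of one registration pass: accepted IDs and rejections."""

    accepted_ids: list[int] = field(default_factory=list)
    rejected: list[tuple[NucleusRecord, int]] = field(default_factory=list)  # (draft, blocking id)

    @property
    def n_accepted(self) -> int:
        return len(self.accepted_ids)


class NucleusRegistry:
    """Global nucleus-ID → record dictionary, non-redundant across planes.

    IDs are consecutive positive integers in registration order.
    """

    def __init__(self) -> None:
        self.records: dict[int, NucleusRecord] = {}
        self.next_id: int = 1
        self._prepared: dict[int, object] = {}   # id -> prepared polygon
        self._bounds: dict[int, tuple] = {}      # id -> (minr, minc, maxr, maxc)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def add(self, draft: NucleusRecord) -> NucleusRecord:
        record = NucleusRecord(
            nucleus_id=self.next_id,
            center=draft.center,
            contour=draft.contour,
            area_px=draft.area_px,
            plane_index=draft.plane_index,
            hierarchy_level=draft.hierarchy_level,
        )
        poly = record.polygon()
        self.records[record.nucleus_id] = record
        self._prepared[record.nucleus_id] = prep(poly)
        self._bounds[record.nucleus_id] = poly.bounds
        self.next_id += 1
        return record

    def blocking_id(self, draft: NucleusRecord) -> int | None:
        """ID of the first registered nucleus conflicting with ``draft``.

        Conflict is boundary-inclusive in both directions: a registered
        centre inside or on the edge of the draft contour, or the draft
        centre inside or on the edge of a registered contour.
        """
        poly = draft.polygon()
        pminr, pminc, pmaxr, pmaxc = poly.bounds
        center = Point(draft.center)
        cr, cc = draft.center
        for nid in sorted(self.records):
            record = self.records[nid]
            rr, rc = record.center
            if pminr <= rr <= pmaxr and pminc <= rc <= pmaxc and poly.covers(Point(record.center)):
                return nid
            minr, minc, maxr, maxc = self._bounds[nid]
            if minr <= cr <= maxr and minc <= cc <= maxc and self._prepared[nid].covers(center):
                return nid
        return None

    def owner_of(self, point: tuple[float, float]) -> int | None:
        """Registered nucleus whose contour covers ``(row, col)``, else None.

        Overlapping contours resolve to the lowest nucleus ID.
        """
        p = Point(point)
        r, c = point
        for nid in sorted(self.records):
            minr, minc, maxr, maxc = self._bounds[nid]
            if minr <= r <= maxr and minc <= c <= maxc and self._prepared[nid].covers(p):
                return nid
        return None

    # --- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            str(nid): {
                "center": [float(r.center[0]), float(r.center[1])],
                "plane": int(r.plane_index),
                "area": float(r.area_px),
                "contour": np.asarray(r.contour, dtype=float).tolist(),
            }
            for nid, r in self.records.items()
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NucleusRegistry":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        registry = cls()
        for nid in sorted(payload, key=int):
            entry = payload[nid]
            registry.add(
                NucleusRecord(
                    nucleus_id=0,
                    center=tuple(entry["center"]),
                    contour=np.asarray(entry["contour"], dtype=float),
                    area_px=entry["area"],
                    plane_index=entry["plane"],
                )
            )
        return registry


def extract_candidates(mask: LabelMask) -> list[NucleusRecord]:
    """Draft one record per instance: outer contour, centroid, pixel area.

    Only the outermost contour of each instance is kept (hierarchy level 0);
    interior holes are irrelevant to centre-in-contour registration.
    Drafts carry ``nucleus_id=0`` until registered.
    """
    drafts: list[NucleusRecord] = []
    labels = mask.labels
    for prop in regionprops(labels):
        instance = labels == prop.label
        # pad so border-touching instances still yield closed contours
        padded = np.pad(instance, 1, mode="constant")
        contours = find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        outer = max(contours, key=len) - 1.0  # undo padding offset
        drafts.append(
            NucleusRecord(
                nucleus_id=0,
                center=(float(prop.centroid[0]), float(prop.centroid[1])),
                contour=outer,
                area_px=float(prop.area),
                plane_index=mask.plane_index,
                hierarchy_level=0,
            )
        )
    return drafts


def register_candidates(
    registry: NucleusRegistry, candidates: Iterable[NucleusRecord]
) -> RegistrationReport:
    """Register one plane's drafts, enforcing cross-plane non-redundancy.

    A candidate is accepted iff no registered centre lies inside or on the
    edge of its contour and its own centre lies outside every registered
    contour; accepted candidates receive fresh sequential IDs.  Rejected
    candidates are reported with the blocking nucleus ID.  The registry is
    updated in place.
    """
    report = RegistrationReport()
    for draft in candidates:
        blocker = registry.blocking_id(draft)
        if blocker is None:
            record = registry.add(draft)
            report.accepted_ids.append(record.nucleus_id)
        else:
            report.rejected.append((draft, blocker))
    return report


def build_registry(
    stack: ZStack,
    segmenter: Callable[[np.ndarray, int], LabelMask],
    *,
    channel: str = "DAPI",
) -> tuple[NucleusRegistry, list[int]]:
    """Segment every plane and accumulate a global nucleus registry.

    Planes are processed focal-plane-first then alternating outward
    (z0, z0−1, z0+1, …), so best-focused contours claim IDs before their
    defocused copies.  Returns the registry and the per-plane candidate
    counts indexed by plane (the raw per-plane instance counts, before
    redundancy rejection).
    """
    volume = stack.channel(channel)
    counts = [0] * stack.n_planes
    registry = NucleusRegistry()
    for plane in stack.plane_order():
        mask = segmenter(volume[plane], plane)
        drafts = extract_candidates(mask)
        counts[plane] = len(drafts)
        register_candidates(registry, drafts)
    return registry, counts
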