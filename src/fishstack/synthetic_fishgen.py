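"""Synthetic two-colour FISH z-stack generator with exact ground truth.

Emulates the imaging setting the pipeline targets: a field of densely
packed, partially overlapping ellipsoidal nuclei (lymphoma-like), each
carrying green/red probe spots laid out according to a planted genotype,
digitised as a short z-stack (default 7 planes, 0.4 µm apart) around a
best-focus plane, with defocus intensity falloff, constant background and
additive Gaussian noise.

Planted genotype patterns (two-colour, one pattern per nucleus):

- ``normal``      — 2 green + 2 red, every green–red distance at least
  three spot diameters (the normal pattern of a dual-fusion probe);
- ``fusion``      — 1 colocalized green–red pair plus 1 green and 1 red
  separated from it and from each other;
- ``break_apart`` — geometrically the same 1-fused + 1-green + 1-red
  layout, arising from a split locus rather than a juxtaposed one.  The
  two aberrant patterns are distinguishable only by probe context, so they
  share a geometry here and differ only in the ground-truth annotation.

Signal separations are enforced in the image plane (not merely in 3-D):
detection quantises depth to the focal plane of registration, so only
in-plane geometry survives measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from fishstack.stack_io import ZStack


class SimulationError(RuntimeError):
    """Layout or spot placement constraints could not be satisfied."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic field.

    Defaults emulate a ×40 / NA 0.8 whole-slide fluorescence scan of a
    follicular-lymphoma-like field: 0.25 µm pixels, 7 planes at 0.4 µm,
    5–8 µm nuclei with 20% of them overlapping a neighbour, sub-0.5 µm
    spots, and a high signal-to-noise 16-bit intensity model.
    """

    n_nuclei: int = 200
    field_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.25
    n_planes: int = 7
    z_step_um: float = 0.4
    nucleus_diameter_um: tuple[float, float] = (5.0, 8.0)
    nucleus_z_semiaxis_um: tuple[float, float] = (1.3, 1.8)  # section-trimmed nuclei
    nucleus_z_jitter_um: float = 0.6       # nucleus centre depth about the focal plane
    overlap_fraction: float = 0.2          # target fraction of nuclei touching a neighbour
    genotype_mix: dict[str, float] = dc_field(
        default_factory=lambda: {"normal": 0.4, "fusion": 0.3, "break_apart": 0.3}
    )
    spot_diameter_um: float = 0.4
    spot_separation_um: tuple[float, float] = (1.8, 2.4)  # planted split distances
    min_spot_separation_um: float = 1.6    # hard floor (> 3 x spot diameter + margin)
    coloc_offset_um: float = 0.05          # fused-pair centre offset
    dapi_peak: float = 18000.0
    spot_peak: float = 30000.0
    z_decay_um: float = 1.5                # DAPI defocus scale about the focal plane
    spot_z_decay_um: float = 0.6           # point-emitter defocus scale about the spot's own z
    background: float = 300.0
    noise_sigma: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.genotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype_mix must sum to 1, got {total}")
        for name, value in (
            ("pixel_size_um", self.pixel_size_um),
            ("z_step_um", self.z_step_um),
            ("spot_diameter_um", self.spot_diameter_um),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def focal_plane_index(self) -> int:
        return self.n_planes // 2

    @property
    def focal_z_um(self) -> float:
        return self.focal_plane_index * self.z_step_um


@dataclass
class SimulatedNucleus:
    nucleus_id: int
    center_um: tuple[float, float, float]   # (row, col, z) in µm
    semiaxes_um: tuple[float, float, float]  # (row, col, z) semi-axes
    angle_rad: float                        # in-plane rotation
    genotype: str


@dataclass
class SimulatedSpot:
    nucleus_id: int
    channel: str     # FITC or TRITC
    center_um: tuple[float, float, float]
    fused_with: int | None = None  # index of the partner spot in a colocalized pair


@dataclass
class GroundTruth:
    nuclei: list[SimulatedNucleus]
    spots: list[SimulatedSpot]
    label_masks: np.ndarray  # (plane, row, col) int32 instance labels

    def genotype_fractions(self) -> dict[str, float]:
        n = len(self.nuclei)
        out: dict[str, float] = {}
        for nuc in self.nuclei:
            out[nuc.genotype] = out.get(nuc.genotype, 0.0) + 1.0 / n
        return out

    def spot_count(self, channel: str) -> int:
        return sum(s.channel == channel for s in self.spots)


def _cross_section(nucleus: SimulatedNucleus, z_um: float) -> tuple[float, float] | None:
    """In-plane semi-axes (µm) of the ellipsoid cut at depth z, or None."""
    a, b, c = nucleus.semiaxes_um
    dz = (z_um - nucleus.center_um[2]) / c
    if abs(dz) >= 1.0:
        return None
    scale = float(np.sqrt(1.0 - dz * dz))
    return a * scale, b * scale


def sample_nuclei(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> list[SimulatedNucleus]:
    """Place ellipsoidal nuclei with a controlled 2-D overlap fraction.

    Sequential rejection sampling with a self-correcting overlap policy:
    each nucleus is forced to touch an existing one while the realised
    overlap fraction (share of nuclei intersecting at least one neighbour,
    by the circumscribing-circle criterion) trails the target, and kept
    clear otherwise.  Layouts are retried until the realised fraction is
    within ±0.05 of the target.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    h_px, w_px = cfg.field_size_px
    h_um, w_um = h_px * cfg.pixel_size_um, w_px * cfg.pixel_size_um
    lo_d, hi_d = cfg.nucleus_diameter_um

    genotypes = list(cfg.genotype_mix)
    probs = np.array([cfg.genotype_mix[g] for g in genotypes])

    for _ in range(30):  # layout attempts
        placed: list[SimulatedNucleus] = []
        radii: list[float] = []
        centers: list[tuple[float, float]] = []
        overlapping = np.zeros(cfg.n_nuclei, dtype=bool)
        ok = True
        for i in range(cfg.n_nuclei):
            realized = overlapping[:i].mean() if i else 0.0
            want_overlap = bool(placed) and realized < cfg.overlap_fraction
            a = rng.uniform(lo_d, hi_d) / 2.0
            b = a * rng.uniform(0.85, 1.0)
            r_eff = (a + b) / 2.0
            for _attempt in range(400):
                row = rng.uniform(a, h_um - a)
                col = rng.uniform(a, w_um - a)
                d = (
                    np.hypot(
                        np.array([c[0] for c in centers]) - row,
                        np.array([c[1] for c in centers]) - col,
                    )
                    if centers
                    else np.array([])
                )
                sums = np.asarray(radii) + r_eff if radii else np.array([])
                touching = d < sums if len(d) else np.array([], dtype=bool)
                too_close = (d < 0.65 * sums).any() if len(d) else False
                if too_close:
                    continue
                if want_overlap and not touching.any():
                    continue
                if not want_overlap and touching.any():
                    continue
                z = cfg.focal_z_um + rng.uniform(-cfg.nucleus_z_jitter_um, cfg.nucleus_z_jitter_um)
                placed.append(
                    SimulatedNucleus(
                        nucleus_id=i + 1,
                        center_um=(row, col, z),
                        semiaxes_um=(a, b, rng.uniform(*cfg.nucleus_z_semiaxis_um)),
                        angle_rad=rng.uniform(0, np.pi),
                        genotype=str(rng.choice(genotypes, p=probs)),
                    )
                )
                if len(d) and touching.any():
                    overlapping[i] = True
                    overlapping[:i][touching] = True
                centers.append((row, col))
                radii.append(r_eff)
                break
            else:
                ok = False
                break
        if not ok:
            continue
        realized = overlapping.mean() if cfg.n_nuclei else 0.0
        if abs(realized - cfg.overlap_fraction) <= 0.05:
            return placed
    raise SimulationError(
        f"could not realise overlap fraction {cfg.overlap_fraction} for "
        f"{cfg.n_nuclei} nuclei in a {cfg.field_size_px} field"
    )


def _spot_layout(nucleus: SimulatedNucleus, cfg: SimulationConfig, rng: np.random.Generator):
    """In-plane spot positions for one nucleus, channels and fusion links.

    Spots sit on a circle inside the focal-plane cross-section so that the
    registered (best-focus) contour contains them with margin; the circle
    radius is chosen so every intended separated green–red chord exceeds
    the planted separation distance.
    """
    section = _cross_section(nucleus, cfg.focal_z_um)
    if section is None:
        raise SimulationError(f"nucleus {nucleus.nucleus_id} has no focal-plane cross-section")
    usable = 0.8 * min(section)

    if nucleus.genotype == "normal":
        # G, R, G, R on a circle: the four green-red chords are the sides.
        n_points, chord_factor = 4, np.sqrt(2.0)
        channels = ["FITC", "TRITC", "FITC", "TRITC"]
    else:
        # fused pair at one vertex, lone green and lone red at the others
        n_points, chord_factor = 3, np.sqrt(3.0)
        channels = ["fused", "FITC", "TRITC"]

    sep_lo, sep_hi = cfg.spot_separation_um
    rho_min_needed = cfg.min_spot_separation_um / chord_factor
    if usable < rho_min_needed:
        raise SimulationError(
            f"nucleus {nucleus.nucleus_id} too small for spot separation constraints"
        )
    rho_lo = min(max(sep_lo / chord_factor, rho_min_needed), usable)
    rho_hi = max(rho_lo, min(sep_hi / chord_factor, usable))
    rho = rng.uniform(rho_lo, rho_hi)
    theta0 = rng.uniform(0, 2 * np.pi)

    cr, cc, cz = nucleus.center_um
    a, b, c = nucleus.semiaxes_um
    spots: list[SimulatedSpot] = []
    for k, ch in enumerate(channels):
        theta = theta0 + 2 * np.pi * k / n_points
        dr = rho * np.cos(theta)
        dc = rho * np.sin(theta)
        # depth inside the ellipsoid at this in-plane offset, biased to centre
        margin = np.sqrt(max(1.0 - (dr / a) ** 2 - (dc / b) ** 2, 0.0))
        z = cz + rng.uniform(-0.5, 0.5) * c * margin
        z = float(np.clip(z, 0.0, (cfg.n_planes - 1) * cfg.z_step_um))
        if ch == "fused":
            offset = cfg.coloc_offset_um
            phi = rng.uniform(0, 2 * np.pi)
            base = len(spots)
            spots.append(
                SimulatedSpot(nucleus.nucleus_id, "FITC", (cr + dr, cc + dc, z), fused_with=base + 1)
            )
            spots.append(
                SimulatedSpot(
                    nucleus.nucleus_id,
                    "TRITC",
                    (cr + dr + offset * np.cos(phi), cc + dc + offset * np.sin(phi), z),
                    fused_with=base,
                )
            )
        else:
            spots.append(SimulatedSpot(nucleus.nucleus_id, ch, (cr + dr, cc + dc, z)))
    return spots


def place_spots(
    nuclei: list[SimulatedNucleus], cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SimulatedSpot]:
    """Plant genotype-consistent spot patterns in every nucleus.

    Every nucleus receives exactly two green and two red spots; separated
    green–red distances exceed three spot diameters (with margin) and
    fused pairs sit within the colocalization offset, all inside the
    nucleus ellipsoid.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    spots: list[SimulatedSpot] = []
    for nucleus in nuclei:
        spots.extend(_spot_layout(nucleus, cfg, rng))
    return spots


def _add_gaussian_spot(plane: np.ndarray, row: float, col: float, amp: float, sigma_px: float) -> None:
    if amp <= 0:
        return
    half = max(int(np.ceil(4 * sigma_px)), 2)
    r0, c0 = int(round(row)), int(round(col))
    r_lo, r_hi = max(r0 - half, 0), min(r0 + half + 1, plane.shape[0])
    c_lo, c_hi = max(c0 - half, 0), min(c0 + half + 1, plane.shape[1])
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    plane[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma_px**2)
    )


def render_stack(
    nuclei: list[SimulatedNucleus],
    spots: list[SimulatedSpot],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ZStack, GroundTruth]:
    """Rasterise nuclei and spots into a noisy 16-bit three-channel z-stack.

    DAPI planes contain the ellipsoid cross-sections, scaled by a Gaussian
    defocus factor about the focal plane; signal planes contain Gaussian
    blobs of the configured spot diameter (FWHM), each defocused about the
    spot's own depth (point emitters lose intensity with defocus much
    faster than the extended nuclear counterstain).  Background and
    Gaussian noise are added and the result is clipped to uint16.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    h_px, w_px = cfg.field_size_px
    px = cfg.pixel_size_um
    volume = np.zeros((3, cfg.n_planes, h_px, w_px), dtype=float)
    labels = np.zeros((cfg.n_planes, h_px, w_px), dtype=np.int32)
    sigma_px = cfg.spot_diameter_um / 2.355 / px  # FWHM -> sigma

    dapi_gain = {n.nucleus_id: rng.uniform(0.85, 1.0) for n in nuclei}

    for p in range(cfg.n_planes):
        z = p * cfg.z_step_um
        decay = np.exp(-((z - cfg.focal_z_um) ** 2) / (2.0 * cfg.z_decay_um**2))
        dapi = volume[0, p]
        for nucleus in nuclei:
            section = _cross_section(nucleus, z)
            if section is None:
                continue
            a_um, b_um = section
            rr, cc = draw_ellipse(
                nucleus.center_um[0] / px,
                nucleus.center_um[1] / px,
                a_um / px,
                b_um / px,
                shape=(h_px, w_px),
                rotation=nucleus.angle_rad,
            )
            if rr.size == 0:
                continue
            intensity = cfg.dapi_peak * decay * dapi_gain[nucleus.nucleus_id]
            np.maximum.at(dapi, (rr, cc), intensity)
            labels[p, rr, cc] = np.where(
                labels[p, rr, cc] == 0, nucleus.nucleus_id, labels[p, rr, cc]
            )
        for spot in spots:
            ch_idx = 1 if spot.channel == "FITC" else 2
            amp = cfg.spot_peak * np.exp(
                -((z - spot.center_um[2]) ** 2) / (2.0 * cfg.spot_z_decay_um**2)
            )
            if amp < 1.0:
                continue
            _add_gaussian_spot(volume[ch_idx, p], spot.center_um[0] / px, spot.center_um[1] / px, amp, sigma_px)

    volume += cfg.background
    if cfg.noise_sigma > 0:
        volume += rng.normal(0.0, cfg.noise_sigma, size=volume.shape)
    data = np.clip(volume, 0, 65535).astype(np.uint16)

    stack = ZStack(
        data=data,
        channel_names=("DAPI", "FITC", "TRITC"),
        z_step_um=cfg.z_step_um,
        pixel_size_um=cfg.pixel_size_um,
        focal_plane_index=cfg.focal_plane_index,
    )
    truth = GroundTruth(nuclei=list(nuclei), spots=list(spots), label_masks=labels)
    return stack, truth


def simulate(cfg: SimulationConfig) -> tuple[ZStack, GroundTruth]:
    """Sample a layout, plant spots and render, all from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    nuclei = sample_nuclei(cfg, rng)
    spots = place_spots(nuclei, cfg, rng)
    return render_stack(nuclei, spots, cfg, rng)
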