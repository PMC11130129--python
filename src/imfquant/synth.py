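"""Synthetic H&E-like muscle sections with pixel-accurate ground truth.

The generator emulates the structure of a sheep laryngeal-muscle (PCA)
stimulation study: a hierarchy of animals in treatment groups, two muscle
sides per animal (nPCA with an intact recurrent laryngeal nerve, cdPCA with
a cryo-damaged one), electrode regions for implanted groups (el+ far from /
el++ near the electrode), four slides per animal with four sections each.
Each rendered section is a pink fiber tessellation with dark nuclei,
clustered white adipocytes, a near-white background and optional crack /
dirt / air-bubble artifacts, together with exact fat and tissue masks.

Each animal carries one standard-normal fat propensity shared by all its
(side, region) cells and scaled by the cell's configured SD, so the
between-animal correlation assumed by the downstream random-intercept model
is actually present in the synthetic data; sections of the same cell share
the resulting level up to a small per-section jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GenerationError, UndefinedFractionError

SIDES = ("nPCA", "cdPCA")
REGIONS_IMPLANT = ("el+", "el++")
NO_REGION = "none"


@dataclass(frozen=True)
class CellStats:
    """True fat-fraction distribution of one (side, region) cell, in percent."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 100.0:
            raise ConfigurationError(f"fat-fraction mean {self.mean} outside [0, 100]")
        if self.sd < 0.0:
            raise ConfigurationError(f"fat-fraction SD {self.sd} must be >= 0")


@dataclass(frozen=True)
class GroupDesign:
    """One treatment group: label, animal count, per-cell fat distributions."""

    label: str
    n_animals: int
    electrodes: bool
    fat: dict[tuple[str, str], CellStats]

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError(f"group {self.label}: animal count must be >= 1")
        for cell in self.cells():
            if cell not in self.fat:
                raise ConfigurationError(f"group {self.label}: no fat stats for cell {cell}")

    def cells(self) -> list[tuple[str, str]]:
        regions = REGIONS_IMPLANT if self.electrodes else (NO_REGION,)
        return [(side, region) for side in SIDES for region in regions]


@dataclass(frozen=True)
class StudyDesign:
    """Hierarchical study layout: groups x animals x slides x sections.

    ``slides_per_animal`` slides are assigned round-robin over the group's
    (side, region) cells; implanted groups with four cells get one slide per
    cell, non-implanted groups get two slides per side.  ``missing_slides``
    removes whole (group, animal-index, side) slide sets, emulating slides
    lost during sample preparation.
    """

    groups: tuple[GroupDesign, ...]
    slides_per_animal: int = 4
    sections_per_slide: int = 4
    defect_rate: float = 10 / 336
    section_jitter_sd: float = 0.5
    missing_slides: tuple[tuple[str, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slides_per_animal < 1 or self.sections_per_slide < 1:
            raise ConfigurationError("slide and section counts must be >= 1")
        if not 0.0 <= self.defect_rate <= 1.0:
            raise ConfigurationError("defect_rate must be in [0, 1]")
        if not self.groups:
            raise ConfigurationError("design needs at least one group")

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.groups)


def default_study_design() -> StudyDesign:
    """The study layout used throughout: 22 animals in CT(4)/SHAM(8)/DC04(4)/DC07(6).

    Cell means for CT and SHAM follow the group summaries the study design is
    parameterized with; the stimulated groups (DC04/DC07), whose cell-level
    values are configuration rather than ground truth, are set to plausible
    levels (close to control, with somewhat higher nPCA spread).  Two DC07
    animals are missing their nPCA slides, so the default design totals
    336 sections of which 10 are flagged unusable.
    """
    ct = GroupDesign(
        "CT", 4, False,
        {("nPCA", NO_REGION): CellStats(5.7, 2.4), ("cdPCA", NO_REGION): CellStats(7.0, 1.5)},
    )
    sham = GroupDesign(
        "SHAM", 8, True,
        {
            ("nPCA", "el+"): CellStats(3.3, 2.0),
            ("nPCA", "el++"): CellStats(4.1, 2.0),
            ("cdPCA", "el+"): CellStats(6.2, 2.0),
            ("cdPCA", "el++"): CellStats(11.5, 3.0),
        },
    )
    dc04 = GroupDesign(
        "DC04", 4, True,
        {
            ("nPCA", "el+"): CellStats(4.5, 3.0),
            ("nPCA", "el++"): CellStats(4.0, 2.5),
            ("cdPCA", "el+"): CellStats(5.0, 2.0),
            ("cdPCA", "el++"): CellStats(6.0, 2.5),
        },
    )
    dc07 = GroupDesign(
        "DC07", 6, True,
        {
            ("nPCA", "el+"): CellStats(4.5, 3.0),
            ("nPCA", "el++"): CellStats(4.0, 2.5),
            ("cdPCA", "el+"): CellStats(5.0, 2.0),
            ("cdPCA", "el++"): CellStats(6.5, 2.5),
        },
    )
    return StudyDesign(
        groups=(ct, sham, dc04, dc07),
        missing_slides=(("DC07", 4, "nPCA"), ("DC07", 5, "nPCA")),
    )


def null_study_design(mean: float = 5.0, sd: float = 2.0) -> StudyDesign:
    """Default layout with every cell set to the same fat distribution."""
    design = default_study_design()
    groups = tuple(
        replace(g, fat={cell: CellStats(mean, sd) for cell in g.cells()})
        for g in design.groups
    )
    return replace(design, groups=groups)


@dataclass(frozen=True)
class SectionSpec:
    """One section to render: identity, target fat level and artifact flags."""

    animal: str
    group: str
    side: str
    region: str
    slide: int
    section: int
    target_fat: float
    crack: bool = False
    dirt: bool = False
    bubble: bool = False
    usable: bool = True


def _slide_cells(group: GroupDesign, design: StudyDesign) -> list[tuple[str, str]]:
    cells = group.cells()
    return [cells[s % len(cells)] for s in range(design.slides_per_animal)]


def sample_study(design: StudyDesign, seed: int) -> list[SectionSpec]:
    """Draw the full list of section specs for a study design.

    Per-animal fat levels are drawn from each cell's (mean, sd) and clipped
    to [0, 100]; sections add a small jitter around the animal level.
    Exactly ``ceil(defect_rate * n_sections)`` specs are flagged unusable
    (those also receive dirt/bubble artifact flags).  Fully reproducible for
    a fixed (design, seed).
    """
    rng = np.random.default_rng(seed)
    specs: list[SectionSpec] = []
    for group in design.groups:
        slide_cells = _slide_cells(group, design)
        for a in range(group.n_animals):
            animal = f"{group.label}{a + 1:02d}"
            # one standard-normal animal effect shared by all cells, scaled
            # by each cell's SD: the structure the downstream
            # random-intercept model assumes
            u = rng.normal()
            levels = {
                cell: float(np.clip(st.mean + st.sd * u, 0.0, 100.0))
                for cell, st in group.fat.items()
            }
            missing_sides = {
                side for (g, idx, side) in design.missing_slides
                if g == group.label and idx == a
            }
            for slide, (side, region) in enumerate(slide_cells):
                if side in missing_sides:
                    continue
                for section in range(design.sections_per_slide):
                    target = float(
                        np.clip(
                            levels[(side, region)]
                            + rng.normal(0.0, design.section_jitter_sd),
                            0.0,
                            100.0,
                        )
                    )
                    specs.append(
                        SectionSpec(animal, group.label, side, region,
                                    slide, section, target)
                    )
    n_defects = math.ceil(design.defect_rate * len(specs))
    if n_defects > len(specs):
        raise ConfigurationError("defect_rate flags more sections than exist")
    defect_idx = rng.choice(len(specs), size=n_defects, replace=False)
    for i in defect_idx:
        specs[i] = replace(specs[i], usable=False, dirt=True, bubble=bool(rng.integers(2)))
    return specs


def specs_to_frame(specs: list[SectionSpec]) -> pd.DataFrame:
    """Tabulate specs with one row per section (CSV-ready)."""
    return pd.DataFrame([vars(s) for s in specs])


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class RenderParams:
    """Appearance and geometry of a rendered section.

    Distances are in µm where suffixed, otherwise pixels.  The default
    palette keeps background/fat saturation well below 0.15 and stained
    tissue saturation well above it, so a 15% saturation threshold separates
    tissue from background by construction.
    """

    canvas: tuple[int, int] = (1024, 1024)
    um_per_px: float = 0.442
    tissue_radius_frac: float = 0.42
    boundary_wobble: float = 0.06
    fiber_size_um: float = 60.0
    fiber_border_px: float = 2.5
    nuclei_per_fiber: float = 2.0
    nucleus_radius_px: tuple[int, int] = (2, 5)
    fat_diameter_um: tuple[float, float] = (40.0, 80.0)
    fat_cluster_size: tuple[int, int] = (2, 5)
    fat_min_diameter_px: int = 6
    fat_tolerance_pp: float = 0.5
    fat_max_cells: int = 20000
    crack_width_px: tuple[int, int] = (8, 16)
    noise: int = 3
    color_background: tuple[int, int, int] = (247, 245, 243)
    color_fiber: tuple[int, int, int] = (224, 148, 168)
    color_border: tuple[int, int, int] = (238, 188, 198)
    color_nucleus: tuple[int, int, int] = (96, 60, 132)
    color_fat: tuple[int, int, int] = (246, 243, 244)
    color_dirt: tuple[int, int, int] = (82, 52, 34)
    color_bubble: tuple[int, int, int] = (236, 234, 246)

    def __post_init__(self) -> None:
        if min(self.canvas) < 256:
            raise ConfigurationError("canvas must be at least 256x256")
        if self.um_per_px <= 0:
            raise ConfigurationError("um_per_px must be positive")


@dataclass
class SyntheticSection:
    """A rendered section with exact ground-truth masks."""

    image: np.ndarray          # (H, W, 3) uint8
    truth_fat: np.ndarray      # (H, W) bool, subset of truth_tissue
    truth_tissue: np.ndarray   # (H, W) bool
    um_per_px: float
    spec: SectionSpec


def realized_fat_fraction(section: SyntheticSection) -> float:
    """Ground-truth fat percentage: 100 * |truth_fat| / |truth_tissue|."""
    n_tissue = int(section.truth_tissue.sum())
    if n_tissue == 0:
        raise UndefinedFractionError("empty tissue mask: fat fraction undefined")
    return 100.0 * float(section.truth_fat.sum()) / n_tissue


def _tissue_blob(shape: tuple[int, int], params: RenderParams,
                 rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(yy - cy, xx - cx)
    base = params.tissue_radius_frac * min(h, w)
    wob = np.zeros_like(theta)
    for k in range(2, 6):
        amp = params.boundary_wobble * base * rng.uniform(0.2, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        wob += amp * np.cos(k * theta + phase)
    return r <= base + wob


def _paint_fibers(image: np.ndarray, blob: np.ndarray, params: RenderParams,
                  rng: np.random.Generator) -> None:
    h, w = blob.shape
    spacing = max(8.0, params.fiber_size_um / params.um_per_px)
    nx = max(2, int(w / spacing) + 2)
    ny = max(2, int(h / spacing) + 2)
    gx, gy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    seeds = np.column_stack([gy.ravel(), gx.ravel()])
    seeds += rng.uniform(-0.35 * spacing, 0.35 * spacing, seeds.shape)
    tree = cKDTree(seeds)
    pts = np.argwhere(blob)
    dists, labels = tree.query(pts, k=2, workers=1)
    fiber_id = labels[:, 0]
    border = (dists[:, 1] - dists[:, 0]) < params.fiber_border_px

    jitter = rng.integers(-8, 9, size=(len(seeds), 3))
    fiber_colors = np.clip(np.array(params.color_fiber) + jitter, 0, 255).astype(np.uint8)
    image[pts[:, 0], pts[:, 1]] = fiber_colors[fiber_id]
    bpts = pts[border]
    image[bpts[:, 0], bpts[:, 1]] = params.color_border

    # nuclei: small dark ellipses sprinkled along fiber borders
    n_nuclei = int(params.nuclei_per_fiber * len(np.unique(fiber_id)))
    if len(bpts) and n_nuclei:
        centers = bpts[rng.choice(len(bpts), size=min(n_nuclei, len(bpts)), replace=False)]
        for cy, cx in centers:
            ry = rng.integers(*params.nucleus_radius_px, endpoint=True)
            rx = rng.integers(*params.nucleus_radius_px, endpoint=True)
            _fill_ellipse(image, blob, (cy, cx), (ry, rx),
                          rng.uniform(0, np.pi), params.color_nucleus)


def _ellipse_mask_window(shape, center, radii, angle):
    """Boolean ellipse raster restricted to a local window; returns (sl, mask)."""
    cy, cx = center
    ry, rx = radii
    ext = int(max(ry, rx)) + 2
    y0, y1 = max(0, int(cy) - ext), min(shape[0], int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(shape[1], int(cx) + ext + 1)
    if y0 >= y1 or x0 >= x1:
        return None, None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = (c * dx + s * dy) / max(rx, 1e-9)
    v = (-s * dx + c * dy) / max(ry, 1e-9)
    return (slice(y0, y1), slice(x0, x1)), (u * u + v * v) <= 1.0


def _fill_ellipse(image, blob, center, radii, angle, color):
    sl, m = _ellipse_mask_window(blob.shape, center, radii, angle)
    if sl is None:
        return
    m = m & blob[sl]
    image[sl][m] = color


def _place_fat(fat: np.ndarray, blob: np.ndarray, target: float,
               params: RenderParams, rng: np.random.Generator) -> None:
    n_tissue = int(blob.sum())
    if n_tissue == 0:
        raise GenerationError("tissue blob is empty")
    tol = params.fat_tolerance_pp
    if target <= tol:
        return
    dt = ndimage.distance_transform_edt(blob)
    d_lo = params.fat_diameter_um[0] / params.um_per_px
    d_hi = params.fat_diameter_um[1] / params.um_per_px
    # adipocytes are interstitial: keep every cell strictly inside the
    # tissue so the convex-hull clip downstream cannot cut them off
    interior = np.argwhere(dt > d_hi / 2.0 + 2.0)
    if not len(interior):
        raise GenerationError("tissue too small to host adipocytes")
    cells_placed = 0
    cluster_left = 0
    cluster_center = None
    while cells_placed < params.fat_max_cells:
        frac = 100.0 * fat.sum() / n_tissue
        deficit = target - frac
        if abs(deficit) <= tol or deficit < 0:
            if deficit < -tol:
                raise GenerationError("overshot fat target beyond tolerance")
            return
        if cluster_left <= 0:
            cluster_center = interior[rng.integers(len(interior))]
            cluster_left = int(rng.integers(*params.fat_cluster_size, endpoint=True))
        area_needed = deficit / 100.0 * n_tissue
        diam = rng.uniform(d_lo, d_hi)
        # shrink the last cells so the realized fraction lands inside tolerance
        max_diam = 2.0 * math.sqrt(max(area_needed, 1.0) / math.pi) / 0.85
        diam = max(params.fat_min_diameter_px, min(diam, max_diam))
        offset = rng.normal(0.0, 0.6 * diam, size=2)
        center = cluster_center + offset
        ratio = rng.uniform(0.7, 1.0)
        radii = (diam / 2.0, diam / 2.0 * ratio)
        cluster_left -= 1
        cells_placed += 1
        cy, cx = int(round(center[0])), int(round(center[1]))
        if not (0 <= cy < blob.shape[0] and 0 <= cx < blob.shape[1]):
            continue
        if dt[cy, cx] <= radii[0] + 2.0:
            continue  # would pierce the tissue boundary
        sl, m = _ellipse_mask_window(blob.shape, center, radii, rng.uniform(0, np.pi))
        if sl is None:
            continue
        add = m & blob[sl]
        gain = int((add & ~fat[sl]).sum())
        if gain == 0:
            continue
        if 100.0 * (fat.sum() + gain) / n_tissue > target + tol:
            continue  # too big for the remaining deficit; retry smaller
        fat[sl] |= add
    raise GenerationError(
        f"could not reach fat target {target:.2f}% within {params.fat_max_cells} cells"
    )


def _draw_crack(params: RenderParams, blob: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Jagged background-colored fissure through the tissue interior."""
    h, w = blob.shape
    dt = ndimage.distance_transform_edt(blob)
    interior = np.argwhere(dt > 10)
    if not len(interior):
        return np.zeros_like(blob)
    start = interior[rng.integers(len(interior))].astype(float)
    angle = rng.uniform(0, 2 * np.pi)
    width = int(rng.integers(*params.crack_width_px, endpoint=True))
    n_steps = int(0.6 * min(h, w) / 4)
    path = np.zeros_like(blob)
    pos = start.copy()
    for _ in range(n_steps):
        angle += rng.normal(0.0, 0.25)
        pos += 4.0 * np.array([np.sin(angle), np.cos(angle)])
        y, x = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= y < h and 0 <= x < w) or not blob[y, x]:
            break
        path[y, x] = True
    crack = ndimage.binary_dilation(path, iterations=max(1, width // 2))
    return crack & blob


def render_section(spec: SectionSpec, params: RenderParams | None = None,
                   seed: int = 0) -> SyntheticSection:
    """Render one section image plus exact fat/tissue ground-truth masks.

    The muscle is a wobbly blob tessellated into eosin-pink fibers with
    lighter endomysium borders and dark nuclei; adipocytes are clustered
    white ellipses added until the realized fat fraction is within
    ``fat_tolerance_pp`` of the spec target.  Crack pixels are removed from
    both truth masks (a crack is an absence of tissue); dirt and bubbles
    only perturb the image.
    """
    params = params or RenderParams()
    h, w = params.canvas
    rng = np.random.default_rng(seed)

    blob = _tissue_blob((h, w), params, rng)
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = params.color_background
    _paint_fibers(image, blob, params, rng)

    fat = np.zeros((h, w), dtype=bool)
    _place_fat(fat, blob, spec.target_fat, params, rng)
    fpts = np.argwhere(fat)
    if len(fpts):
        image[fpts[:, 0], fpts[:, 1]] = params.color_fat

    crack = np.zeros((h, w), dtype=bool)
    if spec.crack:
        crack = _draw_crack(params, blob, rng)
        cpts = np.argwhere(crack)
        image[cpts[:, 0], cpts[:, 1]] = params.color_background
    if spec.dirt:
        for _ in range(rng.integers(2, 5)):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = rng.integers(5, 13)
            sl, m = _ellipse_mask_window((h, w), (cy, cx), (r, r), 0.0)
            if sl is not None:
                image[sl][m] = params.color_dirt
    if spec.bubble:
        cy, cx = int(rng.integers(0, h)), int(rng.integers(0, w))
        r_out = int(rng.integers(40, 90))
        thick = int(rng.integers(6, 11))
        ext = r_out + 2
        y0, y1 = max(0, cy - ext), min(h, cy + ext + 1)
        x0, x1 = max(0, cx - ext), min(w, cx + ext + 1)
        if y0 < y1 and x0 < x1:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            rr = np.hypot(yy - cy, xx - cx)
            ring = (rr <= r_out) & (rr > r_out - thick)
            image[y0:y1, x0:x1][ring] = params.color_bubble

    if params.noise:
        noise = rng.integers(-params.noise, params.noise + 1, size=image.shape)
        image = np.clip(image.astype(np.int16) + noise, 0, 255).astype(np.uint8)

    truth_tissue = blob & ~crack
    truth_fat = fat & truth_tissue
    return SyntheticSection(image, truth_fat, truth_tissue, params.um_per_px, spec)


def section_seeds(root_seed: int, n: int) -> list[int]:
    """Stable per-section render seeds derived from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_slide_table(design: StudyDesign, seed: int,
                         slide_sd: float = 0.7) -> pd.DataFrame:
    """Draw a slide-level fat table directly from the study design.

    Statistical-level counterpart of rendering + measuring: slide means are
    the animal's cell level plus slide-to-slide noise.  Used for mixed-model
    calibration experiments where no images are needed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in design.groups:
        slide_cells = _slide_cells(group, design)
        for a in range(group.n_animals):
            animal = f"{group.label}{a + 1:02d}"
            u = rng.normal()
            levels = {
                cell: float(np.clip(st.mean + st.sd * u, 0.0, 100.0))
                for cell, st in group.fat.items()
            }
            missing_sides = {
                side for (g, idx, side) in design.missing_slides
                if g == group.label and idx == a
            }
            for slide, (side, region) in enumerate(slide_cells):
                if side in missing_sides:
                    continue
                value = float(np.clip(
                    levels[(side, region)] + rng.normal(0.0, slide_sd), 0.0, 100.0))
                rows.append(dict(animal=animal, group=group.label, side=side,
                                 region=region, slide=slide, fat_percent=value))
    return pd.DataFrame(rows)
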