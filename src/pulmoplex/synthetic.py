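"""Ground-truthed synthetic lung-like tissue.

Generates the two artifacts the analysis pipeline consumes — a multichannel
immunofluorescence image and a per-cell intensity table — from a single
planted ground truth, so that every downstream stage (segmentation,
phenotyping, neighborhood statistics, domain inference, proliferation and
vasculature analyses) can be tested against known answers.

The tissue model is deliberately simple but carries the statistical
structure the analysis assumes:

* cells are non-overlapping disks (nucleus + cytoplasmic rim) placed by
  rejection sampling with a minimum spacing;
* marker intensities are log-normal per (cell type, marker) with an
  additive constant background per channel, which is the regime in which
  percentile background subtraction and arcsinh normalization are
  meaningful;
* Ki67 is continuous and bimodal: proliferating cells are drawn from a
  planted high mode so that percentile thresholding has a well-defined
  answer;
* anatomical structures — airway cross-sections with SOX2-high epithelial
  rings wrapped in airway smooth muscle, SOX9-high distal tips, and
  arterial vessels (endothelial ring, vascular smooth muscle ring,
  immune-cell ring with shifted marker profiles) — are planted explicitly
  and registered so geometric tags can be recomputed independently.

Coordinates are physical micrometres with the origin at the top-left
corner, x along columns and y along rows; pixels are 0-based and convert
through the configured pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeSpec",
    "AirwaySpec",
    "VesselSpec",
    "DomainSpec",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "PackingError",
    "generate_ground_truth",
    "render_multiplex_image",
    "emit_cell_table",
]

ARTERY_CLOSE_TAG = "artery-close"


class PackingError(RuntimeError):
    """Requested cell density exceeds what the field can accommodate."""


@dataclass
class CellTypeSpec:
    """One cell type with its marker profile and geometry.

    ``markers`` maps marker name to the mean intensity on the natural
    scale; draws are log-normal with log-scale s.d. ``dispersion`` and are
    mean-preserving (dispersion 0 returns the mean exactly).
    """

    name: str
    markers: dict = dc_field(default_factory=dict)
    count: int = 0
    dispersion: float = 0.3
    nucleus_radius_um: float = 4.0
    proliferation_rate: float = 0.0
    epithelial: bool = False

    def validate(self) -> None:
        if self.count < 0:
            raise ValueError(f"cell type {self.name!r}: count must be >= 0")
        if not 0.0 <= self.proliferation_rate <= 1.0:
            raise ValueError(f"cell type {self.name!r}: proliferation rate must be in [0, 1]")
        if self.nucleus_radius_um <= 0:
            raise ValueError(f"cell type {self.name!r}: nucleus radius must be > 0")
        if self.dispersion < 0:
            raise ValueError(f"cell type {self.name!r}: dispersion must be >= 0")


@dataclass
class AirwaySpec:
    """Airway cross-section: epithelial ring around a lumen, optionally
    wrapped by an airway-smooth-muscle ring (proximal, SOX2-high airways)
    or filled as a solid epithelial disk (distal, SOX9-high tips)."""

    name: str
    center_um: tuple
    lumen_radius_um: float
    epithelial_type: str
    n_epithelial: int
    asm_type: str = ""
    n_asm: int = 0
    asm_ring_um: float = 8.0
    filled: bool = False

    def outer_radius_um(self, config: "SyntheticConfig") -> float:
        r = self.lumen_radius_um + 2 * config.cell_radius(self.epithelial_type)
        if self.n_asm:
            r += self.asm_ring_um + 2 * config.cell_radius(self.asm_type)
        return r


@dataclass
class VesselSpec:
    """Arterial cross-section: endothelial ring, vascular-smooth-muscle
    ring, and an outer ring of immune slots occupied with probability
    ``immune_occupancy``.  Occupied slots are tagged artery-close and their
    marker draws are multiplied by ``immune_marker_scale`` (the planted
    differential signal, e.g. CD90/HLA-DR up, CD163/MRC1 down)."""

    name: str
    center_um: tuple
    endothelial_radius_um: float
    n_endothelial: int
    endothelial_type: str = "endothelial"
    vsm_ring_um: float = 8.0
    n_vsm: int = 0
    vsm_type: str = "vascular smooth muscle"
    immune_slots: int = 0
    immune_occupancy: float = 1.0
    immune_ring_um: float = 10.0
    immune_type: str = "immune"
    immune_marker_scale: dict = dc_field(default_factory=dict)

    def immune_radius_um(self, config: "SyntheticConfig") -> float:
        r = self.endothelial_radius_um + 2 * config.cell_radius(self.endothelial_type)
        if self.n_vsm:
            r += self.vsm_ring_um + 2 * config.cell_radius(self.vsm_type)
        return r + self.immune_ring_um

    def outer_radius_um(self, config: "SyntheticConfig") -> float:
        if not self.immune_slots:
            r = self.endothelial_radius_um + 2 * config.cell_radius(self.endothelial_type)
            if self.n_vsm:
                r += self.vsm_ring_um + 2 * config.cell_radius(self.vsm_type)
            return r
        return self.immune_radius_um(config) + 2 * config.cell_radius(self.immune_type)


@dataclass
class DomainSpec:
    """Vertical band of the field with its own cell-type mixture; used to
    plant spatial domains that only neighborhood-aware clustering can
    recover when the mixtures share cell types."""

    name: str
    x_fraction: tuple
    composition: dict
    count: int = 0


@dataclass
class SyntheticConfig:
    field_size_um: tuple = (500.0, 500.0)
    pixel_size_um: float = 0.51
    cell_types: list = dc_field(default_factory=list)
    airways: list = dc_field(default_factory=list)
    vessels: list = dc_field(default_factory=list)
    domains: list = dc_field(default_factory=list)
    background: dict = dc_field(default_factory=dict)
    noise_sd: float = 0.0
    poisson_noise: bool = False
    cytoplasm_rim_um: float = 3.0
    membrane_thickness_um: float = 1.2
    min_spacing_um: float = 0.0  # 0 -> derived from largest cell body
    dapi_mean: float = 150.0
    epcam_mean: float = 120.0
    ki67_positive_mean: float = 80.0
    ki67_baseline_mean: float = 5.0
    week: float = 6.0

    def __post_init__(self) -> None:
        self._types = {t.name: t for t in self.cell_types}

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.field_size_um[0] <= 0 or self.field_size_um[1] <= 0:
            raise ValueError("field size must be positive")
        for t in self.cell_types:
            t.validate()
        for v in self.vessels:
            if not 0.0 <= v.immune_occupancy <= 1.0:
                raise ValueError(f"vessel {v.name!r}: immune occupancy must be in [0, 1]")
        for d in self.domains:
            for name in d.composition:
                if name not in self._types:
                    raise ValueError(f"domain {d.name!r} references unknown cell type {name!r}")
        w, h = self.field_size_um
        for s in list(self.airways) + list(self.vessels):
            r = s.outer_radius_um(self)
            cx, cy = s.center_um
            if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
                raise ValueError(f"structure {s.name!r} does not fit inside the field")

    def cell_type(self, name: str) -> CellTypeSpec:
        self._types = {t.name: t for t in self.cell_types}
        return self._types[name]

    def cell_radius(self, type_name: str) -> float:
        """Full cell-body radius (nucleus + cytoplasmic rim) in um."""
        return self.cell_type(type_name).nucleus_radius_um + self.cytoplasm_rim_um

    def spacing(self) -> float:
        if self.min_spacing_um > 0:
            return self.min_spacing_um
        if not self.cell_types:
            return 1.0
        rmax = max(self.cell_radius(t.name) for t in self.cell_types)
        return 2.0 * rmax + 1.0

    def channel_names(self) -> list:
        names = ["DAPI", "EPCAM"]
        seen = set(names)
        for t in self.cell_types:
            for m in t.markers:
                if m not in seen:
                    names.append(m)
                    seen.add(m)
        for v in self.vessels:
            for m in v.immune_marker_scale:
                if m not in seen:
                    names.append(m)
                    seen.add(m)
        if "Ki67" not in seen and any(t.proliferation_rate > 0 for t in self.cell_types):
            names.append("Ki67")
        return names


@dataclass
class SyntheticGroundTruth:
    """Planted cells plus the structure registry.

    ``cells`` columns: cell_id, cell_type, x_um, y_um, nucleus_radius_um,
    cell_radius_um, proliferating, domain, tag.  ``structures`` is a list of
    dicts with name, kind, center_um and the relevant radii so that every
    geometric tag can be recomputed from the registry alone.
    """

    cells: pd.DataFrame
    structures: list
    config: SyntheticConfig


class _SpacedSampler:
    """Grid-hashed rejection sampler enforcing a minimum centre spacing."""

    def __init__(self, width: float, height: float, spacing: float):
        self.w, self.h, self.spacing = width, height, spacing
        self.cell = max(spacing, 1e-6)
        self.grid: dict = {}

    def _key(self, x: float, y: float) -> tuple:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float) -> bool:
        kx, ky = self._key(x, y)
        s2 = self.spacing * self.spacing
        for i in range(kx - 1, kx + 2):
            for j in range(ky - 1, ky + 2):
                for (px, py) in self.grid.get((i, j), ()):
                    dx, dy = px - x, py - y
                    if dx * dx + dy * dy < s2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.grid.setdefault(self._key(x, y), []).append((x, y))

    def sample(self, rng, n: int, xlo: float, xhi: float, context: str,
               margin: float, max_tries_per_cell: int = 300) -> np.ndarray:
        pts = np.empty((n, 2))
        placed = 0
        tries = 0
        budget = max(1000, n * max_tries_per_cell)
        while placed < n:
            if tries >= budget:
                raise PackingError(
                    f"could not place {n} cells in {context}: "
                    f"placed {placed} after {tries} attempts "
                    f"(density too high for spacing {self.spacing:.2f} um)"
                )
            x = rng.uniform(xlo + margin, xhi - margin)
            y = rng.uniform(margin, self.h - margin)
            tries += 1
            if self.ok(x, y):
                self.add(x, y)
                pts[placed] = (x, y)
                placed += 1
        return pts


def _ring_points(center, radius, n, phase=0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / max(n, 1)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def _disk_fill_points(center, radius, n) -> np.ndarray:
    """Deterministic sunflower layout of n points inside a disk."""
    k = np.arange(1, n + 1)
    r = radius * np.sqrt((k - 0.5) / n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ang = k * golden
    return np.column_stack([center[0] + r * np.cos(ang),
                            center[1] + r * np.sin(ang)])


def generate_ground_truth(config: SyntheticConfig, seed: int) -> SyntheticGroundTruth:
    """Place every planted cell and build the structure registry.

    Deterministic for a given (config, seed).  Structure cells are laid out
    on exact rings/disks; free cells are rejection-sampled with the
    configured minimum spacing.  Raises :class:`PackingError` (naming the
    offending region) when a requested density cannot be met.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    w, h = config.field_size_um
    spacing = config.spacing()
    sampler = _SpacedSampler(w, h, spacing)

    rows = []  # (type, x, y, domain, tag)
    structures = []

    def add_cell(type_name, x, y, domain, tag):
        rows.append((type_name, float(x), float(y), domain, tag))
        sampler.add(x, y)

    def domain_of(x):
        for d in config.domains:
            if d.x_fraction[0] * w <= x <= d.x_fraction[1] * w:
                return d.name
        return "tissue"

    # --- anatomical structures first (their geometry is exact) ---
    for a in config.airways:
        epi_r = config.cell_radius(a.epithelial_type)
        if a.filled:
            pts = _disk_fill_points(a.center_um, max(a.lumen_radius_um - epi_r, epi_r), a.n_epithelial)
        else:
            pts = _ring_points(a.center_um, a.lumen_radius_um + epi_r, a.n_epithelial)
        for (x, y) in pts:
            add_cell(a.epithelial_type, x, y, domain_of(x), f"airway:{a.name}")
        if a.n_asm:
            asm_radius = a.lumen_radius_um + 2 * epi_r + a.asm_ring_um
            for (x, y) in _ring_points(a.center_um, asm_radius, a.n_asm, phase=0.1):
                add_cell(a.asm_type, x, y, domain_of(x), f"airway-asm:{a.name}")
        structures.append({
            "name": a.name,
            "kind": "airway-filled" if a.filled else "airway",
            "center_um": tuple(a.center_um),
            "lumen_radius_um": a.lumen_radius_um,
            "outer_radius_um": a.outer_radius_um(config),
        })

    for v in config.vessels:
        endo_r = config.cell_radius(v.endothelial_type)
        ring = v.endothelial_radius_um + endo_r
        for (x, y) in _ring_points(v.center_um, ring, v.n_endothelial):
            add_cell(v.endothelial_type, x, y, domain_of(x), f"vessel:{v.name}")
        if v.n_vsm:
            vsm_radius = v.endothelial_radius_um + 2 * endo_r + v.vsm_ring_um
            for (x, y) in _ring_points(v.center_um, vsm_radius, v.n_vsm, phase=0.15):
                add_cell(v.vsm_type, x, y, domain_of(x), f"vessel-vsm:{v.name}")
        imm_radius = v.immune_radius_um(config)
        occupied = rng.random(v.immune_slots) < v.immune_occupancy
        slot_pts = _ring_points(v.center_um, imm_radius, v.immune_slots, phase=0.3)
        for (x, y), occ in zip(slot_pts, occupied):
            if occ:
                add_cell(v.immune_type, x, y, domain_of(x), ARTERY_CLOSE_TAG)
        structures.append({
            "name": v.name,
            "kind": "vessel",
            "center_um": tuple(v.center_um),
            "endothelial_radius_um": v.endothelial_radius_um,
            "immune_radius_um": imm_radius,
            "outer_radius_um": v.outer_radius_um(config),
        })

    # --- free cells: keep a margin to the border and to structures ---
    margin = max((config.cell_radius(t.name) for t in config.cell_types), default=1.0)
    if config.domains:
        for d in config.domains:
            names = list(d.composition)
            probs = np.asarray([d.composition[n] for n in names], dtype=float)
            probs = probs / probs.sum()
            pts = sampler.sample(rng, d.count, d.x_fraction[0] * w, d.x_fraction[1] * w,
                                 f"domain {d.name!r}", margin)
            picks = rng.choice(len(names), size=d.count, p=probs)
            for (x, y), k in zip(pts, picks):
                rows.append((names[k], float(x), float(y), d.name, ""))
    for t in config.cell_types:
        if t.count > 0:
            pts = sampler.sample(rng, t.count, 0.0, w, f"cell type {t.name!r}", margin)
            for (x, y) in pts:
                rows.append((t.name, float(x), float(y), domain_of(x), ""))

    if not rows:
        cells = pd.DataFrame(columns=["cell_id", "cell_type", "x_um", "y_um",
                                      "nucleus_radius_um", "cell_radius_um",
                                      "proliferating", "domain", "tag"])
        return SyntheticGroundTruth(cells, structures, config)

    cells = pd.DataFrame(rows, columns=["cell_type", "x_um", "y_um", "domain", "tag"])
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))
    cells["nucleus_radius_um"] = [config.cell_type(t).nucleus_radius_um for t in cells["cell_type"]]
    cells["cell_radius_um"] = cells["nucleus_radius_um"] + config.cytoplasm_rim_um
    rates = np.asarray([config.cell_type(t).proliferation_rate for t in cells["cell_type"]])
    cells["proliferating"] = rng.random(len(cells)) < rates
    return SyntheticGroundTruth(cells, structures, config)


def _lognormal(rng, mean, sigma, size=None):
    """Mean-preserving log-normal: E[X] = mean for any sigma; sigma=0 -> mean."""
    mean = np.asarray(mean, dtype=float)
    if sigma == 0:
        return mean if size is None else np.broadcast_to(mean, size).copy()
    with np.errstate(divide="ignore"):
        mu = np.where(mean > 0, np.log(np.where(mean > 0, mean, 1.0)) - 0.5 * sigma ** 2, -np.inf)
    draw = np.exp(rng.normal(mu, sigma, size=size))
    return np.where(np.isfinite(draw), draw, 0.0)


def _cell_marker_values(gt: SyntheticGroundTruth, markers: list, rng) -> np.ndarray:
    """Per-cell marker intensities (n_cells x n_markers), before background.

    Applies the Ki67 high mode for proliferating cells and the per-vessel
    marker scaling for artery-close immune cells.
    """
    config = gt.config
    cells = gt.cells
    n = len(cells)
    out = np.zeros((n, len(markers)))
    scale_by_vessel = {v.name: v.immune_marker_scale for v in config.vessels}
    # one shared scale map is typical; tags only say artery-close, so apply the
    # union of vessel scalings (configs in practice use one map for all vessels)
    merged_scale: dict = {}
    for m in scale_by_vessel.values():
        merged_scale.update(m)
    is_artery_close = (cells["tag"] == ARTERY_CLOSE_TAG).to_numpy()
    prolif = cells["proliferating"].to_numpy()
    for j, marker in enumerate(markers):
        means = np.zeros(n)
        disps = np.zeros(n)
        for t in config.cell_types:
            sel = (cells["cell_type"] == t.name).to_numpy()
            if marker == "DAPI":
                means[sel] = config.dapi_mean
            elif marker == "EPCAM":
                means[sel] = config.epcam_mean if t.epithelial else t.markers.get(marker, 0.0)
            else:
                means[sel] = t.markers.get(marker, 0.0)
            disps[sel] = t.dispersion
        if marker == "Ki67":
            # continuous bimodal Ki67: planted high mode for proliferating
            # cells, low baseline otherwise (unless the type sets its own)
            base = np.where(means > 0, means, config.ki67_baseline_mean)
            means = np.where(prolif, config.ki67_positive_mean, base)
        if marker in merged_scale:
            means = np.where(is_artery_close, means * merged_scale[marker], means)
        # draw per-cell with that cell's dispersion (vectorized over the
        # distinct dispersion values, which are few)
        for s in np.unique(disps):
            sel = disps == s
            out[sel, j] = _lognormal(rng, means[sel], float(s), size=int(sel.sum()))
    return out


def render_multiplex_image(gt: SyntheticGroundTruth, config: SyntheticConfig | None = None,
                           seed: int = 0):
    """Rasterize the ground truth into a channel stack plus true label mask.

    DAPI is drawn on every nucleus, EPCAM as a membrane ring on epithelial
    cells, lineage markers as filled cell bodies.  Gaussian (optionally
    Poisson) noise is applied after signal synthesis.  Returns
    (:class:`pulmoplex.io.MultiplexImage`, int32 label array).
    """
    from .io import MultiplexImage

    config = config or gt.config
    px = config.pixel_size_um
    min_nucleus = min((t.nucleus_radius_um for t in config.cell_types), default=4.0)
    if min_nucleus / px < 2.0:
        raise ValueError(
            f"pixel size {px} um/px too coarse: smallest nucleus "
            f"({min_nucleus} um) spans < 2 px"
        )
    W = int(round(config.field_size_um[0] / px))
    H = int(round(config.field_size_um[1] / px))
    channels = config.channel_names()
    data = np.zeros((len(channels), H, W), dtype=np.float32)
    labels = np.zeros((H, W), dtype=np.int32)

    rng = np.random.default_rng(seed)
    values = _cell_marker_values(gt, channels, rng)
    chan_index = {c: i for i, c in enumerate(channels)}
    epithelial = {t.name: t.epithelial for t in config.cell_types}
    mem_px = max(config.membrane_thickness_um / px, 1.0)

    cells = gt.cells
    for i in range(len(cells)):
        row = cells.iloc[i]
        cx, cy = row["x_um"] / px, row["y_um"] / px
        r_nuc = row["nucleus_radius_um"] / px
        r_cell = row["cell_radius_um"] / px
        c0, c1 = max(int(cx - r_cell) - 1, 0), min(int(cx + r_cell) + 2, W)
        r0, r1 = max(int(cy - r_cell) - 1, 0), min(int(cy + r_cell) + 2, H)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
        body = d2 <= r_cell ** 2
        nucleus = d2 <= r_nuc ** 2
        membrane = body & (d2 >= (r_cell - mem_px) ** 2)
        labels[r0:r1, c0:c1][body] = row["cell_id"]
        vals = values[i]
        for c, idx in chan_index.items():
            v = vals[idx]
            if v <= 0:
                continue
            region = data[idx, r0:r1, c0:c1]
            if c == "DAPI":
                region[nucleus] = np.maximum(region[nucleus], v)
            elif c == "EPCAM" and epithelial.get(row["cell_type"], False):
                region[membrane] = np.maximum(region[membrane], v)
            elif c not in ("DAPI", "EPCAM"):
                region[body] = np.maximum(region[body], v)

    for c, idx in chan_index.items():
        data[idx] += config.background.get(c, 0.0)
    if config.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float32)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape).astype(np.float32)
    np.clip(data, 0.0, None, out=data)
    return MultiplexImage(channels=channels, data=data, pixel_size_um=px), labels


def emit_cell_table(gt: SyntheticGroundTruth, config: SyntheticConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-cell intensity table drawn directly from the planted model,
    bypassing segmentation; one row per ground-truth cell."""
    config = config or gt.config
    if len(gt.cells) == 0:
        raise ValueError("ground truth is empty")
    rng = np.random.default_rng(seed)
    markers = config.channel_names()
    values = _cell_marker_values(gt, markers, rng)
    px = config.pixel_size_um
    area_um2 = np.pi * gt.cells["cell_radius_um"].to_numpy() ** 2
    table = pd.DataFrame({
        "cell_id": gt.cells["cell_id"].to_numpy(),
        "x_um": gt.cells["x_um"].to_numpy(),
        "y_um": gt.cells["y_um"].to_numpy(),
        "area_px": area_um2 / px ** 2,
        "area_um2": area_um2,
        "week": config.week,
    })
    for j, m in enumerate(markers):
        table[m] = values[:, j] + config.background.get(m, 0.0)
    return table
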