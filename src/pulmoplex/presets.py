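"""Default study conditions for the synthetic generator and the default
annotation rulebook for the 30-plex developing-lung panel.

The marker profiles encode the panel's lineage logic: EPCAM/PanCK/CDH1 on
epithelium split by SOX2 (proximal airway) vs SOX9 (distal tip), CD31/
CD144/CLDN5 on endothelium, PDPN on lymphatic endothelium, ACTA2 on
smooth muscle (vascular smooth muscle additionally CD90-high), DCN/VIM/
COL1A1 on mesenchyme, CD45 on immune cells with CD68/CD163/MRC1
(macrophage), CD3 (ILC & T), CD19 (B), CD56 (NK) and HLA-DR (dendritic)
subsets, CD56/NCAM1 on neuronal cells, and SOX9 without EPCAM on
chondroblasts.  Cell-type fractions follow the overall composition
reported for first-trimester lung (mesenchymal 33.9%, endothelial 24.6%,
SOX2-high epithelial 13.1%, SOX9-high epithelial 9.7%, airway smooth
muscle 9.2%, immune 4.8%, lymphatic endothelial 2.1%, neuronal 1.1%,
vascular smooth muscle 0.8%, chondroblasts 0.7%), and per-type
proliferation rates follow the reported week-resolved Ki67 fractions
(e.g. 73% of SOX9-high epithelium vs 15% of airway smooth muscle at
week 6, overall 14% at week 13).
"""

from __future__ import annotations

from .phenotyping import AnnotationRulebook, Rule
from .synthetic import (AirwaySpec, CellTypeSpec, DomainSpec, SyntheticConfig,
                        VesselSpec)

__all__ = [
    "MAIN_COMPOSITION",
    "PROLIFERATION_RATES",
    "cell_type_specs",
    "default_rulebook",
    "study_table_config",
    "segmentation_benchmark_config",
    "domain_scene_config",
    "vessel_scene_config",
]

#: overall main-cell-type composition (percent)
MAIN_COMPOSITION = {
    "mesenchymal": 33.9,
    "endothelial": 24.6,
    "SOX2-high epithelial": 13.1,
    "SOX9-high epithelial": 9.7,
    "airway smooth muscle": 9.2,
    "immune": 4.8,
    "lymphatic endothelial": 2.1,
    "neuronal": 1.1,
    "vascular smooth muscle": 0.8,
    "chondroblast": 0.7,
}

#: marker intensity means per type (arbitrary units, pre-background)
_PROFILES = {
    "mesenchymal": {"DCN": 60, "VIM": 70, "COL1A1": 50, "CD90": 35},
    "endothelial": {"CD31": 70, "CD144": 60, "CD34": 50, "CLDN5": 40, "CD90": 25},
    "SOX2-high epithelial": {"SOX2": 80, "PanCK": 50, "CDH1": 50, "TTF1": 30, "CD44": 15},
    "SOX9-high epithelial": {"SOX9": 80, "PanCK": 50, "CDH1": 50, "TTF1": 30, "CD44": 40},
    "airway smooth muscle": {"ACTA2": 90, "VIM": 25},
    "immune": {"CD45": 80, "CD44": 30, "CD68": 25, "HLA-DR": 20},
    "lymphatic endothelial": {"PDPN": 70, "CD31": 45},
    "neuronal": {"CD56": 70, "VIM": 25},
    "vascular smooth muscle": {"ACTA2": 75, "CD90": 60},
    "chondroblast": {"SOX9": 70, "COL1A1": 60},
}
_EPITHELIAL = {"SOX2-high epithelial", "SOX9-high epithelial"}

#: immune subtypes used by the immune subanalysis scenes
IMMUNE_PROFILES = {
    "immune/macrophage": {"CD45": 80, "CD68": 70, "CD163": 60, "MRC1": 50, "HLA-DR": 30},
    "immune/ILC-T": {"CD45": 80, "CD3": 70, "CD4": 40, "CD44": 40},
    "immune/B": {"CD45": 80, "CD19": 70},
    "immune/NK": {"CD45": 80, "CD56": 70},
    "immune/dendritic": {"CD45": 70, "HLA-DR": 80, "CD44": 30},
}

#: per-week, per-type proliferation rates (chosen so the composition-
#: weighted overall rate matches the week's Ki67 percentile threshold)
PROLIFERATION_RATES = {
    6.0: {"mesenchymal": 0.25, "endothelial": 0.30, "SOX2-high epithelial": 0.55,
          "SOX9-high epithelial": 0.73, "airway smooth muscle": 0.15, "immune": 0.25,
          "lymphatic endothelial": 0.20, "neuronal": 0.20,
          "vascular smooth muscle": 0.15, "chondroblast": 0.20},
    13.0: {"mesenchymal": 0.13, "endothelial": 0.17, "SOX2-high epithelial": 0.12,
           "SOX9-high epithelial": 0.18, "airway smooth muscle": 0.07, "immune": 0.15,
           "lymphatic endothelial": 0.05, "neuronal": 0.05,
           "vascular smooth muscle": 0.07, "chondroblast": 0.05},
}

#: per-week composition used for proliferation scenes; week 6 is strongly
#: mesenchymal, week 13 resembles the overall composition
WEEK_COMPOSITION = {
    6.0: {"mesenchymal": 60.0, "endothelial": 8.5, "SOX2-high epithelial": 6.0,
          "SOX9-high epithelial": 10.5, "airway smooth muscle": 6.0, "immune": 3.0,
          "lymphatic endothelial": 0.5, "neuronal": 0.5,
          "vascular smooth muscle": 2.0, "chondroblast": 3.0},
    13.0: {"mesenchymal": 40.0, "endothelial": 22.0, "SOX2-high epithelial": 9.6,
           "SOX9-high epithelial": 12.0, "airway smooth muscle": 9.0, "immune": 6.0,
           "lymphatic endothelial": 1.0, "neuronal": 0.2,
           "vascular smooth muscle": 0.1, "chondroblast": 0.1},
}


def cell_type_specs(composition=None, dispersion: float = 0.25,
                    rates=None, counts_total: int = 0) -> list:
    """CellTypeSpec list for the named composition (percent shares).

    When ``counts_total`` > 0 the shares are converted to exact counts."""
    composition = composition or MAIN_COMPOSITION
    rates = rates or {}
    specs = []
    total = sum(composition.values())
    for name, share in composition.items():
        profile = _PROFILES.get(name) or IMMUNE_PROFILES.get(name)
        if profile is None:
            raise KeyError(f"no marker profile for cell type {name!r}")
        count = int(round(counts_total * share / total)) if counts_total else 0
        specs.append(CellTypeSpec(
            name=name, markers=dict(profile), count=count, dispersion=dispersion,
            proliferation_rate=rates.get(name, 0.0),
            epithelial=name in _EPITHELIAL,
        ))
    return specs


def default_rulebook() -> AnnotationRulebook:
    """Ordered marker rules reproducing the panel's annotation logic."""
    return AnnotationRulebook(rules=[
        Rule("immune", high=("CD45",)),
        Rule("lymphatic endothelial", high=("PDPN",)),
        Rule("endothelial", high=("CD31", "CD144")),
        Rule("vascular smooth muscle", high=("ACTA2", "CD90")),
        Rule("airway smooth muscle", high=("ACTA2",)),
        Rule("SOX2-high epithelial", high=("SOX2", "CDH1")),
        Rule("SOX9-high epithelial", high=("SOX9", "CDH1")),
        Rule("chondroblast", high=("SOX9",)),
        Rule("neuronal", high=("CD56",)),
        Rule("mesenchymal", high=("DCN", "VIM")),
    ])


def immune_rulebook() -> AnnotationRulebook:
    return AnnotationRulebook(rules=[
        Rule("macrophage", high=("CD68", "CD163")),
        Rule("ILC & T", high=("CD3",)),
        Rule("B", high=("CD19",)),
        Rule("NK", high=("CD56",)),
        Rule("dendritic", high=("HLA-DR",)),
    ])


def study_table_config(week: float = 6.0, n_cells: int = 10000,
                       composition=None, with_rates: bool = True,
                       dispersion: float = 0.25) -> SyntheticConfig:
    """Cell-table generator matching the study's per-week conditions."""
    comp = composition or WEEK_COMPOSITION.get(week, MAIN_COMPOSITION)
    rates = PROLIFERATION_RATES.get(week, {}) if with_rates else {}
    # field sized for ~1 cell per 150 um^2 so radius-50 graphs are dense
    side = max((n_cells * 150.0) ** 0.5, 100.0)
    return SyntheticConfig(
        field_size_um=(side, side),
        cell_types=cell_type_specs(comp, dispersion=dispersion, rates=rates,
                                   counts_total=n_cells),
        background={m: 2.0 for m in ("DAPI", "EPCAM")},
        week=week,
        min_spacing_um=7.0,
    )


def segmentation_benchmark_config(n_cells: int = 3000, noise_frac: float = 0.05,
                                  pixel_size_um: float = 0.51) -> SyntheticConfig:
    """Default segmentation benchmark: ~n non-touching cells, Gaussian
    noise with s.d. a fraction of the typical signal level."""
    comp = {"mesenchymal": 60.0, "SOX2-high epithelial": 40.0}
    side = (n_cells * 450.0) ** 0.5
    cfg = SyntheticConfig(
        field_size_um=(side, side),
        pixel_size_um=pixel_size_um,
        cell_types=cell_type_specs(comp, dispersion=0.15, counts_total=n_cells),
        background={"DAPI": 5.0, "EPCAM": 5.0},
        noise_sd=noise_frac * 150.0,
        cytoplasm_rim_um=3.0,
    )
    return cfg


def domain_scene_config(n_cells: int = 10000, mixing: bool = True) -> SyntheticConfig:
    """Three planted spatial domains as vertical bands.

    With ``mixing`` the bands share the same cell types in different
    proportions, so expression-only clustering cannot recover the bands
    and the neighborhood-augmented features are required.
    """
    if mixing:
        bands = [
            ("stroma", (0.0, 1 / 3), {"mesenchymal": 0.75, "endothelial": 0.20, "immune": 0.05}),
            ("vascular", (1 / 3, 2 / 3), {"mesenchymal": 0.20, "endothelial": 0.75, "immune": 0.05}),
            ("immune-rich", (2 / 3, 1.0), {"mesenchymal": 0.20, "endothelial": 0.05, "immune": 0.75}),
        ]
    else:
        bands = [
            ("stroma", (0.0, 1 / 3), {"mesenchymal": 1.0}),
            ("vascular", (1 / 3, 2 / 3), {"endothelial": 1.0}),
            ("immune-rich", (2 / 3, 1.0), {"immune": 1.0}),
        ]
    comp = {"mesenchymal": 1, "endothelial": 1, "immune": 1}
    side = max((n_cells * 150.0) ** 0.5, 100.0)
    per = n_cells // 3
    # dispersion 0.7: realistically heavy-tailed IF intensities whose type
    # distributions overlap, the regime in which expression-only
    # clustering cannot recover the planted bands
    return SyntheticConfig(
        field_size_um=(side, side),
        cell_types=cell_type_specs(comp, dispersion=0.7),
        domains=[DomainSpec(n, fr, c, count=per) for (n, fr, c) in bands],
        min_spacing_um=7.0,
        week=6.0,
    )


def vessel_scene_config(n_vessels: int = 3, n_free: int = 1200,
                        field_um: float = 700.0, week: float = 11.0,
                        image_ready: bool = False) -> SyntheticConfig:
    """Arterial vessels ringed by immune cells with the planted
    differential profile (CD90/HLA-DR up, CD163/MRC1 down artery-close).

    With ``image_ready`` the geometry is sized so the rendered CD144 and
    ACTA2 rings overlap in an artery core well above the 2000 px size
    filter at 0.51 um/px.
    """
    comp = {"mesenchymal": 0.40, "endothelial": 0.15, "immune": 0.25,
            "vascular smooth muscle": 0.05, "airway smooth muscle": 0.15}
    specs = cell_type_specs(comp, dispersion=0.25, counts_total=n_free)
    for s in specs:
        if s.name == "immune":
            s.markers.update({"CD90": 30, "HLA-DR": 40, "CD163": 50, "MRC1": 45})
    scale = {"CD90": 2.5, "HLA-DR": 2.5, "CD163": 0.35, "MRC1": 0.35}
    vessels = []
    margin = 120.0
    import numpy as np
    centers = np.linspace(margin, field_um - margin, max(n_vessels, 1))
    for k in range(n_vessels):
        vessels.append(VesselSpec(
            name=f"artery-{k}",
            center_um=(float(centers[k]), float(centers[k % len(centers)])),
            endothelial_radius_um=26.0, n_endothelial=22,
            vsm_ring_um=4.0, n_vsm=26,
            immune_slots=18, immune_occupancy=1.0, immune_ring_um=10.0,
            immune_marker_scale=dict(scale),
        ))
    cfg = SyntheticConfig(
        field_size_um=(field_um, field_um),
        cell_types=specs,
        vessels=vessels,
        background={m: 2.0 for m in ("DAPI", "EPCAM", "ACTA2", "CD144", "CD45")},
        week=week,
        min_spacing_um=7.0,
        noise_sd=2.0 if image_ready else 0.0,
    )
    return cfg
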