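"""End-to-end orchestration: bundles -> features -> matrix -> detection.

The per-subject feature chain (smoothing at 10 mm FWHM where appropriate,
doughnut radius 6 mm, LCD radius 25 mm) matches the detection method's
defaults; geodesic neighbourhood tables are computed once on a template
subject (all subjects in a cohort share mesh topology, and doughnut discs
live on the inflated surface, which is common to the cohort) and reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bundle import SubjectBundle
from .classifier import LoocvFold, loocv, select_hidden_nodes
from .clustering import (DetectionResult, cluster_components,
                         cohort_sensitivity, detection_verdict,
                         select_putative_lesion, threshold_top_fraction)
from .features import (FLAIR_NAMES, FLAIR_POSITIONS, cortical_thickness,
                       doughnut_map, gw_contrast, local_cortical_deformation,
                       sample_intensity, vertex_normals)
from .geodesics import chord_graph, disc_annulus_table, disc_table
from .mesh import SurfaceMesh, VertexMap, build_adjacency, vertex_areas
from .normalization import (CANONICAL_COLUMNS, ControlStats,
                            compute_control_stats, control_normalized_keys,
                            assemble_feature_matrix, normalize_subject)
from .smoothing import cotan_weights, smooth_values

log = logging.getLogger(__name__)

HEMIS = ("left", "right")

SMOOTHED_FEATURES = ("thickness", "gw_contrast", *FLAIR_NAMES)
DOUGHNUT_FEATURES = ("thickness", "gw_contrast", *FLAIR_NAMES)


@dataclass
class PipelineConfig:
    """Tunable parameters of the detection pipeline."""

    fwhm: float = 10.0                 # mm, feature + doughnut smoothing
    doughnut_radius: float = 6.0       # mm
    lcd_radius: float = 25.0           # mm
    neighborhood_surface: str = "inflated"  # where doughnut discs live
    threshold_fraction: float = 0.05
    min_cluster_size: int = 200        # vertices (full-resolution default)
    min_cluster_area_mm2: float | None = 100.0  # ~1 cm^2; None -> vertex mode
    per_hemisphere_threshold: bool = False
    variance_threshold: float = 0.99   # PCA explained-variance rule
    hidden_nodes: int | str = "auto"
    balanced: bool = False
    seed: int = 0


@dataclass
class CohortContext:
    """Geometry shared by a cohort: neighbourhood tables and adjacency."""

    doughnut_tables: dict[str, tuple]
    lcd_tables: dict[str, tuple]
    smooth_weights: dict[tuple[str, str], sp.csr_matrix]
    areas: dict[tuple[str, str], np.ndarray]
    adjacency: dict[str, sp.csr_matrix]
    n_vertices: dict[str, int]


def build_context(template: SubjectBundle, config: PipelineConfig
                  ) -> CohortContext:
    """Precompute geodesic tables and operators from a template subject.

    Valid for every subject sharing the template's mesh topology (the
    doughnut discs are defined on the inflated surface and the LCD discs on
    the template pial; per-subject pial deviations are sub-millimetre, far
    below the 25 mm neighbourhood scale).
    """
    doughnut_tables, lcd_tables, weights, areas, adjacency, nvert = \
        {}, {}, {}, {}, {}, {}
    for hemi in HEMIS:
        infl = template.mesh(hemi, config.neighborhood_surface)
        graph = chord_graph(infl)
        doughnut_tables[hemi] = disc_annulus_table(
            infl, config.doughnut_radius, graph=graph)
        pial = template.mesh(hemi, "pial")
        lcd_tables[hemi] = disc_table(pial, config.lcd_radius,
                                      graph=chord_graph(pial))
        for kind in ("white", "pial", "inflated"):
            mesh = template.mesh(hemi, kind)
            weights[(hemi, kind)] = cotan_weights(mesh)
            areas[(hemi, kind)] = vertex_areas(mesh).values
        adjacency[hemi] = build_adjacency(template.mesh(hemi, "white"))
        nvert[hemi] = template.mesh(hemi, "white").n_vertices
    return CohortContext(doughnut_tables, lcd_tables, weights, areas,
                         adjacency, nvert)


def extract_subject_features(bundle: SubjectBundle, config: PipelineConfig,
                             ctx: CohortContext
                             ) -> dict[tuple[str, str], np.ndarray]:
    """Raw (pre-normalization) per-vertex features for one subject."""
    raw: dict[tuple[str, str], np.ndarray] = {}
    for hemi in HEMIS:
        white = bundle.mesh(hemi, "white")
        pial = bundle.mesh(hemi, "pial")
        infl = bundle.mesh(hemi, config.neighborhood_surface)
        w_infl = ctx.smooth_weights[(hemi, config.neighborhood_surface)]
        a_infl = ctx.areas[(hemi, config.neighborhood_surface)]

        feats = {"thickness": cortical_thickness(white, pial).values}
        t1 = bundle.volumes[("T1", hemi)]
        flair = bundle.volumes[("FLAIR", hemi)]
        feats["gw_contrast"] = gw_contrast(t1, white, pial).values
        normals = vertex_normals(white)
        for name, pos in zip(FLAIR_NAMES, FLAIR_POSITIONS):
            feats[name] = sample_intensity(flair, white, pial, pos,
                                           normals=normals).values
        # smoothing on the inflated surface (neighbourhood template space)
        for name in SMOOTHED_FEATURES:
            feats[name] = smooth_values(feats[name], infl, config.fwhm,
                                        weights=w_infl, areas=a_infl)
        feats["sulc"] = bundle.maps[("sulc", hemi)]
        feats["curv"] = bundle.maps[("curv", hemi)]
        feats["lcd"] = local_cortical_deformation(
            pial, config.lcd_radius, table=ctx.lcd_tables[hemi]).values
        for name in DOUGHNUT_FEATURES:
            vm = VertexMap(feats[name], name, hemi)
            dn = doughnut_map(vm, infl, config.doughnut_radius,
                              fwhm=config.fwhm,
                              tables=ctx.doughnut_tables[hemi])
            feats[f"doughnut.{name}"] = dn.values
        for name, vals in feats.items():
            raw[(name, hemi)] = vals
    return raw


@dataclass
class CohortMatrix:
    matrix: pd.DataFrame
    stats: ControlStats
    context: CohortContext
    hidden_nodes: int
    #: per-subject step-2..4 maps (z-scored features + asymmetry, before
    #: control normalization), keyed by subject id
    normed_maps: dict[str, dict] = field(default_factory=dict)


def build_cohort_matrix(controls: list[SubjectBundle],
                        patients: list[SubjectBundle],
                        config: PipelineConfig) -> CohortMatrix:
    """Features + normalization + 28-column matrix for a whole cohort.

    Control statistics are computed once, from controls only; the PCA
    hidden-node rule runs on the controls' assembled features.
    """
    ctx = build_context(controls[0], config)
    rows = []
    control_normed = []
    normed_maps = {}
    for bundle in controls + patients:
        raw = extract_subject_features(bundle, config, ctx)
        masks = {h: bundle.cortex_mask(h) for h in HEMIS}
        normed = normalize_subject(raw, bundle.correspondence, masks)
        if bundle.group == "control":
            control_normed.append({k: normed[k] for k in normed
                                   if k[0] in control_normalized_keys()})
        normed_maps[bundle.subject_id] = normed
        rows.append((bundle.subject_id, bundle.group, normed, masks,
                     bundle.lesion))
    stats = compute_control_stats(control_normed)
    matrix = assemble_feature_matrix(rows, stats)
    control_X = matrix.loc[matrix["group"] == "control",
                           list(CANONICAL_COLUMNS)].to_numpy()
    if config.hidden_nodes == "auto":
        hidden = select_hidden_nodes(control_X, config.variance_threshold)
    else:
        hidden = int(config.hidden_nodes)
    return CohortMatrix(matrix, stats, ctx, hidden, normed_maps)


# ---------------------------------------------------------------------------
# detection on probability maps

def pooled_probability(prob_df: pd.DataFrame, ctx: CohortContext
                       ) -> np.ndarray:
    """Probability over the pooled (left then right) vertex index space;
    vertices without a probability (medial wall) get -inf."""
    n_left = ctx.n_vertices["left"]
    n = n_left + ctx.n_vertices["right"]
    pooled = np.full(n, -np.inf)
    for hemi, offset in (("left", 0), ("right", n_left)):
        part = prob_df[prob_df["hemisphere"] == hemi]
        pooled[part["vertex"].to_numpy() + offset] = \
            part["probability"].to_numpy()
    return pooled


def detect_lesion(subject: str, prob_df: pd.DataFrame, ctx: CohortContext,
                  config: PipelineConfig,
                  lesion: tuple[str, np.ndarray] | None = None
                  ) -> DetectionResult:
    """Threshold -> cluster -> select for one subject's probability map."""
    pooled = pooled_probability(prob_df, ctx)
    n_left = ctx.n_vertices["left"]
    cortex = np.flatnonzero(np.isfinite(pooled))
    adjacency = sp.block_diag(
        [ctx.adjacency["left"], ctx.adjacency["right"]]).tocsr()
    areas = np.concatenate([ctx.areas[("left", "white")],
                            ctx.areas[("right", "white")]])
    if config.per_hemisphere_threshold:
        surviving = []
        for hemi, offset in (("left", 0), ("right", n_left)):
            sub = cortex[(cortex >= offset) &
                         (cortex < offset + ctx.n_vertices[hemi])]
            keep = threshold_top_fraction(pooled[sub],
                                          config.threshold_fraction)
            surviving.append(sub[keep])
        surviving = np.concatenate(surviving)
    else:
        keep = threshold_top_fraction(pooled[cortex],
                                      config.threshold_fraction)
        surviving = cortex[keep]
    threshold_value = float(pooled[surviving].min())
    clusters = cluster_components(
        surviving, adjacency,
        min_cluster_size=config.min_cluster_size, areas=areas,
        min_area_mm2=config.min_cluster_area_mm2)
    result = select_putative_lesion(clusters, pooled, subject=subject,
                                    threshold_value=threshold_value,
                                    surviving=surviving)
    if lesion is not None:
        hemi, idx = lesion
        offset = 0 if hemi == "left" else n_left
        detection_verdict(result, np.asarray(idx) + offset)
    return result


@dataclass
class LoocvRun:
    folds: list[LoocvFold]
    sensitivity: float
    table: pd.DataFrame
    hidden_nodes: int


def run_loocv(controls: list[SubjectBundle], patients: list[SubjectBundle],
              config: PipelineConfig | None = None,
              feature_columns: tuple[str, ...] = CANONICAL_COLUMNS,
              cohort: CohortMatrix | None = None) -> LoocvRun:
    """Full study analogue: features, LOOCV classification, detection.

    Pass a prebuilt ``cohort`` to rerun with a different feature subset
    (e.g. the established-only columns) without re-extracting features.
    """
    config = config or PipelineConfig()
    if cohort is None:
        cohort = build_cohort_matrix(controls, patients, config)
    if feature_columns is CANONICAL_COLUMNS:
        hidden = cohort.hidden_nodes
    else:
        control_X = cohort.matrix.loc[cohort.matrix["group"] == "control",
                                      list(feature_columns)].to_numpy()
        hidden = select_hidden_nodes(control_X, config.variance_threshold) \
            if config.hidden_nodes == "auto" else int(config.hidden_nodes)
    lesions = {p.subject_id: p.lesion for p in patients}

    def detector(subject_id, prob_df):
        return detect_lesion(subject_id, prob_df, cohort.context, config,
                             lesion=lesions.get(subject_id))

    folds = loocv(cohort.matrix, hidden_nodes=hidden, seed=config.seed,
                  feature_columns=feature_columns, balanced=config.balanced,
                  detector=detector)
    sens, table = cohort_sensitivity([f.detection for f in folds])
    return LoocvRun(folds, sens, table, hidden)
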