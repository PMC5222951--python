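"""From probability maps to one putative lesion, and feature evaluation.

The detection rule: threshold the vertexwise probability map so only the
top 5% of cortex vertices survive, group survivors into neighbour-connected
clusters, discard clusters below the minimum size (200 vertices ~ 1 cm^2 at
full FreeSurfer resolution; an area-based mode keeps the ~1 cm^2 intent at
other mesh resolutions), and report the cluster with the highest mean
probability as the putative lesion.  Detection succeeds when that cluster
overlaps the manual lesion mask.  One cluster is always reported when any
survive the size filter, so specificity is undefined by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve


@dataclass
class Cluster:
    members: np.ndarray           # global vertex indices (pooled hemis)
    mean_probability: float
    size: int
    area_mm2: float | None = None


@dataclass
class DetectionResult:
    """Outcome of the cluster-selection rule for one subject."""

    subject: str
    threshold_value: float
    surviving: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)  # ranked, best first
    selected: int | None = None          # index into clusters (0 when any)
    verdict: bool | None = None          # overlap with lesion mask
    lesion_rank: int | None = None       # 1-based rank of first overlapping
    n_vertices: int = 0


def threshold_top_fraction(prob: np.ndarray, fraction: float = 0.05
                           ) -> np.ndarray:
    """Indices of the ceil(fraction * N) highest-probability vertices.

    Ties at the cutoff are broken toward the lower vertex index.  The
    surviving set depends only on ranks, so it is invariant under strictly
    monotone transforms of the map.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    prob = np.asarray(prob, dtype=np.float64)
    n = len(prob)
    k = int(np.ceil(fraction * n))
    order = np.lexsort((np.arange(n), -prob))
    if k < n and prob[order[k - 1]] == prob[order[k]]:
        warnings.warn("threshold_top_fraction: ties at the cutoff broken by "
                      "lower vertex index")
    return np.sort(order[:k])


def cluster_components(surviving: np.ndarray, adjacency: sp.csr_matrix,
                       min_cluster_size: int = 200,
                       areas: np.ndarray | None = None,
                       min_area_mm2: float | None = None) -> list[Cluster]:
    """Neighbour-connected components of the surviving set, size-filtered.

    ``adjacency`` is the 1-ring vertex adjacency over the pooled index
    space.  With ``min_area_mm2`` (and per-vertex ``areas``) the filter is
    areal instead of a vertex count.
    """
    surviving = np.asarray(surviving, dtype=np.int64)
    if len(surviving) == 0:
        return []
    sub = adjacency[surviving][:, surviving]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for c in range(n_comp):
        members = surviving[labels == c]
        area = float(areas[members].sum()) if areas is not None else None
        if min_area_mm2 is not None:
            if area is None:
                raise ValueError("min_area_mm2 requires per-vertex areas")
            if area < min_area_mm2:
                continue
        elif len(members) < min_cluster_size:
            continue
        clusters.append(Cluster(members=members, mean_probability=np.nan,
                                size=len(members), area_mm2=area))
    return clusters


def select_putative_lesion(clusters: list[Cluster], prob: np.ndarray,
                           subject: str = "", threshold_value: float = np.nan,
                           surviving: np.ndarray | None = None
                           ) -> DetectionResult:
    """Rank clusters by mean probability; the best is the putative lesion.

    Ties are broken toward the larger cluster, then the lower minimum
    vertex index.  An empty cluster list yields an explicit no-cluster
    result (``selected is None``), not an error.
    """
    prob = np.asarray(prob, dtype=np.float64)
    for cl in clusters:
        cl.mean_probability = float(prob[cl.members].mean())
    ranked = sorted(
        clusters,
        key=lambda cl: (-cl.mean_probability, -cl.size, int(cl.members.min())))
    return DetectionResult(
        subject=subject, threshold_value=threshold_value,
        surviving=surviving if surviving is not None else np.empty(0, int),
        clusters=ranked, selected=0 if ranked else None,
        n_vertices=len(prob))


def detection_verdict(result: DetectionResult,
                      lesion_vertices: np.ndarray) -> bool:
    """True iff the selected cluster overlaps the lesion mask.

    Also records the 1-based rank of the first lesion-overlapping cluster.
    """
    lesion_vertices = np.asarray(lesion_vertices, dtype=np.int64)
    result.lesion_rank = None
    for rank, cl in enumerate(result.clusters, start=1):
        if np.intersect1d(cl.members, lesion_vertices, assume_unique=False).size:
            result.lesion_rank = rank
            break
    result.verdict = result.lesion_rank == 1
    return result.verdict


def vertexwise_roc_auc(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC of per-vertex scores against binary labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, float))
    return fpr, tpr, float(sk_auc(fpr, tpr))


def cohort_sensitivity(results: list[DetectionResult]
                       ) -> tuple[float, pd.DataFrame]:
    """Detected fraction plus a per-subject table (verdict, lesion rank)."""
    if not results:
        raise ValueError("no detection results")
    table = pd.DataFrame({
        "subject": [r.subject for r in results],
        "detected": [bool(r.verdict) for r in results],
        "lesion_rank": [r.lesion_rank for r in results],
        "n_clusters": [len(r.clusters) for r in results],
        "top_cluster_size": [r.clusters[0].size if r.clusters else 0
                             for r in results],
    })
    return float(table["detected"].mean()), table
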