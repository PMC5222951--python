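"""Feature normalization, interhemispheric asymmetry, and matrix assembly.

The normalization chain mirrors standard surface-based lesion-detection
practice: (1) per-vertex feature quantification (already smoothed where
appropriate), (2) within-subject z-scoring, (3) vertex correspondence to a
symmetric template, (4) interhemispheric asymmetry of the z-maps, and
(5) per-vertex normalization of both z-maps and asymmetry maps by the
healthy-control cohort.  Doughnut maps stop after step 2 (they are already
local contrasts); sulcal depth and mean curvature are z-scored but not
control-normalized (kept as plain regional descriptors).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FLAIR_NAMES

log = logging.getLogger(__name__)

HEMIS = ("left", "right")

#: features that run through the full chain (z-score -> asymmetry ->
#: control normalization)
FULL_CHAIN_FEATURES: tuple[str, ...] = (
    "thickness", "gw_contrast", *FLAIR_NAMES, "lcd")

#: canonical 28-column order of the assembled feature matrix
CANONICAL_COLUMNS: tuple[str, ...] = (
    "thickness.z", "gw_contrast.z", "sulc.z", "curv.z",
    *(f"{n}.z" for n in FLAIR_NAMES),
    "lcd.z",
    "doughnut.thickness", "doughnut.gw_contrast",
    *(f"doughnut.{n}" for n in FLAIR_NAMES),
    "asym.thickness", "asym.gw_contrast",
    *(f"asym.{n}" for n in FLAIR_NAMES),
    "asym.lcd",
)

#: the previously established subset (no doughnut / LCD / asymmetry)
ESTABLISHED_COLUMNS: tuple[str, ...] = (
    "thickness.z", "gw_contrast.z", "sulc.z", "curv.z",
    *(f"{n}.z" for n in FLAIR_NAMES),
)

#: canonical columns carrying the novel features
NOVEL_COLUMNS: tuple[str, ...] = tuple(
    c for c in CANONICAL_COLUMNS if c not in ESTABLISHED_COLUMNS)

assert len(CANONICAL_COLUMNS) == 28


@dataclass
class CorrespondenceMap:
    """Bijective left-vertex -> right-vertex matching on the template."""

    left_to_right: np.ndarray

    def __post_init__(self) -> None:
        self.left_to_right = np.asarray(self.left_to_right, dtype=np.int64)
        n = len(self.left_to_right)
        if not np.array_equal(np.sort(self.left_to_right), np.arange(n)):
            raise ValueError("correspondence is not a bijection")

    @property
    def right_to_left(self) -> np.ndarray:
        inv = np.empty_like(self.left_to_right)
        inv[self.left_to_right] = np.arange(len(self.left_to_right))
        return inv

    @classmethod
    def identity(cls, n: int) -> "CorrespondenceMap":
        return cls(np.arange(n))


def intra_subject_zscore(values: np.ndarray,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Within-subject z-score over unmasked, finite vertices (ddof=1)."""
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.ones(len(values), dtype=bool)
    use = mask & np.isfinite(values)
    out = np.full_like(values, np.nan)
    if use.sum() < 2:
        warnings.warn("intra_subject_zscore: fewer than 2 usable vertices")
        out[use] = 0.0
        return out
    mu = values[use].mean()
    sd = values[use].std(ddof=1)
    if sd <= 0:
        warnings.warn("intra_subject_zscore: zero spread, returning zeros")
        out[use] = 0.0
        return out
    out[use] = (values[use] - mu) / sd
    return out


@dataclass
class ControlStats:
    """Per-vertex control-cohort mean and SD for each normalized feature.

    Keys are ``(feature_key, hemisphere)`` where ``feature_key`` is e.g.
    ``"thickness.z"`` or ``"asym.thickness"``.
    """

    mean: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    sd: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    n_controls: int = 0

    def features(self) -> list[str]:
        return sorted({k for k, _ in self.mean})


def compute_control_stats(control_maps: list[dict[tuple[str, str], np.ndarray]]
                          ) -> ControlStats:
    """Reduce a list of per-control ``{(feature_key, hemi): values}`` dicts."""
    if not control_maps:
        raise ValueError("no control subjects given")
    keys = set(control_maps[0])
    for m in control_maps[1:]:
        keys &= set(m)
    stats = ControlStats(n_controls=len(control_maps))
    for key in sorted(keys):
        stack = np.vstack([m[key] for m in control_maps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stats.mean[key] = np.nanmean(stack, axis=0)
            stats.sd[key] = np.nanstd(stack, axis=0, ddof=1)
    return stats


def control_normalize(values: np.ndarray, stats: ControlStats,
                      feature_key: str, hemisphere: str) -> np.ndarray:
    """Per-vertex z against the control cohort: (x - mean) / sd.

    Vertices whose control SD is below a floor of 1e-6 times the cohort
    median SD of that feature are set to 0 (near-constant vertices).
    """
    key = (feature_key, hemisphere)
    if key not in stats.mean:
        raise KeyError(f"control stats missing feature {key}")
    mean, sd = stats.mean[key], stats.sd[key]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        floor = 1e-6 * np.nanmedian(sd)
    ok = sd > max(floor, 0.0)
    out = np.full_like(np.asarray(values, float), np.nan)
    finite = np.isfinite(values) & np.isfinite(mean)
    out[finite & ok] = ((values - mean)[finite & ok]) / sd[finite & ok]
    n_floor = int((finite & ~ok).sum())
    if n_floor:
        log.info("control_normalize(%s/%s): %d vertices at SD floor -> 0",
                 feature_key, hemisphere, n_floor)
        out[finite & ~ok] = 0.0
    return out


class ControlNormalizer:
    """Sklearn-style transformer: per-column z against a control cohort.

    ``fit(X)`` learns per-column (per-vertex) mean and SD from control
    rows; ``transform(X)`` returns ``(X - mean) / sd`` with the same SD
    floor rule as :func:`control_normalize`.  Composes with sklearn
    pipelines for array-shaped workflows.
    """

    def fit(self, X: np.ndarray, y=None) -> "ControlNormalizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2D control matrix with >= 2 rows")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_ = np.nanmean(X, axis=0)
            self.sd_ = np.nanstd(X, axis=0, ddof=1)
            floor = 1e-6 * np.nanmedian(self.sd_)
        self.ok_ = self.sd_ > max(floor, 0.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} columns")
        out = np.zeros_like(X)
        out[:, self.ok_] = ((X - self.mean_)[:, self.ok_]
                            / self.sd_[self.ok_])
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "ControlNormalizer":
        return self


def interhemispheric_asymmetry(left_values: np.ndarray,
                               right_values: np.ndarray,
                               corr: CorrespondenceMap
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Ipsilateral-minus-contralateral maps for both hemispheres.

    ``left_asym[v] = L[v] - R[corr(v)]`` and
    ``right_asym[w] = R[w] - L[corr^-1(w)]``; positive values mean the
    ipsilateral hemisphere has the larger value.
    """
    left_values = np.asarray(left_values, float)
    right_values = np.asarray(right_values, float)
    if len(left_values) != len(corr.left_to_right) or \
            len(right_values) != len(corr.left_to_right):
        raise ValueError("maps and correspondence table disagree in length")
    left_asym = left_values - right_values[corr.left_to_right]
    right_asym = right_values - left_values[corr.right_to_left]
    return left_asym, right_asym


# ---------------------------------------------------------------------------
# feature-matrix assembly


def normalize_subject(raw: dict[tuple[str, str], np.ndarray],
                      corr: CorrespondenceMap,
                      cortex_masks: dict[str, np.ndarray]
                      ) -> dict[tuple[str, str], np.ndarray]:
    """Steps 2-4 for one subject: z-score everything, add asymmetry maps.

    ``raw`` maps ``(feature_name, hemi)`` to per-vertex values, where
    feature names are the base names (``thickness``, ``sulc``, ``curv``,
    ``lcd``, FLAIR samples) plus ``doughnut.*`` maps.  Returns
    ``(feature_key, hemi)`` with keys ``<name>.z``, ``doughnut.*`` (z-scored)
    and ``asym.<name>`` for the full-chain features.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    base_names = sorted({name for name, _ in raw})
    for name in base_names:
        for hemi in HEMIS:
            z = intra_subject_zscore(raw[(name, hemi)], cortex_masks[hemi])
            key = name if name.startswith("doughnut.") else f"{name}.z"
            out[(key, hemi)] = z
    for name in FULL_CHAIN_FEATURES:
        la, ra = interhemispheric_asymmetry(out[(f"{name}.z", "left")],
                                            out[(f"{name}.z", "right")], corr)
        out[(f"asym.{name}", "left")] = la
        out[(f"asym.{name}", "right")] = ra
    return out


#: feature keys that receive step 5 (control normalization)
def control_normalized_keys() -> list[str]:
    return [f"{n}.z" for n in FULL_CHAIN_FEATURES] + \
           [f"asym.{n}" for n in FULL_CHAIN_FEATURES]


def finalize_subject(normed: dict[tuple[str, str], np.ndarray],
                     stats: ControlStats) -> dict[tuple[str, str], np.ndarray]:
    """Step 5: control-normalize the full-chain z-maps and asymmetry maps."""
    out = dict(normed)
    for key in control_normalized_keys():
        for hemi in HEMIS:
            out[(key, hemi)] = control_normalize(normed[(key, hemi)], stats,
                                                 key, hemi)
    return out


def assemble_feature_matrix(subject_rows: list[tuple[str, str,
                                                     dict, dict, object]],
                            stats: ControlStats) -> pd.DataFrame:
    """Build the canonical 28-column vertex-by-feature table.

    ``subject_rows`` holds ``(subject_id, group, normed_maps, cortex_masks,
    lesion)`` tuples, where ``normed_maps`` comes from
    :func:`normalize_subject`, ``cortex_masks`` maps hemisphere to a boolean
    mask and ``lesion`` is ``None`` or ``(hemisphere, vertex_indices)``.

    Labels: lesional vertices 1, contralateral-hemisphere cortex 0,
    ipsilateral non-lesional -1 (excluded from training), controls -1.
    """
    frames = []
    for subject_id, group, normed, cortex_masks, lesion in subject_rows:
        needed = set(control_normalized_keys()) | {
            c for c in CANONICAL_COLUMNS if not c.startswith("asym.")}
        for key in needed:
            for hemi in HEMIS:
                if (key, hemi) not in normed:
                    raise KeyError(f"subject {subject_id}: missing feature "
                                   f"{key}/{hemi}")
        final = finalize_subject(normed, stats)
        for hemi in HEMIS:
            mask = cortex_masks[hemi]
            idx = np.flatnonzero(mask)
            cols = {}
            for col in CANONICAL_COLUMNS:
                if (col, hemi) not in final:
                    raise KeyError(
                        f"subject {subject_id}: missing feature {col}/{hemi}")
                cols[col] = final[(col, hemi)][idx]
            label = np.full(len(idx), -1, dtype=np.int64)
            if lesion is not None:
                les_hemi, les_idx = lesion
                if hemi == les_hemi:
                    lesional = np.isin(idx, les_idx)
                    label[lesional] = 1
                else:
                    label[:] = 0
            frame = pd.DataFrame(cols)
            frame.insert(0, "subject", subject_id)
            frame.insert(1, "group", group)
            frame.insert(2, "hemisphere", hemi)
            frame.insert(3, "vertex", idx)
            frame["label"] = label
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    values = out[list(CANONICAL_COLUMNS)].to_numpy()
    out[list(CANONICAL_COLUMNS)] = np.nan_to_num(values, nan=0.0)
    return out


def training_view(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rows that carry a training label (lesional or contralateral healthy)."""
    return matrix[matrix["label"] >= 0]
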