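"""Seeded synthetic cortical cohorts for exercising the detection pipeline.

Hemispheres are built as spherically parameterized closed surfaces: a base
sphere carries band-limited radial "folding" waves plus smooth regional and
per-subject fields, so every generated mesh is genus 0 (Gauss-Bonnet
testable), the inflated counterpart is simply the undisplaced sphere, and
T1/FLAIR volumes can be rendered analytically from the same radial
functions.  The right hemisphere is the mirror image of the left with
identical vertex ordering, so the interhemispheric correspondence is the
identity map.

Inter-subject variability of each feature is split into a bilaterally
shared smooth field and a per-hemisphere independent smooth field of equal
variance (plus fine-scale measurement noise).  With that split, a
unilateral lesion implanted at ``k`` control-SD expresses close to ``k``
both in the control-normalized feature maps and in the control-normalized
asymmetry maps.  Lesion effect sizes are therefore specified in control-SD
units and converted to raw units analytically from the wave amplitudes
(attenuated for the smoothing the measurement pipeline will apply).

Confounds deliberately present in every subject: a bilateral thin patch
(primary-somatosensory analogue: extreme z-thickness, near-zero
asymmetry), a unilateral-but-normal thick patch (planum-temporale
analogue: raw asymmetry filtered out by control normalization), and random
unilateral FLAIR "motion artifact" blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .bundle import SubjectBundle
from .io import VolumeImage
from .mesh import SurfaceMesh
from .normalization import CorrespondenceMap

HEMIS = ("left", "right")
_MIRROR = np.array([-1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# analytic angular fields

@dataclass
class WaveField:
    """Band-limited field: sum of plane sine waves evaluated on the sphere."""

    dirs: np.ndarray      # (M, 3) unit directions
    k: np.ndarray         # (M,) angular wavenumbers, rad/mm
    phases: np.ndarray
    amps: np.ndarray

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        phase = points_mm @ (self.dirs.T * self.k) + self.phases
        return np.sin(phase) @ self.amps

    def sd(self) -> float:
        return float(np.sqrt(0.5 * np.sum(self.amps ** 2)))

    def smoothed_sd(self, fwhm: float) -> float:
        """SD after Gaussian smoothing with the given FWHM (mm)."""
        sigma2 = fwhm ** 2 / (8.0 * np.log(2.0))
        a = self.amps * np.exp(-0.5 * self.k ** 2 * sigma2)
        return float(np.sqrt(0.5 * np.sum(a ** 2)))


def random_wave_field(rng: np.random.Generator, sd: float,
                      wavelengths: tuple[float, float] = (22.0, 40.0),
                      n_waves: int = 8) -> WaveField:
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lam = rng.uniform(*wavelengths, size=n_waves)
    amps = np.full(n_waves, sd * np.sqrt(2.0 / n_waves))
    return WaveField(dirs, 2.0 * np.pi / lam, rng.uniform(0, 2 * np.pi, n_waves),
                     amps)


@dataclass
class CapPatch:
    """Smooth plateau patch: ``amp`` inside ``radius_mm`` (arc length from
    ``center`` on the reference sphere), cosine taper over ``taper_mm``."""

    center: np.ndarray
    radius_mm: float
    taper_mm: float
    amp: float
    sphere_radius: float

    def profile(self, points_mm: np.ndarray) -> np.ndarray:
        u = points_mm / np.maximum(
            np.linalg.norm(points_mm, axis=-1, keepdims=True), 1e-12)
        arc = self.sphere_radius * np.arccos(np.clip(u @ self.center, -1, 1))
        x = (arc - self.radius_mm) / self.taper_mm
        return np.where(arc <= self.radius_mm, 1.0,
                        np.where(x >= 1.0, 0.0, 0.5 * (1 + np.cos(np.pi * np.clip(x, 0, 1)))))

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        return self.amp * self.profile(points_mm)


@dataclass
class RippleField:
    """High-frequency radial ripple confined to a patch (raises |K|/LCD)."""

    patch: CapPatch
    dir1: np.ndarray
    dir2: np.ndarray
    wavelength_mm: float
    amp: float

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        k = 2.0 * np.pi / self.wavelength_mm
        osc = np.sin(k * (points_mm @ self.dir1)) * \
            np.sin(k * (points_mm @ self.dir2))
        return self.amp * osc * self.patch.profile(points_mm)


# ---------------------------------------------------------------------------
# specs

@dataclass
class LesionSpec:
    """One implanted geodesic-disc lesion, effects in control-SD units."""

    radius_mm: float = 8.0
    shoulder_mm: float = 5.0          # soft edge beyond the mask
    thickness_effect_sd: float = 2.0  # thickening (+) or thinning (-)
    contrast_effect_sd: float = 2.0   # ratio moves toward 1 (boundary blur)
    flair_effect_sd: float = 2.0      # FLAIR hyperintensity
    dimple_amplitude_mm: float = 0.3  # pial ripple -> raised LCD
    dimple_wavelength_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_controls: int = 10
    n_patients: int = 8
    subdivisions: int = 5             # icosphere level; 5 -> 10242 vertices
    sphere_radius: float = 55.0       # mm; ~8,700 cortex vertices at level 5
    medial_wall_angle_deg: float = 45.0
    folding_amplitude: float = 2.5    # mm SD of the folding waves
    folding_wavelengths: tuple[float, float] = (24.0, 40.0)
    # thickness model (mm)
    thickness_base: float = 2.5
    thickness_regional_sd: float = 0.4
    thickness_subject_sd: float = 0.2   # per component (shared & independent)
    pial_jitter_sd: float = 0.05        # per-vertex radial measurement noise
    thin_patch_amp: float = -1.2
    thin_patch_radius: float = 12.0
    asym_patch_amp: float = 0.8
    asym_patch_radius: float = 10.0
    # white-surface subject variability (mm, per component)
    white_subject_sd: float = 0.2
    # T1 intensities and GM modulation fields (fractional)
    t1_wm: float = 110.0
    t1_gm: float = 60.0
    t1_background: float = 15.0
    t1_gm_regional_sd: float = 0.03
    t1_gm_subject_sd: float = 0.025     # per component
    # FLAIR intensities and global modulation fields (fractional)
    flair_wm: float = 90.0
    flair_gm: float = 115.0
    flair_background: float = 20.0
    flair_regional_sd: float = 0.05
    flair_subject_sd: float = 0.025     # per component
    # volume rendering
    voxel_mm: float = 1.5
    boundary_blur_mm: float = 1.2
    volume_noise_sd: float = 1.5
    # FLAIR motion-artifact blobs (per subject)
    n_artifacts: int = 1
    artifact_amp_sd: float = 2.0        # in nominal FLAIR control-SD units
    artifact_radius_mm: float = 6.0
    # proxy maps emitted directly (consumed, not computed, by the pipeline)
    sulc_noise_sd: float = 0.15
    curv_noise_sd: float = 0.02
    # smoothing the measurement pipeline will apply (for SD calibration)
    smoothing_fwhm: float = 10.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thickness_regional_sd", "thickness_subject_sd",
                     "pial_jitter_sd", "white_subject_sd", "volume_noise_sd",
                     "sulc_noise_sd", "curv_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # nominal post-smoothing control SDs used for effect calibration -----
    def _two_component_sd(self, per_component: float) -> float:
        probe = WaveField(np.eye(3), 2 * np.pi / np.full(3, np.mean(
            self.folding_wavelengths)), np.zeros(3),
            np.full(3, per_component * np.sqrt(2.0 / 3)))
        att = probe.smoothed_sd(self.smoothing_fwhm) / max(probe.sd(), 1e-12)
        return float(np.sqrt(2.0) * per_component * att)

    def nominal_thickness_sd(self) -> float:
        return self._two_component_sd(self.thickness_subject_sd)

    def nominal_contrast_sd(self) -> float:
        r0 = self.t1_gm / self.t1_wm
        return r0 * self._two_component_sd(self.t1_gm_subject_sd)

    def nominal_flair_sd(self) -> float:
        return self.flair_gm * self._two_component_sd(self.flair_subject_sd)

    def lesion_erosion(self) -> float:
        """Mask-mean attenuation of the implanted plateau profile under the
        pipeline's Gaussian smoothing (planar convolution integral).

        Effects are specified on the *measured, smoothed* feature scale, so
        the raw implanted amplitude is divided by this factor.
        """
        les = self.lesion
        sig = self.smoothing_fwhm / np.sqrt(8.0 * np.log(2.0))
        if sig <= 0:
            return 1.0
        h = 0.25
        half = les.radius_mm + les.shoulder_mm + 4.0 * sig
        x = np.arange(-half, half, h)
        X, Y = np.meshgrid(x, x)
        d = np.hypot(X, Y)
        prof = np.where(
            d <= les.radius_mm, 1.0,
            np.where(d >= les.radius_mm + les.shoulder_mm, 0.0,
                     0.5 * (1 + np.cos(np.pi * (d - les.radius_mm)
                                       / les.shoulder_mm))))
        sm = ndimage.gaussian_filter(prof, sig / h)
        return float(sm[d <= les.radius_mm].mean())


# fixed anatomical directions (away from the +x medial wall)
_THIN_DIR = np.array([0.0, 0.9, -0.436])
_ASYM_DIR = np.array([0.0, -0.9, 0.436])


@dataclass
class _SharedAnatomy:
    """Cohort-level fields shared by every subject (mirrored bilaterally)."""

    dirs: np.ndarray
    faces: np.ndarray
    cortex_mask: np.ndarray
    fold: WaveField
    thickness_regional: WaveField
    thin_patch: CapPatch
    asym_patch: CapPatch
    t1_gm_regional: WaveField
    flair_regional: WaveField
    sulc_regional: WaveField
    curv_regional: WaveField


def _base_sphere(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    dirs = np.asarray(m.vertices, dtype=np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs, np.asarray(m.faces, dtype=np.int64)


def _shared_anatomy(spec: CohortSpec, rng: np.random.Generator
                    ) -> _SharedAnatomy:
    dirs, faces = _base_sphere(spec)
    angle_from_medial = np.degrees(np.arccos(np.clip(dirs @ [1.0, 0, 0], -1, 1)))
    cortex = angle_from_medial > spec.medial_wall_angle_deg
    R = spec.sphere_radius
    thin = _THIN_DIR / np.linalg.norm(_THIN_DIR)
    asym = _ASYM_DIR / np.linalg.norm(_ASYM_DIR)
    return _SharedAnatomy(
        dirs=dirs, faces=faces, cortex_mask=cortex,
        fold=random_wave_field(rng, spec.folding_amplitude,
                               spec.folding_wavelengths, n_waves=10),
        thickness_regional=random_wave_field(rng, spec.thickness_regional_sd,
                                             (26.0, 45.0)),
        thin_patch=CapPatch(thin, spec.thin_patch_radius, 6.0,
                            spec.thin_patch_amp, R),
        asym_patch=CapPatch(asym, spec.asym_patch_radius, 5.0,
                            spec.asym_patch_amp, R),
        t1_gm_regional=random_wave_field(rng, spec.t1_gm_regional_sd),
        flair_regional=random_wave_field(rng, spec.flair_regional_sd),
        sulc_regional=random_wave_field(rng, 1.0, (25.0, 45.0)),
        curv_regional=random_wave_field(rng, 1.0, (24.0, 40.0)),
    )


@dataclass
class _HemiModel:
    """Analytic radial model of one hemisphere of one subject.

    All fields are evaluated at reference-sphere points ``R0 * u``; for the
    right hemisphere, bilaterally shared fields are evaluated at the
    x-mirrored point so the two hemispheres line up vertexwise.
    """

    spec: CohortSpec
    shared: _SharedAnatomy
    mirrored: bool
    white_shared: WaveField
    white_indep: WaveField
    thick_shared: WaveField
    thick_indep: WaveField
    t1_shared: WaveField
    t1_indep: WaveField
    flair_shared: WaveField
    flair_indep: WaveField
    lesion_patch: CapPatch | None = None
    lesion_ripple: RippleField | None = None
    lesion_dt: float = 0.0
    lesion_dgm_t1: float = 0.0
    lesion_dflair: float = 0.0
    artifact_patches: list[CapPatch] = field(default_factory=list)

    def _pts(self, points_mm: np.ndarray, shared_field: bool) -> np.ndarray:
        if shared_field and self.mirrored:
            return points_mm * _MIRROR
        return points_mm

    def white_radius(self, points_mm: np.ndarray) -> np.ndarray:
        ps = self._pts(points_mm, True)
        r = self.spec.sphere_radius + self.shared.fold(ps) + \
            self.white_shared(ps) + self.white_indep(points_mm)
        return r

    def thickness(self, points_mm: np.ndarray) -> np.ndarray:
        ps = self._pts(points_mm, True)
        t = (self.spec.thickness_base + self.shared.thickness_regional(ps)
             + self.shared.thin_patch(ps)
             + self.thick_shared(ps) + self.thick_indep(points_mm))
        if not self.mirrored:  # unilateral (left) normal variant
            t = t + self.shared.asym_patch(points_mm)
        if self.lesion_patch is not None:
            t = t + self.lesion_dt * self.lesion_patch.profile(points_mm)
        return np.maximum(t, 0.5)

    def pial_radius(self, points_mm: np.ndarray) -> np.ndarray:
        r = self.white_radius(points_mm) + self.thickness(points_mm)
        if self.lesion_ripple is not None:
            r = r + self.lesion_ripple(points_mm)
        return r


# ---------------------------------------------------------------------------
# mesh + map construction

def _subject_hemi_model(spec: CohortSpec, shared: _SharedAnatomy,
                        rng: np.random.Generator, mirrored: bool,
                        shared_fields: dict | None) -> tuple[_HemiModel, dict]:
    """Build one hemisphere model; shared (bilateral) fields are drawn once
    per subject and reused by the mirrored hemisphere."""
    if shared_fields is None:
        shared_fields = {
            "white": random_wave_field(rng, spec.white_subject_sd),
            "thick": random_wave_field(rng, spec.thickness_subject_sd),
            "t1": random_wave_field(rng, spec.t1_gm_subject_sd),
            "flair": random_wave_field(rng, spec.flair_subject_sd),
        }
    model = _HemiModel(
        spec=spec, shared=shared, mirrored=mirrored,
        white_shared=shared_fields["white"],
        white_indep=random_wave_field(rng, spec.white_subject_sd),
        thick_shared=shared_fields["thick"],
        thick_indep=random_wave_field(rng, spec.thickness_subject_sd),
        t1_shared=shared_fields["t1"],
        t1_indep=random_wave_field(rng, spec.t1_gm_subject_sd),
        flair_shared=shared_fields["flair"],
        flair_indep=random_wave_field(rng, spec.flair_subject_sd),
    )
    return model, shared_fields


def _hemi_meshes(spec: CohortSpec, shared: _SharedAnatomy, model: _HemiModel,
                 rng: np.random.Generator, hemisphere: str
                 ) -> dict[tuple[str, str], SurfaceMesh]:
    R = spec.sphere_radius
    dirs = shared.dirs if hemisphere == "left" else shared.dirs * _MIRROR
    faces = shared.faces if hemisphere == "left" else shared.faces[:, ::-1]
    pts = dirs * R
    r_w = model.white_radius(pts)
    r_p = model.pial_radius(pts) + rng.normal(0, spec.pial_jitter_sd,
                                              len(dirs))
    mask = shared.cortex_mask
    out = {}
    for kind, radius in (("white", r_w), ("pial", r_p),
                         ("inflated", np.full(len(dirs), R))):
        out[(hemisphere, kind)] = SurfaceMesh(
            dirs * radius[:, None], faces, hemisphere, kind, mask.copy())
    return out


def _proxy_maps(spec: CohortSpec, shared: _SharedAnatomy,
                rng: np.random.Generator, hemisphere: str
                ) -> dict[str, np.ndarray]:
    """Analytic sulcal-depth and mean-curvature stand-ins (consumed maps)."""
    R = spec.sphere_radius
    dirs = shared.dirs if hemisphere == "left" else shared.dirs * _MIRROR
    ref = dirs * R
    ref_shared = ref * _MIRROR if hemisphere == "right" else ref
    fold = shared.fold(ref_shared)
    amp = max(spec.folding_amplitude, 1e-9)
    sulc = -fold / amp + 0.3 * shared.sulc_regional(ref_shared) + \
        rng.normal(0, spec.sulc_noise_sd, len(dirs))
    curv = 1.0 / R + 0.01 * fold / amp + \
        0.01 * shared.curv_regional(ref_shared) + \
        rng.normal(0, spec.curv_noise_sd, len(dirs))
    return {"sulc": sulc, "curv": curv}


# ---------------------------------------------------------------------------
# volumes

def _render_volumes(spec: CohortSpec, model: _HemiModel,
                    rng: np.random.Generator
                    ) -> dict[str, VolumeImage]:
    """Analytic T1 + FLAIR grids for one hemisphere, with boundary blur,
    lesion intensity changes, FLAIR artifacts and voxel noise."""
    R = spec.sphere_radius
    half = R + 4.0 * spec.folding_amplitude + 6.0 + 8.0
    v = spec.voxel_mm
    n = int(np.ceil(2 * half / v))
    affine = np.eye(4) * v
    affine[:3, 3] = -half
    affine[3, 3] = 1.0
    coords = (np.arange(n) * v) - half
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    rho = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    shell = (rho > R - 14.0) & (rho < R + 14.0)
    pts = np.column_stack([X[shell], Y[shell], Z[shell]])
    u = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    ref = u * R  # evaluate angular fields on the reference sphere
    r_w = model.white_radius(ref)
    r_p = model.white_radius(ref) + model.thickness(ref)
    in_wm_shell = np.linalg.norm(pts, axis=1) < r_w
    in_gm = (~in_wm_shell) & (np.linalg.norm(pts, axis=1) < r_p)

    t1_gm_mod = 1.0 + model.shared.t1_gm_regional(
        model._pts(ref, True)) + model.t1_shared(model._pts(ref, True)) + \
        model.t1_indep(ref)
    flair_mod = 1.0 + model.shared.flair_regional(
        model._pts(ref, True)) + model.flair_shared(model._pts(ref, True)) + \
        model.flair_indep(ref)

    gm_t1 = spec.t1_gm * t1_gm_mod
    wm_t1 = np.full(len(pts), spec.t1_wm)
    gm_fl = spec.flair_gm * flair_mod
    wm_fl = spec.flair_wm * flair_mod

    if model.lesion_patch is not None:
        prof = model.lesion_patch.profile(ref)
        gm_t1 = gm_t1 + model.lesion_dgm_t1 * prof
        lesional_band = np.linalg.norm(pts, axis=1) > (r_w - 1.5)
        gm_fl = gm_fl + model.lesion_dflair * prof
        wm_fl = np.where(lesional_band, wm_fl + model.lesion_dflair * prof,
                         wm_fl)
    for patch in model.artifact_patches:
        gm_fl = gm_fl + patch(ref)

    vols = {}
    for modality, gm, wm, bg in (("T1", gm_t1, wm_t1, spec.t1_background),
                                 ("FLAIR", gm_fl, wm_fl,
                                  spec.flair_background)):
        grid = np.full((n, n, n), bg)
        grid[rho < R - 14.0] = (spec.t1_wm if modality == "T1"
                                else spec.flair_wm)
        vals = np.where(in_wm_shell, wm, np.where(in_gm, gm, bg))
        grid[shell] = vals
        grid = ndimage.gaussian_filter(grid, spec.boundary_blur_mm / v)
        grid += rng.normal(0, spec.volume_noise_sd, grid.shape)
        vols[modality] = VolumeImage(grid, affine, modality)
    return vols


# ---------------------------------------------------------------------------
# lesion placement

def _pick_lesion_vertex(spec: CohortSpec, shared: _SharedAnatomy,
                        rng: np.random.Generator) -> int:
    R = spec.sphere_radius
    les = spec.lesion
    margin_rad = np.radians(spec.medial_wall_angle_deg) + \
        (les.radius_mm + les.shoulder_mm + 5.0) / R
    ang_medial = np.arccos(np.clip(shared.dirs @ [1.0, 0, 0], -1, 1))
    ok = ang_medial > margin_rad
    for patch in (shared.thin_patch, shared.asym_patch):
        clear = (patch.radius_mm + patch.taper_mm + les.radius_mm
                 + les.shoulder_mm + 4.0) / R
        ang = np.arccos(np.clip(shared.dirs @ patch.center, -1, 1))
        ok &= ang > clear
    candidates = np.flatnonzero(ok & shared.cortex_mask)
    if len(candidates) == 0:
        raise ValueError("mesh resolution/geometry too small to place a "
                         f"{les.radius_mm} mm lesion clear of the medial "
                         "wall and anatomy patches")
    return int(rng.choice(candidates))


def _artifact_patches(spec: CohortSpec, rng: np.random.Generator,
                      hemisphere: str) -> list[CapPatch]:
    """Unilateral FLAIR blobs at random cortex directions (both groups)."""
    out = []
    R = spec.sphere_radius
    amp = spec.artifact_amp_sd * spec.nominal_flair_sd()
    medial = np.radians(spec.medial_wall_angle_deg) + \
        (spec.artifact_radius_mm + 4.0) / R
    while len(out) < spec.n_artifacts:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        if np.arccos(np.clip(d[0] if hemisphere == "left" else -d[0],
                             -1, 1)) <= medial:
            continue
        out.append(CapPatch(d, spec.artifact_radius_mm, 3.0, amp, R))
    return out


# ---------------------------------------------------------------------------
# public generators

def generate_hemisphere_pair(spec: CohortSpec, seed: int | None = None
                             ) -> tuple[dict, CorrespondenceMap, np.ndarray]:
    """Left/right white, pial and inflated meshes for one (control) subject.

    Returns ``(surfaces, correspondence, cortex_mask)`` where ``surfaces``
    maps ``(hemisphere, kind)`` to meshes.  Right = mirrored left with
    identity vertex correspondence.
    """
    bundle = _build_subject(spec, seed if seed is not None else spec.seed,
                            "pair", lesioned=False, with_volumes=False,
                            shared=None)
    return (bundle.surfaces, bundle.correspondence,
            bundle.surfaces[("left", "white")].cortex_mask)


def _build_subject(spec: CohortSpec, seed: int, subject_id: str,
                   lesioned: bool, with_volumes: bool = True,
                   shared: _SharedAnatomy | None = None) -> SubjectBundle:
    rng = np.random.default_rng(seed)
    if shared is None:
        shared = _shared_anatomy(spec, np.random.default_rng(spec.seed))
    min_vertex_spacing = 2.2 * spec.sphere_radius / (2.0 ** spec.subdivisions * 10)
    if lesioned and spec.lesion.radius_mm < min_vertex_spacing:
        raise ValueError(
            f"mesh resolution too low for a {spec.lesion.radius_mm} mm "
            f"lesion (vertex spacing ~{min_vertex_spacing:.1f} mm)")

    models: dict[str, _HemiModel] = {}
    sh_fields = None
    for hemi in HEMIS:
        models[hemi], sh_fields = _subject_hemi_model(
            spec, shared, rng, mirrored=(hemi == "right"),
            shared_fields=sh_fields)
        models[hemi].artifact_patches = []

    # unilateral FLAIR artifacts: each blob lands on a random hemisphere
    art_hemi = rng.choice(HEMIS)
    models[art_hemi].artifact_patches = _artifact_patches(spec, rng, art_hemi)

    lesion = None
    if lesioned:
        # dedicated stream: implanting a lesion must not perturb the
        # healthy-anatomy noise realization (implant_lesion determinism)
        rng_les = np.random.default_rng([seed, 17])
        les = spec.lesion
        hemi = str(rng_les.choice(HEMIS))
        center_vertex = _pick_lesion_vertex(spec, shared, rng_les)
        cdir = shared.dirs[center_vertex]
        if hemi == "right":
            cdir = cdir * _MIRROR
        R = spec.sphere_radius
        patch = CapPatch(cdir, les.radius_mm, les.shoulder_mm, 1.0, R)
        m = models[hemi]
        m.lesion_patch = patch
        erosion = spec.lesion_erosion()
        m.lesion_dt = (les.thickness_effect_sd * spec.nominal_thickness_sd()
                       / erosion)
        m.lesion_dgm_t1 = (les.contrast_effect_sd * spec.nominal_contrast_sd()
                           * spec.t1_wm / erosion)
        m.lesion_dflair = (les.flair_effect_sd * spec.nominal_flair_sd()
                           / erosion)
        if les.dimple_amplitude_mm > 0:
            d1 = np.cross(cdir, [0.0, 0.0, 1.0])
            d1 /= np.linalg.norm(d1)
            d2 = np.cross(cdir, d1)
            m.lesion_ripple = RippleField(patch, d1, d2,
                                          les.dimple_wavelength_mm,
                                          les.dimple_amplitude_mm)
        # lesion mask: plateau vertices (arc distance <= radius)
        dirs_h = shared.dirs * _MIRROR if hemi == "right" else shared.dirs
        arc = R * np.arccos(np.clip(dirs_h @ cdir, -1, 1))
        lesion = (hemi, np.flatnonzero((arc <= les.radius_mm)
                                       & shared.cortex_mask))

    surfaces = {}
    maps = {}
    volumes = {}
    for hemi in HEMIS:
        surfaces.update(_hemi_meshes(spec, shared, models[hemi], rng, hemi))
        for name, vals in _proxy_maps(spec, shared, rng, hemi).items():
            maps[(name, hemi)] = vals
        if with_volumes:
            for modality, vol in _render_volumes(spec, models[hemi],
                                                 rng).items():
                volumes[(modality, hemi)] = vol

    return SubjectBundle(
        subject_id=subject_id,
        group="patient" if lesioned else "control",
        surfaces=surfaces, maps=maps, volumes=volumes, lesion=lesion,
        correspondence=CorrespondenceMap.identity(len(shared.dirs)),
        meta={"seed": seed, "cohort_seed": spec.seed,
              "n_vertices": len(shared.dirs),
              "nominal_sd": {
                  "thickness": spec.nominal_thickness_sd(),
                  "gw_contrast": spec.nominal_contrast_sd(),
                  "flair": spec.nominal_flair_sd()}})


def generate_control_cohort(spec: CohortSpec) -> list[SubjectBundle]:
    """The healthy-control cohort (shared anatomy + per-subject fields)."""
    rng = np.random.default_rng(spec.seed)
    shared = _shared_anatomy(spec, np.random.default_rng(spec.seed))
    seeds = rng.integers(0, 2 ** 31 - 1, size=spec.n_controls + spec.n_patients)
    return [_build_subject(spec, int(seeds[i]), f"control{i:02d}",
                           lesioned=False, shared=shared)
            for i in range(spec.n_controls)]


def generate_patient_cohort(spec: CohortSpec) -> list[SubjectBundle]:
    """Patients: controls-like subjects, each with one implanted lesion."""
    rng = np.random.default_rng(spec.seed)
    shared = _shared_anatomy(spec, np.random.default_rng(spec.seed))
    seeds = rng.integers(0, 2 ** 31 - 1, size=spec.n_controls + spec.n_patients)
    return [_build_subject(spec, int(seeds[spec.n_controls + i]),
                           f"patient{i:02d}", lesioned=True, shared=shared)
            for i in range(spec.n_patients)]


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[SubjectBundle], list[SubjectBundle]]:
    """Controls and patients of one seeded cohort."""
    return generate_control_cohort(spec), generate_patient_cohort(spec)


def implant_lesion(bundle: SubjectBundle, spec: CohortSpec,
                   lesion: LesionSpec | None = None
                   ) -> SubjectBundle:
    """Rebuild a control subject with one implanted lesion.

    Deterministic: reuses the subject's stored generation seed, so the
    healthy anatomy is identical and only the lesion differs.  With
    all-zero effect sizes the output is statistically indistinguishable
    from the input (identical geometry up to the ripple term).
    """
    if lesion is not None:
        spec = replace(spec, lesion=lesion)
    shared = _shared_anatomy(spec, np.random.default_rng(spec.seed))
    return _build_subject(spec, bundle.meta["seed"], bundle.subject_id,
                          lesioned=True, shared=shared)
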