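"""Reading and writing standard surface-analysis formats.

FreeSurfer binary triangle surfaces and "curv"-style per-vertex scalar files
are handled through nibabel; FreeSurfer ASCII label files are read through
nibabel and written by a small writer (nibabel provides no label writer).
Every format also has a plain columnar-text fallback so fixtures stay
inspectable:

* vertex map: header line ``<feature_name> <n_vertices>``, one value per
  line, 0-based vertex order;
* surface: header line ``surface <n_vertices> <n_faces>``, then one
  ``x y z`` line per vertex and one ``i j k`` line per face;
* label/mask: header line ``label <n>``, one 0-based vertex index per line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nibabel.freesurfer import io as fsio

from .mesh import SurfaceMesh, VertexMap


class FormatError(ValueError):
    """Malformed file for the named format."""


@dataclass
class VolumeImage:
    """A 3D intensity grid with a voxel-to-mm affine (NIfTI semantics)."""

    data: np.ndarray
    affine: np.ndarray
    modality: str = "T1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"volume grid must be 3D, got {self.data.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("volume affine is singular")


# ---------------------------------------------------------------------------
# surfaces

def load_surface(path: str, format: str = "freesurfer_binary",
                 hemisphere: str = "left", kind: str = "white",
                 cortex_mask: np.ndarray | None = None) -> SurfaceMesh:
    if format == "freesurfer_binary":
        try:
            verts, faces = fsio.read_geometry(path)
        except Exception as exc:  # nibabel raises assorted errors
            raise FormatError(f"{path}: not a FreeSurfer surface: {exc}") from exc
    elif format == "columnar_text":
        verts, faces = _read_surface_text(path)
    else:
        raise ValueError(f"unknown surface format {format!r}")
    return SurfaceMesh(np.asarray(verts, float), np.asarray(faces, int),
                       hemisphere, kind, cortex_mask)


def save_surface(mesh: SurfaceMesh, path: str,
                 format: str = "freesurfer_binary") -> None:
    if format == "freesurfer_binary":
        fsio.write_geometry(path, mesh.vertices, mesh.faces.astype(np.int32))
    elif format == "columnar_text":
        with open(path, "w") as fh:
            fh.write(f"surface {mesh.n_vertices} {mesh.n_faces}\n")
            for x, y, z in mesh.vertices:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
            for i, j, k in mesh.faces:
                fh.write(f"{i} {j} {k}\n")
    else:
        raise ValueError(f"unknown surface format {format!r}")


def _read_surface_text(path: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        tag, nv, nf = lines[0].split()
        if tag != "surface":
            raise ValueError("missing 'surface' header tag")
        nv, nf = int(nv), int(nf)
        verts = np.array([[float(t) for t in lines[1 + i].split()]
                          for i in range(nv)])
        faces = np.array([[int(t) for t in lines[1 + nv + i].split()]
                          for i in range(nf)])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed columnar surface near line "
                          f"{_bad_line(lines, exc)}: {exc}") from exc
    return verts, faces


def _bad_line(lines: list[str], exc: Exception) -> str:
    return getattr(exc, "lineno", "?")


# ---------------------------------------------------------------------------
# per-vertex scalar maps

def load_vertex_map(path: str, format: str = "freesurfer_morph",
                    mesh: SurfaceMesh | None = None,
                    feature_name: str | None = None,
                    hemisphere: str | None = None) -> VertexMap:
    if format == "freesurfer_morph":
        try:
            values = fsio.read_morph_data(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a FreeSurfer morph file: {exc}") from exc
        name = feature_name or os.path.basename(path)
    elif format == "columnar_text":
        with open(path) as fh:
            lines = fh.read().splitlines()
        try:
            name, n = lines[0].rsplit(None, 1)
            values = np.array([float(lines[1 + i]) for i in range(int(n))])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed columnar map: {exc}") from exc
        name = feature_name or name
    else:
        raise ValueError(f"unknown map format {format!r}")
    vm = VertexMap(np.asarray(values, float), name,
                   hemisphere or (mesh.hemisphere if mesh else "left"))
    if mesh is not None:
        if len(vm) != mesh.n_vertices:
            raise ValueError(
                f"{path}: map has {len(vm)} values, mesh has "
                f"{mesh.n_vertices} vertices")
    return vm


def save_vertex_map(vm: VertexMap, path: str,
                    format: str = "freesurfer_morph") -> None:
    if format == "freesurfer_morph":
        fsio.write_morph_data(path, vm.values.astype(np.float32))
    elif format == "columnar_text":
        with open(path, "w") as fh:
            fh.write(f"{vm.feature_name} {len(vm)}\n")
            for v in vm.values:
                fh.write(f"{v:.9g}\n")
    else:
        raise ValueError(f"unknown map format {format!r}")


# ---------------------------------------------------------------------------
# labels (vertex-index masks)

def load_label(path: str, format: str = "freesurfer_label") -> np.ndarray:
    """0-based vertex indices of a label/mask, sorted ascending."""
    if format == "freesurfer_label":
        try:
            idx = fsio.read_label(path)
        except Exception as exc:
            raise FormatError(f"{path}: not a FreeSurfer label: {exc}") from exc
    elif format == "columnar_text":
        with open(path) as fh:
            lines = fh.read().splitlines()
        try:
            tag, n = lines[0].split()
            if tag != "label":
                raise ValueError("missing 'label' header tag")
            idx = np.array([int(lines[1 + i]) for i in range(int(n))])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed columnar label: {exc}") from exc
    else:
        raise ValueError(f"unknown label format {format!r}")
    return np.sort(np.atleast_1d(np.asarray(idx, dtype=np.int64)))


def save_label(indices: np.ndarray, path: str,
               vertices: np.ndarray | None = None,
               format: str = "freesurfer_label") -> None:
    indices = np.sort(np.asarray(indices, dtype=np.int64))
    if format == "freesurfer_label":
        # FreeSurfer ASCII label: comment, count, then "idx x y z value"
        with open(path, "w") as fh:
            fh.write("#!ascii label, written by fcdsurf\n")
            fh.write(f"{len(indices)}\n")
            for i in indices:
                if vertices is not None:
                    x, y, z = vertices[i]
                else:
                    x = y = z = 0.0
                fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f} 1.000000\n")
    elif format == "columnar_text":
        with open(path, "w") as fh:
            fh.write(f"label {len(indices)}\n")
            for i in indices:
                fh.write(f"{i}\n")
    else:
        raise ValueError(f"unknown label format {format!r}")


def mask_from_label(indices: np.ndarray, n_vertices: int) -> np.ndarray:
    mask = np.zeros(n_vertices, dtype=bool)
    mask[indices] = True
    return mask


# ---------------------------------------------------------------------------
# volumes

def load_volume(path: str, modality: str = "T1") -> VolumeImage:
    img = nib.load(path)
    return VolumeImage(np.asarray(img.get_fdata(), float), img.affine, modality)


def save_volume(vol: VolumeImage, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), path)
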