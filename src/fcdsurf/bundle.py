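"""Per-subject container tying together meshes, maps, volumes and masks.

On disk a bundle is a directory in FreeSurfer-style layout: ``lh.white``,
``rh.pial``, ... (binary surfaces), ``lh.sulc``-style morph files,
``lh.lesion.label``, ``T1.lh.nii.gz``/``FLAIR.rh.nii.gz`` volumes,
``lh.cortex.label`` masks, and a ``manifest.json`` with ids, group, seed
and the left-right correspondence.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as fio
from .io import VolumeImage
from .mesh import SurfaceMesh, VertexMap
from .normalization import CorrespondenceMap

_PREFIX = {"left": "lh", "right": "rh"}
_HEMI = {"lh": "left", "rh": "right"}


@dataclass
class SubjectBundle:
    """Everything the pipeline needs about one subject.

    ``surfaces`` maps ``(hemisphere, kind)`` to meshes; ``maps`` maps
    ``(feature_name, hemisphere)`` to per-vertex arrays; ``volumes`` maps
    ``(modality, hemisphere)`` to images.  ``lesion`` is ``None`` or
    ``(hemisphere, vertex_indices)``.
    """

    subject_id: str
    group: str  # "control" | "patient"
    surfaces: dict[tuple[str, str], SurfaceMesh]
    maps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    volumes: dict[tuple[str, str], VolumeImage] = field(default_factory=dict)
    lesion: tuple[str, np.ndarray] | None = None
    correspondence: CorrespondenceMap | None = None
    meta: dict = field(default_factory=dict)

    def mesh(self, hemisphere: str, kind: str) -> SurfaceMesh:
        return self.surfaces[(hemisphere, kind)]

    def cortex_mask(self, hemisphere: str) -> np.ndarray:
        return self.surfaces[(hemisphere, "white")].cortex_mask

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        for (hemi, kind), mesh in self.surfaces.items():
            fio.save_surface(mesh, os.path.join(directory,
                                                f"{_PREFIX[hemi]}.{kind}"))
        for hemi in ("left", "right"):
            if (hemi, "white") in self.surfaces:
                mask = self.cortex_mask(hemi)
                fio.save_label(np.flatnonzero(mask),
                               os.path.join(directory,
                                            f"{_PREFIX[hemi]}.cortex.label"),
                               vertices=self.mesh(hemi, "white").vertices)
        for (name, hemi), values in self.maps.items():
            fio.save_vertex_map(VertexMap(values, name, hemi),
                                os.path.join(directory,
                                             f"{_PREFIX[hemi]}.{name}"))
        for (modality, hemi), vol in self.volumes.items():
            fio.save_volume(vol, os.path.join(
                directory, f"{modality}.{_PREFIX[hemi]}.nii.gz"))
        if self.lesion is not None:
            hemi, idx = self.lesion
            fio.save_label(idx,
                           os.path.join(directory,
                                        f"{_PREFIX[hemi]}.lesion.label"),
                           vertices=self.mesh(hemi, "white").vertices)
        manifest = {
            "subject_id": self.subject_id,
            "group": self.group,
            "surfaces": sorted(f"{_PREFIX[h]}.{k}" for h, k in self.surfaces),
            "maps": sorted(f"{_PREFIX[h]}.{n}" for n, h in self.maps),
            "volumes": sorted(f"{m}.{_PREFIX[h]}" for m, h in self.volumes),
            "lesion_hemisphere": self.lesion[0] if self.lesion else None,
            "correspondence": (self.correspondence.left_to_right.tolist()
                               if self.correspondence is not None else None),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, dict, list))},
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "SubjectBundle":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        surfaces = {}
        masks = {}
        for hemi in ("left", "right"):
            p = os.path.join(directory, f"{_PREFIX[hemi]}.cortex.label")
            if os.path.exists(p):
                masks[hemi] = fio.load_label(p)
        for name in manifest["surfaces"]:
            prefix, kind = name.split(".", 1)
            hemi = _HEMI[prefix]
            mesh = fio.load_surface(os.path.join(directory, name),
                                    hemisphere=hemi, kind=kind)
            if hemi in masks:
                mesh.cortex_mask = fio.mask_from_label(masks[hemi],
                                                       mesh.n_vertices)
            surfaces[(hemi, kind)] = mesh
        maps = {}
        for name in manifest["maps"]:
            prefix, feat = name.split(".", 1)
            vm = fio.load_vertex_map(os.path.join(directory, name),
                                     feature_name=feat,
                                     hemisphere=_HEMI[prefix])
            maps[(feat, _HEMI[prefix])] = vm.values
        volumes = {}
        for name in manifest["volumes"]:
            modality, prefix = name.split(".", 1)
            volumes[(modality, _HEMI[prefix])] = fio.load_volume(
                os.path.join(directory, f"{name}.nii.gz"), modality)
        lesion = None
        if manifest["lesion_hemisphere"]:
            hemi = manifest["lesion_hemisphere"]
            idx = fio.load_label(os.path.join(
                directory, f"{_PREFIX[hemi]}.lesion.label"))
            lesion = (hemi, idx)
        corr = (CorrespondenceMap(np.array(manifest["correspondence"]))
                if manifest["correspondence"] else None)
        return cls(subject_id=manifest["subject_id"], group=manifest["group"],
                   surfaces=surfaces, maps=maps, volumes=volumes,
                   lesion=lesion, correspondence=corr,
                   meta=manifest.get("meta", {}))
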