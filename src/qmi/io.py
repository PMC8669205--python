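"""NIfTI serialization of synthetic serial studies.

A study directory holds one subdirectory per visit (``visit_00`` ...)
with 4D multi-echo magnitude/phase volumes and 3D parameter maps, plus
study-level cortex and lesion masks and a JSON manifest listing visits,
modalities, echo times and file paths.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict

import nibabel as nib
import numpy as np

from .phantom import Study, Visit
from .relaxometry import EchoSeries, QuantitativeMap

__all__ = ["save_study", "load_study", "save_volume", "load_volume"]


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(data: np.ndarray, path, voxel_size_mm) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def save_study(study: Study, out_dir) -> Path:
    """Write a study to ``out_dir`` and return the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = study.voxel_size_mm
    manifest = {
        "voxel_size_mm": list(vox),
        "n_visits": study.n_visits,
        "onset_visits": {str(k): int(v) for k, v in study.onset_visits.items()},
        "visits": [],
    }
    save_volume(study.cortex_mask.astype(np.float32), out / "cortex_mask.nii.gz", vox)
    manifest["cortex_mask"] = "cortex_mask.nii.gz"
    manifest["lesion_masks"] = {}
    for lid, mask in study.lesion_masks.items():
        name = f"lesion_{lid:02d}_mask.nii.gz"
        save_volume(mask.astype(np.float32), out / name, vox)
        manifest["lesion_masks"][str(lid)] = name

    for visit in study.visits:
        vdir = out / f"visit_{visit.index:02d}"
        vdir.mkdir(exist_ok=True)
        rel = vdir.name
        entry = {"index": visit.index, "dir": rel,
                 "gre_echo_times_ms": list(map(float, visit.gre.echo_times_ms)),
                 "se_echo_times_ms": list(map(float, visit.spin_echo.echo_times_ms)),
                 "maps": {}}
        save_volume(visit.gre.magnitude, vdir / "gre_magnitude.nii.gz", vox)
        save_volume(visit.gre.phase, vdir / "gre_phase.nii.gz", vox)
        save_volume(visit.spin_echo.magnitude, vdir / "se_magnitude.nii.gz", vox)
        save_volume(visit.spin_echo.phase, vdir / "se_phase.nii.gz", vox)
        for p, qmap in visit.maps.items():
            name = f"{p}.nii.gz"
            save_volume(qmap.values, vdir / name, vox)
            entry["maps"][p] = name
        manifest["visits"].append(entry)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def load_study(study_dir) -> Study:
    """Load a study written by :func:`save_study`."""
    root = Path(study_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    vox = tuple(manifest["voxel_size_mm"])
    cortex = load_volume(root / manifest["cortex_mask"]) > 0.5
    lesion_masks = {int(k): load_volume(root / v) > 0.5
                    for k, v in manifest.get("lesion_masks", {}).items()}
    onset = {int(k): int(v)
             for k, v in manifest.get("onset_visits", {}).items()}

    visits = []
    for entry in manifest["visits"]:
        vdir = root / entry["dir"]
        gre = EchoSeries(load_volume(vdir / "gre_magnitude.nii.gz"),
                         load_volume(vdir / "gre_phase.nii.gz"),
                         np.asarray(entry["gre_echo_times_ms"]), vox)
        se = EchoSeries(load_volume(vdir / "se_magnitude.nii.gz"),
                        load_volume(vdir / "se_phase.nii.gz"),
                        np.asarray(entry["se_echo_times_ms"]), vox)
        maps: Dict[str, QuantitativeMap] = {}
        for p, name in entry["maps"].items():
            maps[p] = QuantitativeMap(load_volume(vdir / name), p,
                                      voxel_size_mm=vox)
        visits.append(Visit(index=int(entry["index"]), gre=gre,
                            spin_echo=se, maps=maps))
    visits.sort(key=lambda v: v.index)
    return Study(visits=visits, cortex_mask=cortex, lesion_masks=lesion_masks,
                 voxel_size_mm=vox, onset_visits=onset)
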