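"""Readers and writers for surfaces, parcellations, time series, tables.

Surfaces: GIFTI (.surf.gii/.gii, the primary dialect) and FreeSurfer
ASCII (.asc, read-only). Parcellations: FreeSurfer .annot and a TSV
fallback (vertex_index<TAB>label_id). Time series: HDF5 with one dataset
per hemisphere per subject at "ts/<subject>/<hemi>". Tabular outputs are
TSV (tab, LF, UTF-8, header row) with fixed 9-significant-digit float
formatting so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .functional import TimeSeriesSet
from .landmarks import CorrespondenceMap
from .mesh import EXCLUDED_LABEL, Parcellation, SurfaceMesh, compute_centroids

#: FreeSurfer annot names that mark non-cortical vertices.
RESERVED_NAMES = {"unknown", "???", "corpuscallosum", "medial_wall"}


def fmt_float(x: float) -> str:
    """Fixed 9-significant-digit representation (platform-stable)."""
    return f"{x:.9g}"


# ---------------------------------------------------------------------------
# surfaces


def read_surface(path, hemisphere: str = "left") -> SurfaceMesh:
    """Read a GIFTI or FreeSurfer ASCII surface."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith(".gii"):
        return _read_gifti(path, hemisphere)
    if name.endswith(".asc"):
        return _read_freesurfer_ascii(path, hemisphere)
    raise ValueError(f"unknown surface format: {path} (expected .gii or .asc)")


def _read_gifti(path: Path, hemisphere: str) -> SurfaceMesh:
    img = nib.load(str(path))
    coords = faces = None
    for arr in img.darrays:
        if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(arr.data, dtype=np.float64)
        elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if coords is None or faces is None:
        raise ValueError(f"{path}: GIFTI file lacks a pointset or triangle array")
    return SurfaceMesh(coords, faces, hemisphere=hemisphere)


def _read_freesurfer_ascii(path: Path, hemisphere: str) -> SurfaceMesh:
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    try:
        n_vert, n_face = (int(tok) for tok in lines[0].split()[:2])
        verts = np.array(
            [[float(t) for t in ln.split()[:3]] for ln in lines[1 : 1 + n_vert]]
        )
        faces = np.array(
            [[int(t) for t in ln.split()[:3]] for ln in lines[1 + n_vert : 1 + n_vert + n_face]]
        )
        if len(verts) != n_vert or len(faces) != n_face:
            raise ValueError("truncated file")
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed FreeSurfer ASCII surface ({exc})") from exc
    return SurfaceMesh(verts, faces, hemisphere=hemisphere)


def write_surface_gifti(mesh: SurfaceMesh, path) -> None:
    coords = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tris = nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    nib.save(nib.gifti.GiftiImage(darrays=[coords, tris]), str(path))


# ---------------------------------------------------------------------------
# parcellations


def read_parcellation(path, mesh: SurfaceMesh) -> Parcellation:
    """Read a FreeSurfer .annot or TSV parcellation; centroids computed.

    Reserved regions (unknown/medial wall) become the excluded label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.lower().endswith(".annot"):
        parc = _read_annot(path)
    else:
        parc = _read_parcellation_tsv(path)
    if parc.labels.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"{path}: label count {parc.labels.shape[0]} does not match "
            f"mesh vertex count {mesh.n_vertices}"
        )
    compute_centroids(mesh, parc)
    return parc


def _read_annot(path: Path) -> Parcellation:
    raw_labels, _, names = nib.freesurfer.read_annot(str(path))
    names = [n.decode() if isinstance(n, bytes) else str(n) for n in names]
    labels = np.full(raw_labels.shape[0], EXCLUDED_LABEL, dtype=np.int64)
    region_names: dict[int, str] = {}
    next_id = 0
    remap: dict[int, int] = {}
    for old_id, name in enumerate(names):
        if name.lower() in RESERVED_NAMES:
            continue
        remap[old_id] = next_id
        region_names[next_id] = name
        next_id += 1
    for old_id, new_id in remap.items():
        labels[raw_labels == old_id] = new_id
    return Parcellation(labels, region_names=region_names)


def _read_parcellation_tsv(path: Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    if not {"vertex_index", "label_id"} <= set(df.columns):
        # headerless fallback: two integer columns
        df = pd.read_csv(path, sep="\t", header=None, names=["vertex_index", "label_id"])
    vidx = df["vertex_index"].to_numpy(dtype=np.int64)
    lab = df["label_id"].to_numpy(dtype=np.int64)
    n = int(vidx.max()) + 1
    labels = np.full(n, EXCLUDED_LABEL, dtype=np.int64)
    labels[vidx] = lab
    names = {}
    if "region_name" in df.columns:
        for i, name in zip(lab, df["region_name"]):
            if i != EXCLUDED_LABEL:
                names[int(i)] = str(name)
    else:
        names = {int(r): f"region_{int(r):03d}" for r in np.unique(lab) if r != EXCLUDED_LABEL}
    return Parcellation(labels, region_names=names)


def write_parcellation_tsv(parc: Parcellation, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("vertex_index\tlabel_id\tregion_name\n")
        for v, lab in enumerate(parc.labels):
            name = parc.region_names.get(int(lab), "excluded")
            fh.write(f"{v}\t{int(lab)}\t{name}\n")


def align_parcellations_by_name(
    left: Parcellation, right: Parcellation
) -> tuple[Parcellation, Parcellation]:
    """Remap region ids so region j left and region j right share a name.

    Annot files can order regions differently per hemisphere; the
    landmark match requires columns in paired order, so pairing is by
    region name.
    """
    names_l = {v: k for k, v in left.region_names.items()}
    names_r = {v: k for k, v in right.region_names.items()}
    common = sorted(set(names_l) & set(names_r))
    if not common:
        raise ValueError("no common region names between hemispheres")
    missing = set(names_l) ^ set(names_r)
    if missing:
        raise ValueError(f"regions present in only one hemisphere: {sorted(missing)}")

    def remap(parc: Parcellation, old_of_name) -> Parcellation:
        labels = np.full_like(parc.labels, EXCLUDED_LABEL)
        cent: dict[int, int] = {}
        for new_id, name in enumerate(common):
            old = old_of_name[name]
            labels[parc.labels == old] = new_id
            if old in parc.centroid_vertex:
                cent[new_id] = parc.centroid_vertex[old]
        return Parcellation(
            labels, region_names=dict(enumerate(common)), centroid_vertex=cent
        )

    return remap(left, names_l), remap(right, names_r)


# ---------------------------------------------------------------------------
# time series


def write_timeseries_h5(path, subjects, tr: float = 2.0) -> None:
    """Write subject (left, right) TimeSeriesSet pairs to HDF5 at
    ``ts/<subject>/<hemi>``."""
    with h5py.File(path, "w") as fh:
        for ts_l, ts_r in subjects:
            grp = fh.require_group(f"ts/{ts_l.subject}")
            grp.create_dataset("left", data=ts_l.data)
            grp.create_dataset("right", data=ts_r.data)
            grp.attrs["tr"] = ts_l.tr if ts_l.tr else tr


def read_timeseries_h5(path) -> list[tuple[TimeSeriesSet, TimeSeriesSet]]:
    out = []
    with h5py.File(path, "r") as fh:
        if "ts" not in fh:
            raise ValueError(f"{path}: no 'ts' group")
        for subject in sorted(fh["ts"]):
            grp = fh["ts"][subject]
            tr = float(grp.attrs.get("tr", 1.0))
            out.append(
                (
                    TimeSeriesSet(grp["left"][()], tr=tr, subject=subject, hemisphere="left"),
                    TimeSeriesSet(grp["right"][()], tr=tr, subject=subject, hemisphere="right"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# tables


def write_correspondence_tsv(cmap: CorrespondenceMap, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("seed_index\ttarget_index\tscore\tdirection\tkind\n")
        for v, (t, s) in enumerate(zip(cmap.target_index, cmap.score)):
            fh.write(f"{v}\t{int(t)}\t{fmt_float(s)}\t{cmap.direction}\t{cmap.kind}\n")


def read_correspondence_tsv(path) -> CorrespondenceMap:
    df = pd.read_csv(path, sep="\t")
    return CorrespondenceMap(
        df["target_index"].to_numpy(np.int64),
        df["score"].to_numpy(np.float64),
        direction=str(df["direction"].iloc[0]),
        kind=str(df["kind"].iloc[0]),
    )


def write_vector_tsv(values: np.ndarray, path, column: str) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"vertex_index\t{column}\n")
        for v, x in enumerate(values):
            fh.write(f"{v}\t{fmt_float(float(x))}\n")


def write_manifest(path, payload: dict) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
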