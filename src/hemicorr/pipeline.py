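"""End-to-end analysis: anatomical + functional correspondence -> symmetry report.

``analyze_scene`` runs the full method on in-memory objects (the form
used from Python and by the synthetic benchmarks); ``run_pipeline``
wraps it with file I/O, a manifest, and deterministic TSV outputs for
the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .functional import group_cross_hemi_argmax, heat_smooth
from .io import (
    align_parcellations_by_name,
    read_parcellation,
    read_surface,
    read_timeseries_h5,
    write_correspondence_tsv,
    write_manifest,
    write_vector_tsv,
)
from .landmarks import build_label_vectors, match_anatomical
from .mesh import validate_mesh
from .metrics import SymmetryReport, afcd, fad, high_fad_clusters


def resolve_fad_threshold(fad_values: np.ndarray, spec: str | float) -> float:
    """An absolute mm threshold (e.g. ``100`` / ``"100mm"``) or a
    percentile of the finite values (e.g. ``"p95"``)."""
    if isinstance(spec, (int, float)):
        return float(spec)
    s = str(spec).strip().lower()
    finite = np.asarray(fad_values)[np.isfinite(fad_values)]
    if s.startswith("p"):
        return float(np.percentile(finite, float(s[1:])))
    if s.endswith("mm"):
        s = s[:-2]
    return float(s)


def analyze_scene(
    scene,
    fwhm: float | None = None,
    fad_threshold: str | float = "p95",
    min_cluster: int = 20,
    fisher_z: bool = False,
    keep_dense: bool | None = None,
) -> dict:
    """Full method on a (synthetic or loaded) scene.

    Steps: label vectors and anatomical correspondence in both
    directions; optional surface smoothing of every subject's series to
    ``fwhm`` mm; group functional correspondence in both directions;
    AFCD per direction; FAD (left-hemisphere reference); high-FAD
    clusters. Returns a dict with the correspondence maps, per-vertex
    metrics and the :class:`SymmetryReport`.
    """
    left, right = scene.left_mesh, scene.right_mesh
    parc_l, parc_r = scene.parc_left, scene.parc_right

    lv_l = build_label_vectors(left, parc_l)
    lv_r = build_label_vectors(right, parc_r)
    ac_lr = match_anatomical(lv_l, lv_r)
    ac_rl = match_anatomical(lv_r, lv_l)

    ts_left = [pair[0] for pair in scene.subjects]
    ts_right = [pair[1] for pair in scene.subjects]
    if fwhm is not None:
        ts_left = [heat_smooth(left, t, fwhm) for t in ts_left]
        ts_right = [heat_smooth(right, t, fwhm) for t in ts_right]

    excl_l = parc_l.excluded_mask()
    excl_r = parc_r.excluded_mask()
    fc_lr_summary = group_cross_hemi_argmax(
        ts_left, ts_right, excl_l, excl_r, keep_dense=keep_dense, fisher_z=fisher_z
    )
    fc_rl_summary = group_cross_hemi_argmax(
        ts_right, ts_left, excl_r, excl_l, keep_dense=keep_dense, fisher_z=fisher_z
    )
    fc_lr = fc_lr_summary.to_correspondence()
    fc_rl = fc_rl_summary.to_correspondence()

    afcd_lr = afcd(ac_lr, fc_lr, right)
    afcd_rl = afcd(ac_rl, fc_rl, left)
    fad_vals = fad(ac_lr, fc_lr, fc_rl, left, ac_rl)

    thr = resolve_fad_threshold(fad_vals, fad_threshold)
    if thr > 0:
        clusters = high_fad_clusters(fad_vals, left, threshold=thr, min_vertices=min_cluster)
    else:
        # degenerate percentile threshold (e.g. p95 of an all-zero FAD
        # map): nothing is meaningfully asymmetric
        clusters = high_fad_clusters(fad_vals, left, threshold=np.inf, min_vertices=min_cluster)

    report = SymmetryReport(afcd_lr, afcd_rl, fad_vals, clusters)
    report.summarize()
    return {
        "ac_lr": ac_lr,
        "ac_rl": ac_rl,
        "fc_lr": fc_lr,
        "fc_rl": fc_rl,
        "fc_lr_summary": fc_lr_summary,
        "fc_rl_summary": fc_rl_summary,
        "afcd_lr": afcd_lr,
        "afcd_rl": afcd_rl,
        "fad": fad_vals,
        "fad_threshold_mm": thr,
        "clusters": clusters,
        "report": report,
    }


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    left_surf: str
    right_surf: str
    left_parc: str
    right_parc: str
    timeseries: str
    out_dir: str
    fwhm: float | None = 8.0
    fad_threshold: str = "p95"
    min_cluster: int = 20
    fisher_z: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for label in ("left_surf", "right_surf", "left_parc", "right_parc", "timeseries"):
            p = Path(getattr(self, label))
            if not p.exists():
                raise FileNotFoundError(f"{label}: {p} does not exist")
        if self.fwhm is not None and self.fwhm <= 0:
            raise ValueError("fwhm must be positive (or None to skip smoothing)")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


class _SceneFromFiles:
    """Duck-typed scene assembled from input files."""

    def __init__(self, cfg: RunConfig):
        self.left_mesh = read_surface(cfg.left_surf, hemisphere="left")
        self.right_mesh = read_surface(cfg.right_surf, hemisphere="right")
        for tag, mesh in (("left", self.left_mesh), ("right", self.right_mesh)):
            rep = validate_mesh(mesh)
            if not rep.is_valid:
                raise ValueError(f"{tag} surface invalid: {'; '.join(rep.violations)}")
        parc_l = read_parcellation(cfg.left_parc, self.left_mesh)
        parc_r = read_parcellation(cfg.right_parc, self.right_mesh)
        self.parc_left, self.parc_right = align_parcellations_by_name(parc_l, parc_r)
        from .mesh import compute_centroids

        compute_centroids(self.left_mesh, self.parc_left)
        compute_centroids(self.right_mesh, self.parc_right)
        self.subjects = read_timeseries_h5(cfg.timeseries)


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read inputs, run :func:`analyze_scene`,
    write deterministic TSV/JSON artifacts plus a manifest.

    Any stage failure aborts with the stage name and removes partial
    outputs; rerunning the same config reproduces outputs byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load-inputs"
    try:
        scene = _SceneFromFiles(config)
        stage = "analysis"
        result = analyze_scene(
            scene,
            fwhm=config.fwhm,
            fad_threshold=config.fad_threshold,
            min_cluster=config.min_cluster,
            fisher_z=config.fisher_z,
        )
        stage = "write-outputs"
        for name in ("ac_lr", "ac_rl", "fc_lr", "fc_rl"):
            p = out / f"{name}.tsv"
            write_correspondence_tsv(result[name], p)
            written.append(p)
        for name in ("afcd_lr", "afcd_rl", "fad"):
            p = out / f"{name}.tsv"
            write_vector_tsv(result[name], p, f"{name}_mm")
            written.append(p)
        p = out / "clusters.tsv"
        clusters = result["clusters"].copy()
        if len(clusters):
            clusters["vertices"] = clusters["vertices"].map(
                lambda vs: ",".join(str(v) for v in vs)
            )
        clusters.to_csv(p, sep="\t", index=False, lineterminator="\n", float_format="%.9g")
        written.append(p)
        p = out / "summary.json"
        summary = dict(result["report"].summary)
        summary["fad_threshold_mm"] = result["fad_threshold_mm"]
        write_manifest(p, summary)
        written.append(p)
        p = out / "manifest.json"
        write_manifest(p, _manifest_payload(config))
        written.append(p)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return result


def _manifest_payload(config: RunConfig) -> dict:
    payload = {
        "tool": "hemicorr",
        "version": __version__,
        "parameters": {
            "fwhm": config.fwhm,
            "fad_threshold": config.fad_threshold,
            "min_cluster": config.min_cluster,
            "fisher_z": config.fisher_z,
            "seed": config.seed,
        },
        "inputs": {},
    }
    for label in ("left_surf", "right_surf", "left_parc", "right_parc", "timeseries"):
        p = Path(getattr(config, label))
        payload["inputs"][label] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
        }
    return payload
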