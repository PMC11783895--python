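"""End-to-end workflows over HDF5 feature stores.

These functions connect the pieces: reconstruct fragments from a raw
coordinate store, write the four feature representations, build split
manifests, and assemble (features, labels) arrays for training.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from . import featurize as fz
from .fragments import Fragment
from .split import SplitParams, build_baseline_split, random_split
from .store import DatasetHandle

__all__ = [
    "load_fragment",
    "featurize_store",
    "blocked_split_store",
    "random_split_store",
    "assemble",
    "save_manifest",
    "load_manifest",
]

log = logging.getLogger(__name__)

#: feature collection names
REP_COORD = "coord"
REP_POINTS = "points"
REP_VOXEL = "voxel"
REP_HILBERT = "hilbert"
REP_SURFACE = "surface"


def load_fragment(handle: DatasetHandle, i: int) -> Fragment:
    """Rebuild a Fragment from the raw-coordinate collection + topology."""
    coords = handle.read_entry(REP_COORD, i)
    code = handle.label_strings()[i]
    topo = handle.read_topology(code)
    return Fragment(
        label=code,
        atom_names=topo["atoms"],
        elements=topo["elements"],
        coords=np.asarray(coords, float),
        source_id=f"{handle.path}:{i}",
        n_residues=2 if len(code) == 6 else 1,
        res_indices=np.array(topo["res_indices"]),
    )


def featurize_store(handle: DatasetHandle, reps=(REP_POINTS, REP_VOXEL,
                                                 REP_HILBERT),
                    seed: int = 0, target_points: int | None = None,
                    surface_points: int = fz.TARGET_POINTS_SURFACE) -> None:
    """Write feature collections computed from the ``coord`` collection.

    ``points``: prepared point clouds (per-task default target count);
    ``voxel``: 32^3 Gaussian density grids; ``hilbert``: 128^2 curve
    images; ``surface``: surface-vertex point clouds (slowest).
    """
    n = handle.count(REP_COORD)
    labels = handle.label_strings()
    if target_points is None:
        dual = any(len(c) == 6 for c in labels)
        target_points = (fz.TARGET_POINTS_DUAL if dual
                         else fz.TARGET_POINTS_SINGLE)
    existing = set(handle.collections())
    todo = [r for r in reps if r not in existing]
    if not todo:
        return
    batches: dict[str, list] = {r: [] for r in todo}
    for i in range(n):
        frag = load_fragment(handle, i)
        if REP_POINTS in todo:
            pc = fz.prepare_pointcloud(frag, target_points, seed=seed + i)
            batches[REP_POINTS].append(pc.points)
        if REP_VOXEL in todo or REP_HILBERT in todo:
            grid = fz.voxelize(frag)
            if REP_VOXEL in todo:
                batches[REP_VOXEL].append(grid.values.astype(np.float32))
            if REP_HILBERT in todo:
                img = fz.make_hilbert_image(grid)
                batches[REP_HILBERT].append(img.pixels.astype(np.float32))
        if REP_SURFACE in todo:
            pc = fz.surface_pointcloud(frag, surface_points, seed=seed + i)
            batches[REP_SURFACE].append(pc.points)
    for rep in todo:
        handle.write_homogeneous(rep, np.stack(batches[rep]), labels)
    handle.flush()


def _class_indices(labels: list[str]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, code in enumerate(labels):
        out.setdefault(code, []).append(i)
    return {c: np.array(v) for c, v in out.items()}


def blocked_split_store(handle: DatasetHandle, seed: int = 0,
                        params: SplitParams = SplitParams()) -> dict:
    """Conformation-blocked split manifest over every class in the store."""
    labels = handle.label_strings()
    records = []
    for code, idx in sorted(_class_indices(labels).items()):
        topo = handle.read_topology(code)
        heavy = np.array([e != "H" for e in topo["elements"]])
        coords = np.stack([handle.read_entry(REP_COORD, int(i))[heavy]
                           for i in idx])
        recs = build_baseline_split(coords, label=code, seed=seed,
                                    params=params)
        for rec in recs:
            records.append({
                "sample_id": int(idx[rec.sample_id]),
                "label": code,
                "assignment": rec.assignment,
                "cluster": rec.cluster,
                "subcluster": rec.subcluster,
            })
    return {
        "mode": "baseline",
        "seed": seed,
        "params": {
            "threshold_factor": params.threshold_factor,
            "bottom_fraction": params.bottom_fraction,
            "large_cluster_gate": params.large_cluster_gate,
            "n_subclusters": params.n_subclusters,
            "max_train_per_cluster": params.max_train_per_cluster,
            "max_test_per_cluster": params.max_test_per_cluster,
            "small_cluster_take": params.small_cluster_take,
            "sample_cap": params.sample_cap,
            "tsne_perplexity": params.tsne_perplexity,
        },
        "records": records,
    }


def random_split_store(handle: DatasetHandle, n_train: int, n_test: int,
                       seed: int = 0) -> dict:
    """Unblocked per-class random split manifest (control)."""
    labels = handle.label_strings()
    records = []
    for code, idx in sorted(_class_indices(labels).items()):
        recs = random_split(len(idx), n_train, n_test, seed=seed)
        for rec in recs:
            records.append({
                "sample_id": int(idx[rec.sample_id]),
                "label": code,
                "assignment": rec.assignment,
                "cluster": -1,
                "subcluster": None,
            })
    return {"mode": "random", "seed": seed,
            "params": {"n_train": n_train, "n_test": n_test},
            "records": records}


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def assemble(handle: DatasetHandle, rep: str, manifest: dict | None = None,
             subset: str = "train",
             indices=None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(features, integer labels, class codes) for a subset of the store.

    Either pass a split ``manifest`` and a ``subset`` name, or explicit
    ``indices``.  Class ids are indices into the returned sorted code list.
    """
    labels = handle.label_strings()
    codes = sorted(set(labels))
    code_id = {c: i for i, c in enumerate(codes)}
    if indices is None:
        if manifest is None:
            indices = np.arange(len(labels))
        else:
            indices = np.array([r["sample_id"] for r in manifest["records"]
                                if r["assignment"] == subset], dtype=int)
    x = np.stack([handle.read_entry(rep, int(i)) for i in indices])
    y = np.array([code_id[labels[int(i)]] for i in indices])
    return x, y, codes
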