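"""Indexed HDF5 feature storage with constant-time random access.

Layout (one file holds any number of representations of the same samples)::

    /<rep>/data      homogeneous: (n, *shape) float32, one slice per entry
                     heterogeneous: (total, d) float32 concatenation
    /<rep>/start     heterogeneous only: (n,) int64 start offsets
    /<rep>/end       heterogeneous only: (n,) int64 end offsets
    /labels          (n,) int32 class ids (shared across representations)
    /label_codes     (c,) fixed-length strings: id -> class code
    /topology/<code> JSON fragment topology (atom names, elements, bonds)

Heterogeneous entries (coordinate sets, meshes) are concatenated along the
first dimension — the second dimension is fixed per collection — and the
start/end offsets make ``read_entry`` a single contiguous read whose cost is
independent of the index.
"""

from __future__ import annotations

import json
import time
from concurrent.futures import ThreadPoolExecutor

import h5py
import numpy as np

__all__ = ["DatasetHandle"]


class DatasetHandle:
    """Reader/writer for the feature-store layout above."""

    def __init__(self, path, mode: str = "r"):
        self.path = str(path)
        self._file = h5py.File(self.path, mode)

    # -- lifecycle ---------------------------------------------------------

    def close(self):
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def flush(self):
        self._file.flush()

    # -- labels ------------------------------------------------------------

    def _intern_labels(self, labels) -> np.ndarray:
        """Map class-code strings to integer ids, extending /label_codes."""
        labels = [str(c) for c in labels]
        existing = list(self.label_codes())
        lookup = {c: i for i, c in enumerate(existing)}
        new = sorted({c for c in labels if c not in lookup})
        if new:
            codes = existing + new
            if "label_codes" in self._file:
                del self._file["label_codes"]
            self._file.create_dataset(
                "label_codes", data=np.array(codes, dtype="S8"))
            lookup = {c: i for i, c in enumerate(codes)}
        return np.array([lookup[c] for c in labels], dtype=np.int32)

    def label_codes(self) -> list[str]:
        if "label_codes" not in self._file:
            return []
        return [c.decode() for c in self._file["label_codes"][()]]

    def labels(self) -> np.ndarray:
        """Integer class ids, one per entry."""
        if "labels" not in self._file:
            return np.zeros(0, dtype=np.int32)
        return self._file["labels"][()]

    def label_strings(self) -> list[str]:
        codes = self.label_codes()
        return [codes[i] for i in self.labels()]

    def _extend_labels(self, ids: np.ndarray, new_total: int):
        current = self.labels()
        n_old = len(current)
        if new_total <= n_old:
            tail = current[new_total - len(ids):new_total]
            if not np.array_equal(tail, ids):
                raise ValueError("labels disagree with the shared label table")
            return
        n_append = new_total - n_old
        if n_append > len(ids):
            raise ValueError("label table out of sync with collections")
        if not np.array_equal(current[new_total - len(ids):], ids[:-n_append]
                              if n_append < len(ids) else ids[:0]):
            raise ValueError("labels disagree with the shared label table")
        if "labels" not in self._file:
            self._file.create_dataset("labels", data=ids[-n_append:],
                                      maxshape=(None,), dtype=np.int32)
        else:
            ds = self._file["labels"]
            ds.resize((new_total,))
            ds[n_old:] = ids[-n_append:]

    # -- collections -------------------------------------------------------

    def collections(self) -> dict[str, dict]:
        out = {}
        for name, group in self._file.items():
            if not isinstance(group, h5py.Group) or "data" not in group:
                continue
            kind = "heterogeneous" if "start" in group else "homogeneous"
            n = (group["start"].shape[0] if kind == "heterogeneous"
                 else group["data"].shape[0])
            out[name] = {"kind": kind, "count": n,
                         "shape": group["data"].shape[1:]}
        return out

    def count(self, name: str) -> int:
        return self.collections()[name]["count"]

    def write_homogeneous(self, name: str, entries, labels,
                          compression=None) -> None:
        """Store fixed-shape entries, one HDF5 slice each; append-safe."""
        entries = np.asarray(entries, dtype=np.float32)
        if entries.ndim < 2:
            raise ValueError("entries must be (n, *shape)")
        if len(entries) != len(labels):
            raise ValueError("one label per entry required")
        ids = self._intern_labels(labels)
        if name in self._file:
            group = self._file[name]
            data = group["data"]
            if data.shape[1:] != entries.shape[1:]:
                raise ValueError(
                    f"shape mismatch: collection {data.shape[1:]}, "
                    f"entries {entries.shape[1:]}")
            n_old = data.shape[0]
            data.resize((n_old + len(entries),) + data.shape[1:])
            data[n_old:] = entries
            total = n_old + len(entries)
        else:
            group = self._file.create_group(name)
            group.create_dataset(
                "data", data=entries,
                maxshape=(None,) + entries.shape[1:],
                compression=compression)
            total = len(entries)
        self._extend_labels(ids, total)

    def write_heterogeneous(self, name: str, entries, labels,
                            compression=None) -> None:
        """Store variable-length entries with a fixed second dimension."""
        entries = [np.asarray(e, dtype=np.float32) for e in entries]
        if not entries:
            raise ValueError("no entries to write")
        if len(entries) != len(labels):
            raise ValueError("one label per entry required")
        widths = {e.shape[1] if e.ndim == 2 else -1 for e in entries}
        if len(widths) != 1 or -1 in widths:
            raise ValueError("entries must share one fixed second dimension")
        ids = self._intern_labels(labels)
        lengths = np.array([len(e) for e in entries], dtype=np.int64)
        concat = np.concatenate(entries, axis=0)
        if name in self._file:
            group = self._file[name]
            data, start, end = group["data"], group["start"], group["end"]
            if data.shape[1] != concat.shape[1]:
                raise ValueError("second dimension mismatch on append")
            base = data.shape[0]
            data.resize((base + len(concat), concat.shape[1]))
            data[base:] = concat
            new_start = base + np.concatenate([[0], np.cumsum(lengths)[:-1]])
            new_end = base + np.cumsum(lengths)
            n_old = start.shape[0]
            start.resize((n_old + len(entries),))
            end.resize((n_old + len(entries),))
            start[n_old:] = new_start
            end[n_old:] = new_end
            total = n_old + len(entries)
        else:
            group = self._file.create_group(name)
            group.create_dataset("data", data=concat,
                                 maxshape=(None, concat.shape[1]),
                                 compression=compression)
            starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
            group.create_dataset("start", data=starts, maxshape=(None,))
            group.create_dataset("end", data=np.cumsum(lengths),
                                 maxshape=(None,))
            total = len(entries)
        self._extend_labels(ids, total)

    def read_entry(self, name: str, i: int) -> np.ndarray:
        """Entry ``i`` of a collection; constant-time random access."""
        group = self._file[name]
        if "start" in group:
            n = group["start"].shape[0]
            if not 0 <= i < n:
                raise IndexError(f"entry {i} out of range [0, {n})")
            s, e = group["start"][i], group["end"][i]
            return group["data"][s:e]
        n = group["data"].shape[0]
        if not 0 <= i < n:
            raise IndexError(f"entry {i} out of range [0, {n})")
        return group["data"][i]

    # -- topology ----------------------------------------------------------

    def write_topology(self, code: str, topology: dict) -> None:
        grp = self._file.require_group("topology")
        if code in grp:
            del grp[code]
        grp.create_dataset(code, data=json.dumps(topology))

    def read_topology(self, code: str) -> dict:
        return json.loads(self._file["topology"][code][()])

    def topology_codes(self) -> list[str]:
        if "topology" not in self._file:
            return []
        return list(self._file["topology"].keys())

    # -- batched iteration -------------------------------------------------

    def iterate_batches(self, names, batch_size: int = 64, workers: int = 1,
                        seed: int = 0, shuffle: bool = True):
        """Yield (features, labels) batches covering every entry once.

        ``names`` may be one collection name or a list (features then is a
        dict name -> batch).  The visit order depends only on ``seed``;
        ``workers`` parallelizes reads (thread pool) without changing
        content.  Homogeneous batches are stacked arrays; heterogeneous
        batches are lists of arrays.
        """
        single = isinstance(names, str)
        name_list = [names] if single else list(names)
        info = self.collections()
        for nm in name_list:
            if nm not in info:
                raise KeyError(f"no collection {nm!r} in {self.path}")
        if batch_size < 1 or workers < 1:
            raise ValueError("batch_size and workers must be >= 1")
        n = info[name_list[0]]["count"]
        labels = self.labels()
        order = (np.random.default_rng(seed).permutation(n) if shuffle
                 else np.arange(n))

        def fetch(nm, idx):
            return self.read_entry(nm, int(idx))

        pool = ThreadPoolExecutor(max_workers=workers) if workers > 1 else None
        try:
            for lo in range(0, n, batch_size):
                batch_idx = order[lo:lo + batch_size]
                features = {}
                for nm in name_list:
                    if pool is not None:
                        entries = list(pool.map(lambda i, nm=nm: fetch(nm, i),
                                                batch_idx))
                    else:
                        entries = [fetch(nm, i) for i in batch_idx]
                    if info[nm]["kind"] == "homogeneous":
                        features[nm] = np.stack(entries)
                    else:
                        features[nm] = entries
                out = features[names] if single else features
                yield out, labels[batch_idx]
        finally:
            if pool is not None:
                pool.shutdown()

    # -- retrieval benchmark ----------------------------------------------

    def benchmark_throughput(self, name: str, cores: int = 1,
                             batch_size: int = 128,
                             repeats: int = 10) -> dict:
        """Timed full-epoch retrieval; reports sample and bit throughput."""
        info = self.collections()[name]
        n = info["count"]
        if info["kind"] == "homogeneous":
            per_sample_bits = int(np.prod(info["shape"])) * 32
        else:
            total_rows = self._file[name]["data"].shape[0]
            per_sample_bits = int(round(total_rows / n)) * info["shape"][0] * 32
        times = []
        for rep in range(repeats):
            t0 = time.perf_counter()
            for batch, _ in self.iterate_batches(name, batch_size,
                                                 workers=cores, seed=rep):
                pass
            times.append(time.perf_counter() - t0)
        mean_epoch = float(np.mean(times))
        samples_per_s = n / mean_epoch
        return {
            "samples_per_s": samples_per_s,
            "bits_per_s": samples_per_s * per_sample_bits,
            "per_sample_bits": per_sample_bits,
            "mean_epoch_s": mean_epoch,
            "epoch_times_s": times,
        }
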