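"""Portable array persistence (HDF5) with manifest validation.

An :class:`ArrayBundle` is a flat mapping of named arrays plus JSON-encodable
metadata.  On save, a manifest of shapes/dtypes and a content hash are stored
alongside the data; on load the manifest is re-validated so silent truncation
or tampering is detected.  Round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import CorruptBundleError

__all__ = ["ArrayBundle", "save_bundle", "load_bundle"]


@dataclass
class ArrayBundle:
    """Named arrays + metadata; the package's on-disk interchange container."""

    arrays: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        """SHA-256 over array names, dtypes, shapes and raw bytes."""
        h = hashlib.sha256()
        for name in sorted(self.arrays):
            a = np.ascontiguousarray(self.arrays[name])
            h.update(name.encode())
            h.update(str(a.dtype).encode())
            h.update(str(a.shape).encode())
            h.update(a.tobytes())
        return h.hexdigest()

    def manifest(self) -> dict:
        return {
            name: {"shape": list(a.shape), "dtype": str(a.dtype)}
            for name, a in self.arrays.items()
        }


def save_bundle(path: str | Path, bundle: ArrayBundle) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("arrays")
        for name, a in bundle.arrays.items():
            g.create_dataset(name, data=np.asarray(a))
        f.attrs["meta"] = json.dumps(bundle.meta, sort_keys=True)
        f.attrs["manifest"] = json.dumps(bundle.manifest(), sort_keys=True)
        f.attrs["content_hash"] = bundle.content_hash()


def load_bundle(path: str | Path) -> ArrayBundle:
    path = Path(path)
    if not path.exists():
        raise CorruptBundleError(f"no such bundle: {path}")
    with h5py.File(path, "r") as f:
        if "arrays" not in f or "manifest" not in f.attrs:
            raise CorruptBundleError(f"{path} is not an array bundle")
        arrays = {name: ds[()] for name, ds in f["arrays"].items()}
        meta = json.loads(f.attrs["meta"])
        manifest = json.loads(f.attrs["manifest"])
        stored_hash = f.attrs["content_hash"]
    bundle = ArrayBundle(arrays=arrays, meta=meta)
    if bundle.manifest() != manifest:
        raise CorruptBundleError(f"{path}: shape/dtype manifest mismatch")
    if bundle.content_hash() != stored_hash:
        raise CorruptBundleError(f"{path}: content hash mismatch")
    return bundle
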