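"""Shared helpers: counter-based random substreams and JSON encoding."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["substream", "dump_json", "sha256_of_file"]


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Independent random stream keyed by ``(seed, *keys)``.

    Counter-based keying makes every consumer (patient, iteration, subset)
    draw from its own stream, so results are invariant to evaluation order
    and to cohort size: stream ``(seed, 1, k)`` is the same no matter how
    many other patients exist.
    """
    if any(int(k) < 0 for k in keys):
        raise ValueError("substream keys must be non-negative integers")
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def sha256_of_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
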