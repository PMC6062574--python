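"""Seed derivation rules.

A single user-facing integer seed is expanded into independent per-stage and
per-cell streams by a fixed, documented rule so that every stage (and every
cell within a stage) is reproducible in isolation:

* stage stream:  ``SeedSequence([seed, crc32(stage_name)])``
* cell stream:   ``SeedSequence([seed, crc32(stage_name), blake2s(barcode)[:8], *extra])``

The barcode hash is computed with :func:`hashlib.blake2s`, which is stable
across processes and Python versions (unlike the builtin ``hash``).
"""

from __future__ import annotations

import hashlib
import zlib

import numpy as np

__all__ = ["stage_rng", "cell_rng", "spawn_rngs"]


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def _barcode_key(barcode: str) -> int:
    return int.from_bytes(hashlib.blake2s(barcode.encode("utf-8")).digest()[:8], "little")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage under a global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _name_key(stage)]))


def cell_rng(seed: int, stage: str, barcode: str, *extra: int) -> np.random.Generator:
    """Generator for one cell within a stage.

    ``extra`` integers (e.g. a target depth) further split the stream.
    """
    entropy = [seed, _name_key(stage), _barcode_key(barcode), *extra]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn_rngs(seed: int, stage: str, n: int) -> list[np.random.Generator]:
    """``n`` independent child generators for iteration-style loops."""
    ss = np.random.SeedSequence([seed, _name_key(stage)])
    return [np.random.default_rng(child) for child in ss.spawn(n)]
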