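"""Shared helpers: stage-keyed RNG streams and nucleotide encoding."""

from __future__ import annotations

import hashlib
from typing import Mapping

import numpy as np

BASES = np.array(list("ACGT"))
_CODE = {b: i for i, b in enumerate("ACGT")}
MISSING_CODE = -1


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return an RNG stream derived from (master seed, stage name).

    Each pipeline stage gets its own stream so adding or reordering stages
    never perturbs the draws of another stage.
    """
    digest = hashlib.blake2b(f"{stage}:{seed}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little") % (2**31))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A,C,G,T -> 0..3; anything else -> -1)."""
    out = np.full(len(seq), MISSING_CODE, dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _CODE.get(ch, MISSING_CODE)
    return out


def decode_sequence(arr: np.ndarray) -> str:
    """Decode an int8 array back to a nucleotide string (-1 -> N)."""
    chars = np.where(arr >= 0, BASES[np.clip(arr, 0, 3)], "N")
    return "".join(chars)


def as_matrix(seqs: Mapping[str, "np.ndarray | str"] | np.ndarray) -> np.ndarray:
    """Coerce a label->sequence mapping (strings or int8 arrays) to a 2D int8 array."""
    if isinstance(seqs, np.ndarray):
        return np.atleast_2d(seqs).astype(np.int8)
    rows = []
    for v in seqs.values():
        rows.append(encode_sequence(v) if isinstance(v, str) else np.asarray(v, dtype=np.int8))
    return np.vstack(rows)
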