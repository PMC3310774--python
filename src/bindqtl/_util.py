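"""Shared helpers: sequence encoding and seeded random substreams."""
from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes 0-3."""
    try:
        return np.fromiter((_BASE_TO_INT[b] for b in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGT base in sequence: {e}") from None


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[int(c)] for c in codes)


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def revcomp_str(seq: str) -> str:
    return decode_seq(revcomp(encode_seq(seq)))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single master seed.

    Every stochastic stage draws from its own named stream so that toggling
    one stage cannot perturb another stage's draws.
    """
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))
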