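"""One-hot encoding of DNA windows.

Each base becomes a binary indicator vector of length 4 under the fixed
alphabet order A, C, G, T. A window of length L encodes to an L x 4 matrix
(rows 5'->3'); flattening row-major gives the 4L-dimensional feature vector
used by numeric models (4,012 features for the standard 1,003-base window).
"""

from __future__ import annotations

import numpy as np

from .errors import EncodingError

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def one_hot(sequence: str) -> np.ndarray:
    """Encode a DNA string into an (L, 4) binary matrix. Case-insensitive."""
    seq = sequence.upper()
    matrix = np.zeros((len(seq), 4), dtype=np.uint8)
    for i, base in enumerate(seq):
        j = _INDEX.get(base)
        if j is None:
            raise EncodingError(f"cannot encode character {base!r} at position {i + 1}")
        matrix[i, j] = 1
    return matrix


def decode(matrix: np.ndarray) -> str:
    """Invert :func:`one_hot`."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4 or not ((matrix.sum(axis=1) == 1).all()):
        raise EncodingError("not a valid one-hot matrix (rows must sum to 1 over 4 columns)")
    return "".join(ALPHABET[j] for j in matrix.argmax(axis=1))


def flatten(matrix: np.ndarray) -> np.ndarray:
    """Row-major flatten of a one-hot matrix into a 4L feature vector."""
    return np.asarray(matrix, dtype=np.float64).reshape(-1)


def encode_batch(sequences) -> np.ndarray:
    """Stack one-hot matrices of equal-length sequences into (N, L, 4) floats."""
    if len(sequences) == 0:
        return np.zeros((0, 0, 4), dtype=np.float64)
    return np.stack([one_hot(s) for s in sequences]).astype(np.float64)


def flatten_batch(sequences) -> np.ndarray:
    """(N, 4L) feature matrix for numeric kernels and vector models."""
    batch = encode_batch(sequences)
    return batch.reshape(batch.shape[0], -1)
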