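"""Weighted-degree string kernel and RBF kernel, with gram-matrix builders.

The weighted-degree (WD) kernel scores two equal-length sequences s_i, s_j by
their positionally matching k-mers up to a maximum length d:

    K(s_i, s_j) = sum_{k=1}^{d} beta_k sum_{l=1}^{L-k+1} I[u_{k,l}(s_i) = u_{k,l}(s_j)]

with beta_k = 2 (d - k + 1) / (d (d + 1)), which sums to 1 over k. The kernel
is positional (no shift or mismatch tolerance): a k-mer only counts when it
matches at the same offset in both sequences.

The gram builder exploits an exact reformulation: let c_l be the length of
the run of consecutive position-wise base matches ending at position l; the
number of matching k-mers equals sum_l I[c_l >= k], so

    K(s_i, s_j) = sum_l B(min(c_l, d)),   B(m) = sum_{k=1}^{m} beta_k.

This computes each pair in O(L) regardless of d and vectorizes across a whole
block of sequence pairs, while remaining bit-identical to the direct
double-loop evaluation.

The RBF kernel on one-hot feature vectors is K(x, x') = exp(-gamma ||x-x'||^2).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf_kernel

from .errors import ConfigurationError, ContractError

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def wd_beta(d: int) -> np.ndarray:
    """Weight vector beta_k = 2(d-k+1)/(d(d+1)), k = 1..d. Sums to 1."""
    if d < 1:
        raise ConfigurationError("d must be >= 1")
    k = np.arange(1, d + 1, dtype=np.float64)
    return 2.0 * (d - k + 1.0) / (d * (d + 1.0))


@dataclass(frozen=True)
class WDKernelParams:
    """Maximum k-mer length d and (derived) weights for the WD kernel."""

    d: int = 10

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ConfigurationError("d must be >= 1")

    @property
    def beta(self) -> np.ndarray:
        return wd_beta(self.d)


@dataclass(frozen=True)
class RBFKernelParams:
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ConfigurationError("gamma must be positive")


def encode_sequences(sequences) -> np.ndarray:
    """Map sequences to an (N, L) int8 matrix of base codes (A=0,C=1,G=2,T=3)."""
    if len(sequences) == 0:
        return np.zeros((0, 0), dtype=np.int8)
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ContractError("all sequences must have equal length")
    flat = "".join(s.upper() for s in sequences)
    arr = np.frombuffer(flat.encode("ascii"), dtype=np.uint8).reshape(len(sequences), L)
    codes = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[ord(base)] = code
    out = codes[arr]
    if (out < 0).any():
        raise ContractError("sequences must be over the alphabet {A,C,G,T}")
    return out


def _cumulative_beta(d: int, max_run: int) -> np.ndarray:
    """B(m) = sum_{k<=min(m,d)} beta_k, tabulated for run lengths 0..max_run."""
    beta = wd_beta(d)
    table = np.zeros(max_run + 1, dtype=np.float64)
    csum = np.cumsum(beta)
    m = np.arange(1, max_run + 1)
    table[1:] = csum[np.minimum(m, d) - 1]
    return table


def wd_kernel(s_i: str, s_j: str, params: WDKernelParams = WDKernelParams()) -> float:
    """WD kernel value between two equal-length sequences."""
    if len(s_i) != len(s_j):
        raise ContractError(
            f"sequences must have equal length, got {len(s_i)} and {len(s_j)}"
        )
    if len(s_i) == 0:
        raise ContractError("sequences must be non-empty")
    a = encode_sequences([s_i])[0]
    b = encode_sequences([s_j])[0]
    table = _cumulative_beta(params.d, len(s_i))
    match = a == b
    total = 0.0
    run = 0
    for m in match:
        run = run + 1 if m else 0
        total += table[run]
    return float(total)


def wd_self_kernel_value(L: int, params: WDKernelParams = WDKernelParams()) -> float:
    """Closed form K(s, s) = sum_k beta_k (L - k + 1) for any sequence of length L."""
    beta = params.beta
    k = np.arange(1, params.d + 1)
    return float(np.sum(beta[k - 1 <= L - 1] * (L - k[k - 1 <= L - 1] + 1)))


def wd_gram(
    seqs_rows,
    seqs_cols=None,
    params: WDKernelParams = WDKernelParams(),
    n_blocks: int = 1,
) -> np.ndarray:
    """Dense WD gram matrix between two sequence lists.

    ``n_blocks`` partitions the rows into contiguous blocks computed
    independently (the unit a parallel scheduler would dispatch); the result
    is bit-identical for any partition. When ``seqs_cols`` is None the
    self-gram of ``seqs_rows`` is computed; it is exactly symmetric because
    entry (i, j) and (j, i) perform the same comparisons and additions.
    """
    symmetric = seqs_cols is None
    rows = encode_sequences(list(seqs_rows))
    cols = rows if symmetric else encode_sequences(list(seqs_cols))
    if rows.size and cols.size and rows.shape[1] != cols.shape[1]:
        raise ContractError("row and column sequences must share one length")
    n_r, L = rows.shape if rows.size else (len(rows), 0)
    n_c = cols.shape[0]
    gram = np.zeros((n_r, n_c), dtype=np.float64)
    if n_r == 0 or n_c == 0:
        return gram
    table = _cumulative_beta(params.d, L)
    if n_blocks < 1:
        raise ConfigurationError("n_blocks must be >= 1")
    bounds = np.linspace(0, n_r, min(n_blocks, n_r) + 1, dtype=int)
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        block = rows[b0:b1]  # (r, L)
        run = np.zeros((b1 - b0, n_c), dtype=np.int32)
        acc = np.zeros((b1 - b0, n_c), dtype=np.float64)
        for l in range(L):
            match = block[:, l][:, None] == cols[:, l][None, :]
            run = (run + 1) * match
            acc += table[run]
        gram[b0:b1] = acc
    return gram


def rbf_kernel_value(x, x_prime, params: RBFKernelParams) -> float:
    """exp(-gamma ||x - x'||^2) for two equal-length numeric vectors."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ContractError(f"vector shapes differ: {x.shape} vs {x_prime.shape}")
    return float(np.exp(-params.gamma * np.sum((x - x_prime) ** 2)))


def rbf_gram(X_rows, X_cols=None, params: RBFKernelParams = RBFKernelParams()) -> np.ndarray:
    """Dense RBF gram matrix (delegates to scikit-learn's pairwise kernel)."""
    X_rows = np.asarray(X_rows, dtype=np.float64)
    X_cols = X_rows if X_cols is None else np.asarray(X_cols, dtype=np.float64)
    if X_rows.shape[1] != X_cols.shape[1]:
        raise ContractError("row and column features must share dimensionality")
    return _sk_rbf_kernel(X_rows, X_cols, gamma=params.gamma)


def sequence_list_hash(sequences) -> str:
    """Stable content hash of a sequence list, for gram-cache keys."""
    h = hashlib.sha256()
    for s in sequences:
        h.update(s.encode("ascii"))
        h.update(b"\n")
    return h.hexdigest()


def save_gram(path, gram: np.ndarray, d: int, sequences) -> None:
    """Cache a WD gram matrix with a JSON header keyed by (d, sequence hash)."""
    np.save(f"{path}.npy", gram)
    with open(f"{path}.json", "w") as fh:
        json.dump({"d": d, "hash": sequence_list_hash(sequences), "shape": list(gram.shape)}, fh)


def load_gram(path, d: int, sequences):
    """Load a cached gram matrix; returns None on any key mismatch or miss."""
    try:
        with open(f"{path}.json") as fh:
            header = json.load(fh)
    except FileNotFoundError:
        return None
    if header.get("d") != d or header.get("hash") != sequence_list_hash(sequences):
        return None
    return np.load(f"{path}.npy")
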