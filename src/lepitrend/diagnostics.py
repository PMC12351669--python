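"""MCMC convergence diagnostics: split-R-hat.

The potential scale reduction factor compares within- and between-chain
variance after splitting each chain in half; values at or above 1.1 flag
non-convergence.  Optionally draws are rank-normalized first (more robust
for heavy-tailed quantities).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

RHAT_THRESHOLD = 1.1


def _split(chains: np.ndarray) -> np.ndarray:
    c, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    flat = x.ravel()
    ranks = np.argsort(np.argsort(flat)) + 1.0
    z = ndtri((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(x.shape)


def compute_rhat(chains: np.ndarray, rank_normalize: bool = False) -> float:
    """Split-R-hat for one scalar quantity.

    ``chains``: array (n_chains, n_draws).  Requires >= 2 chains and >= 4
    draws per chain.  Returns NaN when the draws carry no variance (e.g. all
    chains stuck at one constant)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    if chains.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    if rank_normalize:
        chains = _rank_normalize(chains)
    s = _split(chains)
    m, n = s.shape
    means = s.mean(axis=1)
    w = np.mean(np.var(s, axis=1, ddof=1))
    b = n * np.var(means, ddof=1)
    if w == 0:
        return float("nan")
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def rhat_table(draws: dict[str, np.ndarray], rank_normalize: bool = False) -> dict[str, float]:
    """R-hat per scalar parameter from ``{name: (chains, draws[, k])}``;
    vector-valued parameters get one entry per component."""
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            out[name] = compute_rhat(arr, rank_normalize)
        else:
            for j in range(arr.shape[2]):
                out[f"{name}[{j}]"] = compute_rhat(arr[:, :, j], rank_normalize)
    return out
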