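"""Independent brute-force oracles shared by the test suite."""

from functools import lru_cache
from itertools import combinations

import numpy as np


def partitions(n: int, max_part: int | None = None):
    """All integer partitions of n (as tuples, non-increasing)."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for k in range(min(n, max_part), 0, -1):
        for rest in partitions(n - k, k):
            yield (k,) + rest


@lru_cache(maxsize=None)
def all_abundance_vectors(n_max: int):
    """Every abundance vector (partition) with total 1..n_max."""
    out = []
    for n in range(1, n_max + 1):
        out.extend(partitions(n))
    return tuple(out)


def brute_force_richness(abundances, m: int) -> float:
    """Mean number of distinct species over all (n choose m) subsamples."""
    inds = []
    for sp, c in enumerate(abundances):
        inds.extend([sp] * c)
    vals = [len({inds[i] for i in s}) for s in combinations(range(len(inds)), m)]
    return float(np.mean(vals))
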