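"""Shared helpers: seed derivation and midrank assignment."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.stats import rankdata


def derive_seed(seed: int, tag: str) -> int:
    """Deterministically derive a sub-seed from a global seed and a stage tag.

    Hashes ``"{seed}:{tag}"`` with SHA-256 and keeps the top 4 bytes, so each
    pipeline stage gets an independent, stable stream and adding stages never
    perturbs the seeds of existing ones. Result is always < 2**31.
    """
    digest = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def midranks(values, *, descending: bool = True) -> np.ndarray:
    """Assign ranks 1..N with midranks (average of tied positions) for ties.

    NaN entries mean "undefined metric" and are ranked after every defined
    value; tied NaNs share the midrank of the trailing positions. The rank sum
    is always exactly N(N+1)/2.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    ranks = np.empty(n, dtype=float)
    undef = np.isnan(v)
    defined = ~undef
    if defined.any():
        x = -v[defined] if descending else v[defined]
        ranks[defined] = rankdata(x, method="average")
    if undef.any():
        k = int(defined.sum())
        ranks[undef] = k + (int(undef.sum()) + 1) / 2.0
    return ranks
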