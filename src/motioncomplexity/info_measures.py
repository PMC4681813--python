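"""Symbol-sequence complexity: LZ-76 parsing, block entropies, EMC.

LZ-76 counts the blocks of the exhaustive-history parsing of a sequence:
scanning left to right, each block is the shortest continuation that does
not occur as a substring of the preceding text (the copy source may overlap
the block itself); the final block is counted whether or not it is novel.

Effective measure complexity (EMC) accumulates the excess of the
conditional entropies over the entropy rate,

    EMC = sum_L (h_L - h),    h_L = H(L+1) - H(L),  h_0 = H(1),

where H(L) is the plug-in Shannon entropy (bits) of overlapping length-L
blocks and the entropy rate h is approximated by the last reliably
estimated h_L.  EMC is near zero for memoryless sources and equals the
structural (non-random) information stored in the sequence otherwise.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "lz76_count",
    "lz76_normalized",
    "block_entropy",
    "conditional_entropies",
    "emc",
    "EntropyProfile",
]

logger = logging.getLogger(__name__)


def lz76_count(seq: str) -> int:
    """Number of blocks in the LZ-76 exhaustive-history parsing.

    The empty string has complexity 0 by convention.
    """
    n = len(seq)
    if n == 0:
        return 0
    count = 0
    m = 0  # start of the current block
    while m < n:
        j = m + 1
        # grow the block while seq[m:j] occurs in seq[0:j-1]
        while j <= n and seq.find(seq[m:j], 0, j - 1) != -1:
            j += 1
        # j == n + 1 means we ran off the end: final block counted anyway
        block_end = min(j, n)
        count += 1
        m = block_end
    return count


def lz76_normalized(seq: str, alphabet_size: int) -> float:
    """LZ-76 count normalised by the asymptotic random-sequence rate.

    Returns ``c(n) * log_k(n) / n``; approaches 1 for long i.i.d.
    equiprobable sequences over a k-letter alphabet.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet size must be at least 2")
    n = len(seq)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    return lz76_count(seq) * math.log(n, alphabet_size) / n


def block_entropy(seq: str, L: int) -> float:
    """Plug-in Shannon entropy (bits) of overlapping length-L blocks."""
    if L < 1 or L > len(seq):
        raise ValueError("require 1 <= L <= len(seq)")
    counts = Counter(seq[i : i + L] for i in range(len(seq) - L + 1))
    total = sum(counts.values())
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-(p * np.log2(p)).sum())


def _n_distinct_blocks(seq: str, L: int) -> int:
    return len({seq[i : i + L] for i in range(len(seq) - L + 1)})


@dataclass(frozen=True)
class EntropyProfile:
    """Block/conditional entropy estimates underlying an EMC value."""

    block_entropies: np.ndarray     # H(1..L_max)  (bits)
    conditional_entropies: np.ndarray  # h_0..h_{L_max-1}
    entropy_rate: float             # last reliable h_L
    emc: float                      # bits
    l_max: int
    undersampled: np.ndarray        # bool per L in 1..L_max


def conditional_entropies(seq: str, l_max: int) -> np.ndarray:
    """h_L = H(L+1) - H(L) for L = 0 .. l_max-1, with h_0 = H(1)."""
    H = np.array([block_entropy(seq, L) for L in range(1, l_max + 1)])
    h = np.empty(l_max)
    h[0] = H[0]
    h[1:] = np.diff(H)
    return h


def emc(seq: str, l_max: int = 8) -> tuple[float, EntropyProfile]:
    """Effective measure complexity of a symbol sequence.

    The requested ``l_max`` is truncated to the largest block length whose
    number of distinct observed blocks stays below sqrt(n) (an
    undersampling guard); the entropy rate is the conditional entropy at
    that last reliable length.
    """
    n = len(seq)
    if n < 4:
        raise ValueError("sequence too short for entropy estimation")
    guard = math.sqrt(n)
    eff_lmax = 1
    for L in range(1, l_max + 1):
        if L > n:
            break
        if _n_distinct_blocks(seq, L) < guard:
            eff_lmax = L
        else:
            break
    if eff_lmax < l_max:
        logger.warning(
            "EMC: truncating l_max from %d to %d (undersampling guard sqrt(n)=%.0f)",
            l_max, eff_lmax, guard,
        )
    H = np.array([block_entropy(seq, L) for L in range(1, eff_lmax + 1)])
    h = np.empty(eff_lmax)
    h[0] = H[0]
    h[1:] = np.diff(H)
    rate = float(h[-1])
    value = float(np.sum(h - rate))
    undersampled = np.array(
        [_n_distinct_blocks(seq, L) >= guard for L in range(1, eff_lmax + 1)]
    )
    profile = EntropyProfile(
        block_entropies=H,
        conditional_entropies=h,
        entropy_rate=rate,
        emc=value,
        l_max=eff_lmax,
        undersampled=undersampled,
    )
    return value, profile
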