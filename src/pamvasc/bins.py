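"""Diameter-bin conventions shared by the phantom generator and morphometry."""

from __future__ import annotations

import math
from typing import Sequence, Tuple

DEFAULT_BINS_UM: Tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, math.inf)


def bin_edges_to_pairs(edges: Sequence[float]) -> Tuple[Tuple[float, float], ...]:
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    return tuple(zip(edges[:-1], edges[1:]))


def assign_bin(diameter_um: float, edges: Sequence[float] = DEFAULT_BINS_UM) -> Tuple[float, float]:
    """Bin containing ``diameter_um``; a value exactly on an edge goes to the upper bin."""
    pairs = bin_edges_to_pairs(edges)
    for lo, hi in pairs:
        if lo <= diameter_um < hi:
            return (lo, hi)
    if diameter_um >= pairs[-1][1]:
        return pairs[-1]
    return pairs[0]


def bin_label(pair: Tuple[float, float]) -> str:
    lo, hi = pair
    hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
    return f"{lo:g}-{hi_s}"
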