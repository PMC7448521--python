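"""1D comparator: fixed-size sliding windows along the chromosome.

For a gene spanning L = max(pos) - min(pos) base pairs, windows of sizes
L/2, L/4, L/8, L/12, L/16 and L/20 slide at a skip of L/40; each interval's
variant set is a window (duplicates deduplicated, whole-gene window always
included).  Downstream testing, combination and signal search are shared
with the 3D scan — the two methods differ only in window definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combine import GeneResult, gene_pvalue
from .data import SummaryStats, VariantTable
from .windows import Window, WindowSet, filter_windows

__all__ = ["Scan1DConfig", "make_1d_windows", "scan1d_gene_test"]

GLOBAL_1D = "SCAN1D(GLOBAL)"


@dataclass
class Scan1DConfig:
    """Window sizes and skip as fractions of the gene length L."""

    sizes: tuple = (1 / 2, 1 / 4, 1 / 8, 1 / 12, 1 / 16, 1 / 20)
    skip: float = 1 / 40

    def __post_init__(self):
        if any(s2 >= s1 for s1, s2 in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly descending")
        if any(s <= self.skip for s in self.sizes):
            raise ValueError("all sizes must exceed the skip fraction")


def make_1d_windows(
    positions: np.ndarray,
    cfg: Scan1DConfig | None = None,
    variants: VariantTable | None = None,
    min_mac: int = 10,
) -> WindowSet:
    """Sliding closed intervals [t, t+s] over chromosomal positions.

    Returns the deduplicated variant-set family plus the whole-gene window.
    When a :class:`VariantTable` is given the MAC filter is applied exactly
    as for the 3D windows.
    """
    cfg = cfg or Scan1DConfig()
    pos = np.asarray(positions, dtype=float).ravel()
    m = pos.size
    if m == 0:
        raise ValueError("no variants")
    lo, hi = float(pos.min()), float(pos.max())
    L = hi - lo
    all_members = frozenset(range(m))
    windows: list[Window] = []
    seen: set[frozenset] = set()

    def add(members: frozenset, provenance: str) -> None:
        if members and members not in seen:
            seen.add(members)
            mac = int(variants.mac[list(members)].sum()) if variants is not None else 0
            windows.append(Window(members=members, provenance=provenance, mac=mac))

    add(all_members, GLOBAL_1D)
    if L > 0:
        skip = L * cfg.skip
        tol = 1e-9 * L
        for si, frac in enumerate(cfg.sizes):
            s = L * frac
            t = lo
            k = 0
            while t <= hi - s + tol:
                members = frozenset(
                    int(j) for j in np.flatnonzero((pos >= t - tol) & (pos <= t + s + tol))
                )
                add(members, f"SCAN1D({si},{k})")
                k += 1
                t = lo + k * skip
    ws = WindowSet(windows=windows, trees={}, m=m)
    if variants is not None:
        ws = filter_windows(ws, variants, min_mac=min_mac)
    return ws


def scan1d_gene_test(
    stats: SummaryStats,
    variants: VariantTable,
    cfg: Scan1DConfig | None = None,
    test_kind: str = "mean",
    weights: str | None = None,
    method: str = "cauchy",
    min_mac: int = 10,
    B: int = 5000,
    seed=None,
    gene_id: str = "gene",
) -> GeneResult:
    """Gene-level 1D scan test; identical contracts to the 3D gene test."""
    ws = make_1d_windows(variants.pos, cfg, variants=variants, min_mac=min_mac)
    return gene_pvalue(
        stats, ws, variants, test_kind=test_kind, weights=weights,
        method=method, B=B, seed=seed, gene_id=gene_id,
    )
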