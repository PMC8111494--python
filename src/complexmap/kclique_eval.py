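"""Clique-based precision/recall between predicted clusters and gold
standard complexes.

For each clique size k (2 up to the largest complex/cluster), every
size-k subset of a predicted cluster is checked for containment in some
gold complex (precision side), and every size-k subset of a gold complex
for containment in some cluster (recall side); complexes are treated as
complete cliques over their members.  Per-k values are aggregated by a
weighted mean whose weight at k is the number of complexes on that side
with size >= k, limiting the dominance of a few huge complexes.  Subset
enumeration switches to seeded uniform sampling above ``max_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np

from .core import ComplexSet


@dataclass
class KCliqueResult:
    """Per-k precision/recall plus their weighted aggregates."""

    ks: list[int]
    precision_at_k: list[float | None]
    recall_at_k: list[float | None]
    precision_weights: list[int]
    recall_weights: list[int]
    p_weighted: float
    r_weighted: float

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tprecision\trecall\tw_precision\tw_recall\n")
            for k, p, r, wp, wr in zip(
                self.ks, self.precision_at_k, self.recall_at_k,
                self.precision_weights, self.recall_weights,
            ):
                ps = "NA" if p is None else f"{p:.6f}"
                rs = "NA" if r is None else f"{r:.6f}"
                fh.write(f"{k}\t{ps}\t{rs}\t{wp}\t{wr}\n")
            fh.write(f"# P_weighted={self.p_weighted:.6f}\tR_weighted={self.r_weighted:.6f}\n")


def _containment_fraction(
    source: list[frozenset[str]],
    targets: list[frozenset[str]],
    k: int,
    max_samples: int,
    rng: np.random.Generator,
) -> float | None:
    """Fraction of size-k subsets of ``source`` complexes contained in at
    least one ``target`` complex.

    Each source complex contributes C(size, k) subsets.  Exhaustive when
    the total subset count is <= max_samples, otherwise ``max_samples``
    subsets are drawn with per-complex allocation proportional to its
    subset count (uniform over all subsets in expectation).
    """
    eligible = [c for c in source if len(c) >= k]
    if not eligible:
        return None
    counts = [comb(len(c), k) for c in eligible]
    total = sum(counts)
    # pre-index targets by membership for fast superset checks
    big_targets = [t for t in targets if len(t) >= k]

    def contained(subset: frozenset[str]) -> bool:
        return any(subset <= t for t in big_targets)

    if total <= max_samples:
        hit = 0
        for c in eligible:
            for sub in combinations(sorted(c), k):
                if contained(frozenset(sub)):
                    hit += 1
        return hit / total

    alloc = rng.multinomial(max_samples, np.array(counts) / total)
    hit = 0
    drawn = 0
    for c, n_draw in zip(eligible, alloc):
        members = sorted(c)
        for _ in range(int(n_draw)):
            sub = frozenset(rng.choice(members, size=k, replace=False).tolist())
            drawn += 1
            if contained(sub):
                hit += 1
    return hit / drawn if drawn else None


def clique_pr_at_k(
    clusters: ComplexSet,
    gold: ComplexSet,
    k: int,
    max_samples: int = 10_000,
    seed: int = 0,
) -> tuple[float | None, float | None]:
    """(P_k, R_k) at one clique size; a side with no complex of size >= k
    is undefined (None)."""
    if k < 2:
        raise ValueError("clique size must be >= 2")
    rng = np.random.default_rng((seed, k))
    p = _containment_fraction(list(clusters), list(gold), k, max_samples, rng)
    r = _containment_fraction(list(gold), list(clusters), k, max_samples, rng)
    return p, r


def weighted_kpr(
    clusters: ComplexSet,
    gold: ComplexSet,
    max_samples: int = 10_000,
    seed: int = 0,
    recall_weighting: str = "gold",
) -> KCliqueResult:
    """Weighted k-clique precision/recall across all clique sizes.

    Precision at k is weighted by the number of *clusters* with size >= k.
    Recall weighting defaults to the analogous count on the *gold* side;
    ``recall_weighting="clusters"`` switches to cluster-side weights.
    Undefined sides at a given k are excluded from their aggregate.
    """
    if len(clusters) == 0 or len(gold) == 0:
        raise ValueError("both cluster and gold sets must be non-empty")
    if recall_weighting not in ("gold", "clusters"):
        raise ValueError("recall_weighting must be 'gold' or 'clusters'")
    kmax = max(max(len(c) for c in clusters), max(len(c) for c in gold))

    ks, ps, rs, wps, wrs = [], [], [], [], []
    for k in range(2, kmax + 1):
        p, r = clique_pr_at_k(clusters, gold, k, max_samples=max_samples, seed=seed)
        wp = sum(1 for c in clusters if len(c) >= k)
        wr = (
            sum(1 for c in gold if len(c) >= k)
            if recall_weighting == "gold"
            else sum(1 for c in clusters if len(c) >= k)
        )
        ks.append(k)
        ps.append(p)
        rs.append(r)
        wps.append(wp)
        wrs.append(wr)

    def agg(values: list[float | None], weights: list[int]) -> float:
        num = sum(w * v for v, w in zip(values, weights) if v is not None and w > 0)
        den = sum(w for v, w in zip(values, weights) if v is not None and w > 0)
        return num / den if den else float("nan")

    return KCliqueResult(
        ks=ks,
        precision_at_k=ps,
        recall_at_k=rs,
        precision_weights=wps,
        recall_weights=wrs,
        p_weighted=agg(ps, wps),
        r_weighted=agg(rs, wrs),
    )


def complex_recovery_rate(
    predicted: ComplexSet, planted: ComplexSet, jaccard_threshold: float = 0.8
) -> float:
    """Fraction of planted complexes matched by some predicted cluster at
    Jaccard >= threshold (a strict recovery criterion; many benchmarks
    accept far looser overlap)."""
    if len(planted) == 0:
        raise ValueError("no planted complexes")
    hit = 0
    for truth in planted:
        for pred in predicted:
            inter = len(truth & pred)
            if inter and inter / len(truth | pred) >= jaccard_threshold:
                hit += 1
                break
    return hit / len(planted)
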