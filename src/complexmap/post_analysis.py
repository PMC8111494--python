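"""Downstream analyses on a final complex map.

Covers: the subcomplex index SC(A, B) = |A∩B|/|A| (an asymmetric overlap
measure); a non-redundant complex set built by a greedy tier-ordered
pass; promiscuous (multi-complex, "moonlighting") proteins; protein-age
enrichment z-scores by resampling a non-promiscuous background; and
per-complex annotation enrichment with an empirical false-discovery
threshold derived from membership-shuffled complexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ComplexSet
from .wmm_features import hypergeom_tail


def subcomplex_index(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """SC(A, B) = |A ∩ B| / |A|: 1 when A is a subset of B, 0 when
    disjoint.  Normalized by |A| alone, unlike the Jaccard index."""
    if len(a) == 0:
        raise ValueError("SC undefined for empty A")
    return len(set(a) & set(b)) / len(a)


def _tier_rank(tier: str | None) -> int:
    order = {"ExtremelyHigh": 0, "VeryHigh": 1, "High": 2, "MediumHigh": 3, "Medium": 4}
    return order.get(tier or "", len(order))


def nonredundant_set(
    complexes: ComplexSet, sc_cutoff: float = 0.5, method: str = "greedy"
) -> ComplexSet:
    """Reduce a complex map to a mutually non-redundant subset.

    ``greedy`` (default): complexes are visited in confidence-tier order,
    then size descending, then lexicographic; a candidate is kept iff its
    SC against every kept complex — in both directions — is < cutoff.
    ``symmetric``: keep exactly the complexes whose SC vs *every* other
    complex is < cutoff (can empty mutually redundant groups).
    """
    if not 0.0 < sc_cutoff <= 1.0:
        raise ValueError("sc_cutoff must be in (0,1]")
    tiers = complexes.tiers or [None] * len(complexes)
    order = sorted(
        range(len(complexes)),
        key=lambda i: (_tier_rank(tiers[i]), -len(complexes[i]), sorted(complexes[i])),
    )
    if method == "greedy":
        kept_idx: list[int] = []
        for i in order:
            c = complexes[i]
            ok = True
            for j in kept_idx:
                k = complexes[j]
                if subcomplex_index(c, k) >= sc_cutoff or subcomplex_index(k, c) >= sc_cutoff:
                    ok = False
                    break
            if ok:
                kept_idx.append(i)
    elif method == "symmetric":
        kept_idx = []
        for i in order:
            c = complexes[i]
            if all(
                subcomplex_index(c, complexes[j]) < sc_cutoff
                for j in range(len(complexes))
                if j != i and complexes[j] != c
            ):
                kept_idx.append(i)
    else:
        raise ValueError("method must be 'greedy' or 'symmetric'")
    return ComplexSet(
        [complexes[i] for i in kept_idx],
        tiers=[tiers[i] for i in kept_idx] if complexes.tiers else None,
    )


def promiscuous_proteins(nonredundant: ComplexSet) -> dict[str, int]:
    """Proteins participating in >= 2 complexes of the non-redundant set,
    with their membership counts."""
    counts: dict[str, int] = {}
    for c in nonredundant:
        for p in c:
            counts[p] = counts.get(p, 0) + 1
    return {p: n for p, n in sorted(counts.items()) if n >= 2}


def age_group_zscores(
    promiscuous: set[str],
    background: set[str],
    ages: dict[str, str],
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-age-group z-score of promiscuous-protein counts vs a resampled
    non-promiscuous background.

    Each resample draws |promiscuous| proteins from the background without
    replacement and counts them per age group; z = (observed - mean)/sd.
    Proteins without an age annotation are counted under 'unmapped'.
    Groups with zero resampling variance get NaN.
    """
    promiscuous = set(promiscuous)
    background = set(background) - promiscuous
    if len(background) < len(promiscuous):
        raise ValueError("background smaller than promiscuous set")
    rng = np.random.default_rng(seed)

    def group_of(p: str) -> str:
        return ages.get(p, "unmapped")

    groups = sorted({group_of(p) for p in promiscuous | background})
    gindex = {g: i for i, g in enumerate(groups)}
    observed = np.zeros(len(groups))
    for p in promiscuous:
        observed[gindex[group_of(p)]] += 1

    bg = sorted(background)
    bg_groups = np.array([gindex[group_of(p)] for p in bg])
    counts = np.zeros((n_resamples, len(groups)))
    for r in range(n_resamples):
        draw = rng.choice(len(bg), size=len(promiscuous), replace=False)
        counts[r] = np.bincount(bg_groups[draw], minlength=len(groups))
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, np.nan)
    return pd.DataFrame(
        {"age_group": groups, "observed": observed, "resampled_mean": mean,
         "resampled_sd": sd, "zscore": z}
    )


@dataclass
class EnrichmentResult:
    """Per-(complex, term) hypergeometric enrichment with an empirical
    FDR-derived p-value threshold."""

    table: pd.DataFrame  # complex_id, term, overlap, p_value, enriched
    p_threshold: float
    alpha: float
    n_enriched_complexes: int
    n_complexes: int


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style annotation sets: term, description, tab-separated members."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


def shuffle_complex_memberships(
    complexes: ComplexSet, rng: np.random.Generator, max_retries: int = 100
) -> ComplexSet:
    """Reassign protein ids to new cluster ids, preserving the number of
    clusters, the cluster-size distribution, and each protein's number of
    memberships (the membership multiset is permuted over cluster slots).

    A permutation that would place the same protein twice in one cluster
    is repaired by swapping with a slot elsewhere.
    """
    sizes = [len(c) for c in complexes]
    slots: list[str] = []
    for c in complexes:
        slots.extend(sorted(c))
    for _ in range(max_retries):
        perm = [slots[i] for i in rng.permutation(len(slots))]
        # repair duplicate proteins within a cluster by swapping outward
        ok = True
        pos = 0
        bounds = []
        for s in sizes:
            bounds.append((pos, pos + s))
            pos += s
        for lo, hi in bounds:
            seen: set[str] = set()
            for i in range(lo, hi):
                if perm[i] in seen:
                    swapped = False
                    for j in rng.permutation(len(perm)):
                        if lo <= j < hi:
                            continue
                        # find j whose value is new to this cluster and whose
                        # cluster would accept perm[i]
                        jlo, jhi = next(b for b in bounds if b[0] <= j < b[1])
                        if perm[j] not in seen and perm[j] not in perm[lo:hi] and perm[
                            i
                        ] not in perm[jlo:jhi]:
                            perm[i], perm[j] = perm[j], perm[i]
                            swapped = True
                            break
                    if not swapped:
                        ok = False
                        break
                seen.add(perm[i])
            if not ok:
                break
        if ok:
            shuffled = []
            for lo, hi in bounds:
                shuffled.append(frozenset(perm[lo:hi]))
            return ComplexSet(shuffled)
    raise RuntimeError("could not produce a valid membership shuffle")


def _enrichment_pvalues(
    complexes: ComplexSet,
    annotations: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    N = len(background)
    rows = []
    for ci, c in enumerate(complexes):
        members = set(c) & background
        for term in sorted(annotations):
            term_set = annotations[term] & background
            if not term_set:
                continue
            k = len(members & term_set)
            p = hypergeom_tail(k, len(members), len(term_set), N)
            rows.append((ci, term, k, p))
    return pd.DataFrame(rows, columns=["complex_id", "term", "overlap", "p_value"])


def enrichment_with_shuffled_fdr(
    complexes: ComplexSet,
    annotations: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
    n_shuffles: int = 20,
    seed: int = 0,
    method: str = "shuffled",
) -> EnrichmentResult:
    """Hypergeometric annotation enrichment per complex, with the
    significance threshold set empirically from membership-shuffled
    complexes.

    A complex is *enriched* when its best term p-value falls at or below
    the threshold; the threshold is the largest candidate p at which the
    shuffled sets' mean enriched-complex rate is <= alpha times the real
    rate (empirical FDR <= alpha).  ``method="bh"`` replaces the shuffled
    null with Benjamini-Hochberg across all (complex, term) p-values.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    missing = {t for t, s in annotations.items() if not (s & background)}
    if missing:
        warnings.warn(f"skipping {len(missing)} terms absent from background", stacklevel=2)
        annotations = {t: s for t, s in annotations.items() if t not in missing}
    for c in complexes:
        if not set(c) <= background:
            raise ValueError("background must contain every complex member")

    real = _enrichment_pvalues(complexes, annotations, background)
    if real.empty:
        empty = real.assign(enriched=pd.Series(dtype=bool))
        return EnrichmentResult(empty, 0.0, alpha, 0, len(complexes))

    best_real = real.groupby("complex_id")["p_value"].min()

    if method == "bh":
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(real["p_value"], alpha=alpha, method="fdr_bh")
        real = real.assign(enriched=reject)
        thr = float(real.loc[real["enriched"], "p_value"].max()) if reject.any() else 0.0
    elif method == "shuffled":
        rng = np.random.default_rng(seed)
        shuffled_best: list[pd.Series] = []
        for _ in range(n_shuffles):
            shuf = shuffle_complex_memberships(complexes, rng)
            sp = _enrichment_pvalues(shuf, annotations, background)
            shuffled_best.append(sp.groupby("complex_id")["p_value"].min())
        thr = 0.0
        for cand in sorted(best_real.unique()):
            real_rate = float((best_real <= cand).mean())
            shuf_rate = float(np.mean([(s <= cand).mean() for s in shuffled_best]))
            if real_rate > 0 and shuf_rate <= alpha * real_rate:
                thr = max(thr, float(cand))
        real = real.assign(enriched=real["p_value"] <= thr)
    else:
        raise ValueError("method must be 'shuffled' or 'bh'")

    n_enr = int(real.groupby("complex_id")["enriched"].any().sum())
    return EnrichmentResult(real, float(thr), alpha, n_enr, len(complexes))
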