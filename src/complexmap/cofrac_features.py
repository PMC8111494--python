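"""Pairwise elution-profile similarity measures for co-fractionation data.

Co-complex members co-elute during biochemical separation, so their
abundance profiles across fractions are similar.  Four complementary
measures are computed per pair: a Poisson-noise-resampled Pearson
correlation (robust to sparse counts), a lag-tolerant weighted
cross-correlation, a co-apex score (elution peak coincidence), and an
ion-intensity distance similarity (L1 between fraction-normalized
profiles).  The exact functional forms are package conventions that
preserve the roles of the classical CF-MS measures.  A cross-species
support filter keeps only pairs scoring > 0.5 in at least two species.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .core import canonical_pair

UNDEFINED = float("nan")


def _validate(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("profiles must be equal-length 1-D vectors of length >= 2")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("profiles must be non-negative")
    return a, b


def _pair_rng(accession_a: str, accession_b: str, seed: int) -> np.random.Generator:
    """Stable per-pair RNG keyed by the sorted accessions and base seed."""
    a, b = canonical_pair(accession_a, accession_b)
    key = zlib.crc32(f"{a}|{b}|{seed}".encode())
    return np.random.default_rng(key)


def poisson_pearson(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    n_repeats: int = 10,
    pseudocount: float = 1.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean Pearson correlation under Poisson resampling of both profiles.

    Each repeat resamples every entry from Poisson(value + pseudocount)
    and correlates the two resampled vectors; zero-variance repeats are
    skipped.  Returns NaN when every repeat is degenerate.
    """
    a, b = _validate(profile_a, profile_b)
    if rng is None:
        rng = np.random.default_rng(seed)
    ra = rng.poisson(a + pseudocount, size=(n_repeats, len(a))).astype(float)
    rb = rng.poisson(b + pseudocount, size=(n_repeats, len(b))).astype(float)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    sa = np.sqrt((ra_c**2).sum(axis=1))
    sb = np.sqrt((rb_c**2).sum(axis=1))
    ok = (sa > 0) & (sb > 0)
    if not ok.any():
        return UNDEFINED
    corr = (ra_c[ok] * rb_c[ok]).sum(axis=1) / (sa[ok] * sb[ok])
    return float(corr.mean())


def co_apex(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """1 / (1 + |apex_a - apex_b|); argmax ties resolve to the earliest
    fraction, so two flat profiles score 1."""
    a, b = _validate(profile_a, profile_b)
    return 1.0 / (1.0 + abs(int(np.argmax(a)) - int(np.argmax(b))))


def weighted_cross_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray, max_lag: int = 3
) -> float:
    """Maximum over lags |l| <= max_lag of the full-norm cross-correlation
    sum_t a[t] b[t+l] / (||a|| ||b||), down-weighted by 1/(1+|l|).

    At max_lag 0 this is exactly cosine similarity.
    """
    a, b = _validate(profile_a, profile_b)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return UNDEFINED
    best = -np.inf
    L = len(a)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            dot = float(np.dot(a[: L - lag], b[lag:]))
        else:
            dot = float(np.dot(a[-lag:], b[: L + lag]))
        best = max(best, dot / (na * nb) / (1.0 + abs(lag)))
    return best


def ms1_intensity_similarity(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """1 - normalized L1 distance between fraction-normalized profiles.

    Profiles are scaled to sum 1; the L1 distance (in [0, 2]) is halved so
    the similarity lives in [0, 1], with 1 for proportional profiles.
    """
    a, b = _validate(profile_a, profile_b)
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        return UNDEFINED
    return 1.0 - 0.5 * float(np.abs(a / sa - b / sb).sum())


def species_support_filter(
    pair_scores: dict[str, list[float]], score_cutoff: float = 0.5, min_species: int = 2
) -> bool:
    """Keep a pair iff at least ``min_species`` species have *any* measure
    strictly greater than ``score_cutoff``."""
    if not pair_scores:
        raise ValueError("need scores for at least one species")
    n_support = sum(
        1
        for scores in pair_scores.values()
        if any(np.isfinite(s) and s > score_cutoff for s in scores)
    )
    return n_support >= min_species


def elution_features(
    elution: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    experiment_name: str = "cofrac",
    n_repeats: int = 10,
    pseudocount: float = 1.0,
    max_lag: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature fragment with the four similarity measures for each pair.

    ``pairs`` restricts computation to candidate pairs (canonicalized);
    by default all within-matrix pairs are scored.  Undefined measures
    (degenerate profiles) are emitted as 0.0 so the downstream zero-filled
    matrix stays consistent.
    """
    proteins = set(elution.index)
    if pairs is None:
        ps = sorted(proteins)
        pairs = [(ps[i], ps[j]) for i in range(len(ps)) for j in range(i + 1, len(ps))]
    else:
        pairs = sorted({canonical_pair(a, b) for a, b in pairs if a in proteins and b in proteins})

    mat = elution.to_numpy(dtype=float)
    row_of = {p: i for i, p in enumerate(elution.index)}
    cols = [
        f"{experiment_name}_poisson_pearson",
        f"{experiment_name}_wcc",
        f"{experiment_name}_co_apex",
        f"{experiment_name}_ms1_sim",
    ]
    values = np.zeros((len(pairs), 4))
    for r, (a, b) in enumerate(pairs):
        pa, pb = mat[row_of[a]], mat[row_of[b]]
        rng = _pair_rng(a, b, seed)
        v = [
            poisson_pearson(pa, pb, n_repeats=n_repeats, pseudocount=pseudocount, rng=rng),
            weighted_cross_correlation(pa, pb, max_lag=max_lag),
            co_apex(pa, pb),
            ms1_intensity_similarity(pa, pb),
        ]
        values[r] = [0.0 if not np.isfinite(x) else x for x in v]
    return pd.DataFrame(
        values,
        index=pd.MultiIndex.from_tuples(pairs, names=["accession_A", "accession_B"]),
        columns=cols,
    )
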