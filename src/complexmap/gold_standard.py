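"""Gold-standard complex handling: redundancy merge, train/test split,
and co-complex pair labeling.

Literature-curated complex catalogues (CORUM-style lists, one complex per
line) are heavily redundant; near-duplicate complexes are merged until no
pair exceeds a Jaccard threshold.  The merged set is split into train and
test halves such that no within-complex protein *pair* occurs in both
splits — the unit of leakage for a co-complex classifier is the pair, not
the complex.  Positive labels are within-complex pairs of a split;
negative labels are cross-complex pairs among that split's proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComplexSet, Pair, canonical_pair, iter_pairs

# Defaults mirroring the published split procedure.
DEFAULT_SEED = 1234
DEFAULT_SIZE_THRESHOLD = 30
DEFAULT_SUBSAMPLE_LARGE = 0.1
DEFAULT_MERGE_THRESHOLD = 0.6


@dataclass
class LabeledPairs:
    """Positive / negative co-complex pair labels for one split."""

    positives: set[Pair]
    negatives: set[Pair]
    split_tag: str = "train"

    def __post_init__(self) -> None:
        clash = self.positives & self.negatives
        if clash:
            raise ValueError(f"{len(clash)} pairs labeled both + and -")


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def merge_redundant(complexes: ComplexSet, jaccard_threshold: float = DEFAULT_MERGE_THRESHOLD) -> ComplexSet:
    """Merge complexes until every pair has Jaccard <= threshold.

    The over-threshold pair with the highest Jaccard is replaced by its
    union, recomputing after each merge (descending-Jaccard order gives a
    deterministic fixed point independent of input ordering).  Exact
    duplicates merge trivially (Jaccard 1).
    """
    if not 0.0 < jaccard_threshold <= 1.0:
        raise ValueError("jaccard_threshold must be in (0,1]")
    current = sorted(set(complexes.complexes), key=lambda c: (-len(c), sorted(c)))
    while True:
        best: tuple[float, int, int] | None = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                jc = jaccard(current[i], current[j])
                if jc > jaccard_threshold and (best is None or jc > best[0]):
                    best = (jc, i, j)
        if best is None:
            break
        _, i, j = best
        merged = current[i] | current[j]
        current = [c for k, c in enumerate(current) if k not in (i, j)]
        current.append(merged)
        current = sorted(set(current), key=lambda c: (-len(c), sorted(c)))
    return ComplexSet(current)


def split_train_test(
    complexes: ComplexSet,
    seed: int = DEFAULT_SEED,
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
    remove_large: bool = True,
    remove_largest: bool = False,
) -> tuple[ComplexSet, ComplexSet]:
    """Randomly split complexes into train/test, removing pair leakage.

    Complexes are shuffled with ``seed`` and assigned alternately.  A
    complex whose within-complex pairs overlap pairs already assigned to
    the *other* split is dropped (the later-assigned complex loses).
    ``remove_large`` drops complexes with more than ``size_threshold``
    members beforehand; ``remove_largest`` additionally drops the single
    largest complex.
    """
    pool = list(complexes.complexes)
    if remove_largest and pool:
        largest = max(pool, key=lambda c: (len(c), sorted(c)))
        pool.remove(largest)
    if remove_large:
        pool = [c for c in pool if len(c) <= size_threshold]

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    train: list[frozenset[str]] = []
    test: list[frozenset[str]] = []
    train_pairs: set[Pair] = set()
    test_pairs: set[Pair] = set()
    for rank, idx in enumerate(order):
        c = pool[idx]
        cpairs = set(iter_pairs(c))
        if rank % 2 == 0:  # train slot
            if cpairs & test_pairs:
                continue
            train.append(c)
            train_pairs |= cpairs
        else:
            if cpairs & train_pairs:
                continue
            test.append(c)
            test_pairs |= cpairs
    return ComplexSet(train), ComplexSet(test)


def derive_labeled_pairs(
    split: ComplexSet,
    all_complexes: ComplexSet,
    subsample_large_pairs: float = DEFAULT_SUBSAMPLE_LARGE,
    seed: int = DEFAULT_SEED,
    size_threshold: int = DEFAULT_SIZE_THRESHOLD,
    split_tag: str = "train",
    exclude: "LabeledPairs | None" = None,
) -> LabeledPairs:
    """Label co-complex pairs for one split.

    Positives: within-complex pairs of the split.  For complexes larger
    than ``size_threshold`` members only a ``subsample_large_pairs``
    fraction of their pairs is retained (floor, dedicated RNG stream).
    Negatives: cross-complex pairs among the split's proteins that are not
    within-complex anywhere in ``all_complexes`` (both proteins must be
    gold-standard complex members; other pairs stay unlabeled).
    ``exclude`` removes pairs already labeled for the other split, keeping
    the two splits' labeled pair sets disjoint.
    """
    if not 0.0 <= subsample_large_pairs <= 1.0:
        raise ValueError("subsample_large_pairs must be in [0,1]")
    rng = np.random.default_rng((seed, 0xC0FFEE))

    positives: set[Pair] = set()
    for c in split.complexes:
        cpairs = sorted(iter_pairs(c))
        if len(c) > size_threshold and subsample_large_pairs < 1.0:
            n_keep = int(np.floor(subsample_large_pairs * len(cpairs)))
            keep_idx = rng.choice(len(cpairs), size=n_keep, replace=False)
            cpairs = [cpairs[i] for i in sorted(keep_idx)]
        positives.update(cpairs)

    # pairs co-complexed anywhere in the full gold standard are never negative
    all_within = all_complexes.within_pairs()
    proteins = sorted(split.proteins)
    negatives: set[Pair] = set()
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            pair = (proteins[i], proteins[j])
            if pair not in all_within:
                negatives.add(pair)
    if exclude is not None:
        taken = exclude.positives | exclude.negatives
        positives -= taken
        negatives -= taken
    return LabeledPairs(positives=positives, negatives=negatives, split_tag=split_tag)
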