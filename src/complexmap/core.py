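"""Core containers shared across the pipeline.

The pipeline's currency is the *unordered protein pair*: every feature,
label and score is keyed by a pair of accessions stored in canonical
(lexicographic) order so that (A, B) and (B, A) always collide.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical lexicographic order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def iter_pairs(members: Iterable[str]) -> Iterator[Pair]:
    """All canonical within-set pairs of a collection of accessions."""
    ms = sorted(set(members))
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            yield (ms[i], ms[j])


@dataclass
class ComplexSet:
    """Ordered collection of protein complexes (sets of accessions).

    ``names`` and ``tiers`` are optional parallel annotations; a tier is a
    confidence label assigned by the clustering-union stage.
    """

    complexes: list[frozenset[str]]
    names: list[str] | None = None
    tiers: list[str] | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if self.names is not None and len(self.names) != len(self.complexes):
            raise ValueError("names length mismatch")
        if self.tiers is not None and len(self.tiers) != len(self.complexes):
            raise ValueError("tiers length mismatch")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def within_pairs(self) -> set[Pair]:
        """Union of all within-complex pairs."""
        pairs: set[Pair] = set()
        for c in self.complexes:
            pairs.update(iter_pairs(c))
        return pairs

    @classmethod
    def from_file(cls, path: str | Path) -> "ComplexSet":
        """Read a complex list: one complex per line, whitespace-separated
        accessions; '#' lines are comments; blank lines skipped."""
        complexes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                members = frozenset(line.split())
                if members:
                    complexes.append(members)
        return cls(complexes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.complexes:
                fh.write(" ".join(sorted(c)) + "\n")


@dataclass
class Experiment:
    """One proteomic observation (e.g. a pull-down): bait-tagged or not,
    a map from protein accession to an abundance score."""

    experiment_id: str
    dataset: str
    observations: dict[str, float]
    bait: str | None = None


@dataclass
class ExperimentSet:
    """A compendium of experiments from one or more datasets."""

    experiments: list[Experiment]

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self) -> Iterator[Experiment]:
        return iter(self.experiments)

    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.experiments:
            seen.setdefault(e.dataset, None)
        return list(seen)

    def subset(self, dataset: str) -> "ExperimentSet":
        exps = [e for e in self.experiments if e.dataset == dataset]
        if not exps:
            raise KeyError(f"unknown dataset: {dataset!r}")
        return ExperimentSet(exps)

    def to_file(self, path: str | Path) -> None:
        """Tab-delimited: experiment_id, dataset, protein_accession, abundance."""
        with open(path, "w") as fh:
            fh.write("experiment_id\tdataset\tprotein_accession\tabundance\n")
            for e in self.experiments:
                for prot in sorted(e.observations):
                    fh.write(f"{e.experiment_id}\t{e.dataset}\t{prot}\t{e.observations[prot]:.6g}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentSet":
        order: list[str] = []
        exps: dict[str, Experiment] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("experiment_id"):
                raise ValueError("missing experiment table header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                eid, dataset, prot, ab = line.split("\t")
                if eid not in exps:
                    exps[eid] = Experiment(eid, dataset, {})
                    order.append(eid)
                exps[eid].observations[prot] = float(ab)
        return cls([exps[e] for e in order])


@dataclass
class ScoredNetwork:
    """Unordered protein pairs with a co-complex probability in [0, 1]."""

    scores: dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score out of [0,1] for {pair}: {s}")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, pair: Pair) -> float:
        return self.scores[pair]

    def items(self) -> Iterable[tuple[Pair, float]]:
        return self.scores.items()

    def to_pairs_w_prob(self, path: str | Path) -> None:
        """Write gzip tab-delimited 'pairsWprob': accession_A, accession_B,
        probability, sorted by pair for byte-stable output."""
        if str(path).endswith(".gz"):
            # mtime pinned to 0 so identical runs give byte-identical files
            raw = gzip.GzipFile(path, "wb", compresslevel=6, mtime=0)
            fh: io.TextIOBase = io.TextIOWrapper(raw, encoding="utf-8")
        else:
            fh = open(path, "w")
        with fh:
            # full float precision: rounding would alias near-1 scores onto
            # the extreme threshold of the clustering sweep
            for (a, b) in sorted(self.scores):
                fh.write(f"{a}\t{b}\t{self.scores[(a, b)]:.17g}\n")

    @classmethod
    def from_pairs_w_prob(cls, path: str | Path) -> "ScoredNetwork":
        opener = gzip.open if str(path).endswith(".gz") else open
        scores: dict[Pair, float] = {}
        with opener(path, "rt") as fh:
            for line in fh:
                a, b, p = line.split()
                scores[canonical_pair(a, b)] = float(p)
        return cls(scores)


# Confidence tiers for the clustering union, best first.
TIER_NAMES = ("ExtremelyHigh", "VeryHigh", "High", "MediumHigh", "Medium")


def write_complex_map(cs: ComplexSet, path: str | Path, prefix: str = "CPX") -> None:
    """Tab-delimited complex map: zero-padded complex id, confidence tier,
    space-separated member accessions."""
    tiers = cs.tiers or ["NA"] * len(cs)
    with open(path, "w") as fh:
        for i, (members, tier) in enumerate(zip(cs.complexes, tiers), start=1):
            fh.write(f"{prefix}_{i:05d}\t{tier}\t{' '.join(sorted(members))}\n")


def read_complex_map(path: str | Path) -> ComplexSet:
    complexes, names, tiers = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, tier, members = line.split("\t")
            names.append(cid)
            tiers.append(tier)
            complexes.append(frozenset(members.split()))
    return ComplexSet(complexes, names=names, tiers=tiers)
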