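"""Assembly of heterogeneous feature fragments into one pairwise matrix.

Fragments (pair-indexed DataFrames from the WMM and co-fractionation
modules) are outer-joined over the union of their pairs; cells a fragment
does not cover are semantically zero, mirroring how sparse evidence over
tens of millions of pairs is densified for a classifier.  Train/test
labels attach as a +1/-1 column; labeled pairs absent from every fragment
enter as all-zero rows so the classifier still sees them.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Pair, canonical_pair
from .gold_standard import LabeledPairs

UNLABELED = 0
POSITIVE = 1
NEGATIVE = -1


def _canonicalize_fragment(frag: pd.DataFrame) -> pd.DataFrame:
    """Reorder any (B, A) index entries to canonical (A, B)."""
    idx = [canonical_pair(a, b) for a, b in frag.index]
    out = frag.copy()
    out.index = pd.MultiIndex.from_tuples(idx, names=["accession_A", "accession_B"])
    if out.index.has_duplicates:
        # same pair listed twice within one fragment: merge if consistent
        grouped = out.groupby(level=[0, 1])
        if (grouped.nunique() > 1).any().any():
            raise ValueError("fragment lists a pair twice with conflicting values")
        out = grouped.first()
    return out


@dataclass
class FeatureMatrix:
    """Pairwise feature matrix with optional labels.

    ``data`` is indexed by canonical pairs with sorted feature columns;
    every cell is defined (missing evidence is 0.0).  ``labels`` maps a
    subset of pairs to +1 / -1.
    """

    data: pd.DataFrame
    labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def pairs(self) -> list[Pair]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def label_counts(self) -> tuple[int, int]:
        pos = int((self.labels == POSITIVE).sum())
        neg = int((self.labels == NEGATIVE).sum())
        return pos, neg

    def labeled_view(self) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
        """(X, y, pairs) over labeled rows only, y in {+1, -1}."""
        labeled = self.labels[self.labels != UNLABELED]
        rows = self.data.loc[labeled.index]
        return rows.to_numpy(dtype=float), labeled.to_numpy(dtype=int), list(labeled.index)

    def to_tsv(self, path: str | Path) -> None:
        """Gzip (or plain) tab-delimited matrix, first two columns
        accession_A / accession_B, mtime pinned for reproducibility."""
        out = self.data.sort_index()
        text = out.to_csv(sep="\t", float_format="%.10g")
        if str(path).endswith(".gz"):
            with gzip.GzipFile(path, "wb", compresslevel=6, mtime=0) as raw:
                with io.TextIOWrapper(raw, encoding="utf-8") as fh:
                    fh.write(text)
        else:
            Path(path).write_text(text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            df = pd.read_csv(fh, sep="\t", index_col=[0, 1])
        return cls(df)


def assemble(fragments: list[pd.DataFrame]) -> FeatureMatrix:
    """Outer-join fragments over the union of pairs with 0.0 fill.

    Column order is sorted and pair order lexicographic, so assembly is
    independent of fragment order.  A feature column appearing in two
    fragments with conflicting values for the same pair is an error.
    """
    if not fragments:
        return FeatureMatrix(
            pd.DataFrame(index=pd.MultiIndex.from_tuples([], names=["accession_A", "accession_B"]))
        )
    frags = [_canonicalize_fragment(f) for f in fragments]

    seen: dict[str, pd.Series] = {}
    for frag in frags:
        for col in frag.columns:
            s = frag[col]
            if col in seen:
                prev = seen[col]
                common = prev.index.intersection(s.index)
                if len(common):
                    bad = common[~np.isclose(prev.loc[common], s.loc[common])]
                    if len(bad):
                        offenders = ", ".join(f"{a}-{b}" for a, b in list(bad[:5]))
                        raise ValueError(
                            f"conflicting values for feature {col!r} at pairs: {offenders}"
                        )
                seen[col] = prev.combine_first(s)
            else:
                seen[col] = s

    df = pd.DataFrame(seen).fillna(0.0)
    df = df[sorted(df.columns)].sort_index()
    df.index.names = ["accession_A", "accession_B"]
    return FeatureMatrix(df)


def attach_labels(matrix: FeatureMatrix, labels: LabeledPairs, add_missing: bool = True) -> FeatureMatrix:
    """Attach +1/-1 labels; labeled pairs missing from the matrix are
    added as all-zero rows when ``add_missing`` (default), so sparsely
    observed gold-standard pairs still reach the classifier."""
    pos = {canonical_pair(a, b) for a, b in labels.positives}
    neg = {canonical_pair(a, b) for a, b in labels.negatives}
    if pos & neg:
        raise ValueError("pairs labeled both positive and negative")

    df = matrix.data
    wanted = sorted((pos | neg) - set(df.index))
    if wanted and add_missing:
        zeros = pd.DataFrame(
            0.0,
            index=pd.MultiIndex.from_tuples(wanted, names=["accession_A", "accession_B"]),
            columns=df.columns,
        )
        df = pd.concat([df, zeros]).sort_index()

    lab = pd.Series(UNLABELED, index=df.index, dtype=int)
    lab.loc[lab.index.isin(pos)] = POSITIVE
    lab.loc[lab.index.isin(neg)] = NEGATIVE
    return FeatureMatrix(df, labels=lab)
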