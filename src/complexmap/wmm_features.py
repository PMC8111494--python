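"""Weighted Matrix Model (WMM) co-occurrence features.

A compendium of N experiments is reduced to presence/absence calls; for
every pair of proteins observed together at least once, the hypergeometric
tail probability of their co-occurrence count is computed:

    p(#shared >= k | n, m, N) = sum_{i=k}^{min(n,m)} C(n,i) C(N-n, m-i) / C(N,m)

where n and m are the pair's marginal presence counts.  Conditioning on
the marginals is what discounts promiscuously detected ("frequent flyer")
proteins: a pair of sticky proteins needs many more shared experiments to
look surprising.  The emitted features are the negative natural log of the
p-value and the raw pair count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import ExperimentSet

ALL = "all"  # sentinel cutoff: any observation counts as presence


@dataclass
class PresenceMatrix:
    """Presence/absence calls over an ordered experiment list."""

    experiments: list[str]
    presence: dict[str, frozenset[int]]
    threshold_rule: str

    def __post_init__(self) -> None:
        if len(self.experiments) < 1:
            raise ValueError("need at least one experiment")
        n = len(self.experiments)
        for prot, idx in self.presence.items():
            if idx and max(idx) >= n:
                raise ValueError(f"presence index out of range for {prot}")

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)


def call_presence(experiments: ExperimentSet, abundance_cutoff: float | str = ALL) -> PresenceMatrix:
    """Call a protein present in an experiment iff abundance > cutoff
    (strict), or on any observation when the cutoff is the "all" sentinel."""
    if isinstance(abundance_cutoff, str):
        if abundance_cutoff != ALL:
            raise ValueError(f"unknown cutoff sentinel: {abundance_cutoff!r}")
        cut = None
    else:
        if abundance_cutoff < 0:
            raise ValueError("abundance_cutoff must be >= 0")
        cut = float(abundance_cutoff)

    exp_ids = [e.experiment_id for e in experiments]
    presence: dict[str, set[int]] = {}
    for i, e in enumerate(experiments):
        for prot, ab in e.observations.items():
            if cut is None or ab > cut:
                presence.setdefault(prot, set()).add(i)
    rule = f"abundance>{cut}" if cut is not None else "any-observation"
    return PresenceMatrix(
        experiments=exp_ids,
        presence={p: frozenset(s) for p, s in presence.items()},
        threshold_rule=rule,
    )


def hypergeom_tail(k: int, n: int, m: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(#shared >= k | n, m, N).

    Computed via the log-space survival function for stability; k = 0
    returns exactly 1.
    """
    if not (0 <= k <= min(n, m) <= N and n <= N and m <= N):
        raise ValueError(f"invalid (k={k}, n={n}, m={m}, N={N})")
    if k == 0:
        return 1.0
    # scipy parameterization: population N, n successes, m draws
    return float(np.exp(hypergeom.logsf(k - 1, N, n, m)))


def neg_ln_hypergeom_tail(k: int, n: int, m: int, N: int) -> float:
    """-ln of :func:`hypergeom_tail`, evaluated without leaving log space."""
    if not (0 <= k <= min(n, m) <= N and n <= N and m <= N):
        raise ValueError(f"invalid (k={k}, n={n}, m={m}, N={N})")
    if k == 0:
        return 0.0
    v = -float(hypergeom.logsf(k - 1, N, n, m))
    return max(v, 0.0)  # clip -0.0 / tiny negative round-off at certainty


def wmm_feature_pairs(
    presence: PresenceMatrix,
    min_pair_count: int = 1,
    feature_prefix: str = "wmm",
) -> pd.DataFrame:
    """Emit one row per unordered pair with k >= max(1, min_pair_count).

    Returns a feature fragment: a DataFrame indexed by canonical pairs
    with columns ``{prefix}_neg_ln_p`` and ``{prefix}_pair_count``.  Pairs
    never observed together are absent (the zero-filled matrix is
    materialized downstream).
    """
    if not presence.presence:
        raise ValueError("empty presence matrix")
    k_min = max(1, min_pair_count)
    N = presence.n_experiments
    proteins = sorted(presence.presence)
    rows = []
    index = []
    for a, b in combinations(proteins, 2):
        sa, sb = presence.presence[a], presence.presence[b]
        k = len(sa & sb)
        if k < k_min:
            continue
        n, m = len(sa), len(sb)
        index.append((a, b))
        rows.append((neg_ln_hypergeom_tail(k, n, m, N), float(k)))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["accession_A", "accession_B"]),
        columns=[f"{feature_prefix}_neg_ln_p", f"{feature_prefix}_pair_count"],
    )


def write_fragment(fragment: pd.DataFrame, path: str | Path) -> None:
    """Long-form tab-delimited fragment: accession_A, accession_B,
    feature_name, value (A < B lexicographically)."""
    with open(path, "w") as fh:
        fh.write("accession_A\taccession_B\tfeature_name\tvalue\n")
        for (a, b), row in fragment.iterrows():
            for name, value in row.items():
                fh.write(f"{a}\t{b}\t{name}\t{value:.10g}\n")


def read_fragment(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot_table(
        index=["accession_A", "accession_B"], columns="feature_name", values="value"
    )
    wide.columns.name = None
    return wide
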