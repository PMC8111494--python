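"""Synthetic proteomic compendia with planted ground-truth complexes.

Emulates the statistical structure the pipeline assumes: pull-down
experiments with bait/prey detection noise and spurious contaminants
(AP-MS / proximity-labeling "matrix" structure), and co-fractionation
elution matrices where co-complex members share a Gaussian elution peak.
Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ComplexSet, Experiment, ExperimentSet


@dataclass
class PlantedWorld:
    """Ground truth for a simulation: planted complexes plus free
    background proteins, over a named proteome."""

    complexes: ComplexSet
    proteome: set[str]
    seed: int

    def __post_init__(self) -> None:
        for c in self.complexes:
            if len(c) < 2:
                raise ValueError("planted complex smaller than 2")
            if not c <= self.proteome:
                raise ValueError("complex member outside proteome")

    @property
    def complex_members(self) -> set[str]:
        return self.complexes.proteins

    @property
    def background_proteins(self) -> set[str]:
        return self.proteome - self.complex_members

    def membership(self) -> dict[str, list[int]]:
        """protein -> indices of the planted complexes containing it."""
        out: dict[str, list[int]] = {}
        for i, c in enumerate(self.complexes):
            for p in c:
                out.setdefault(p, []).append(i)
        return out


def _accession(i: int) -> str:
    return f"P{i:05d}"


def generate_planted_complexes(
    n_complexes: int,
    size_range: tuple[int, int] = (3, 8),
    overlap_fraction: float = 0.2,
    n_background_proteins: int = 100,
    seed: int = 0,
) -> PlantedWorld:
    """Plant ``n_complexes`` complexes with sizes uniform in ``size_range``.

    A fraction ``overlap_fraction`` of the complexes (rounded, never the
    first) share exactly one member with a previously planted complex,
    giving promiscuous proteins; all other members are fresh accessions.
    Background proteins belong to no complex.
    """
    lo, hi = size_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid size_range {size_range}")
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0,1]")
    if n_background_proteins < 0:
        raise ValueError("n_background_proteins must be >= 0")

    rng = np.random.default_rng(seed)
    n_overlapping = int(round(overlap_fraction * n_complexes))
    n_overlapping = min(n_overlapping, n_complexes - 1)
    # which complexes (beyond the first) borrow a member from an earlier one
    overlap_idx: set[int] = set()
    if n_overlapping > 0:
        overlap_idx = set(
            rng.choice(np.arange(1, n_complexes), size=n_overlapping, replace=False).tolist()
        )

    next_id = 0
    complexes: list[frozenset[str]] = []
    for ci in range(n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        if ci in overlap_idx:
            donor = complexes[int(rng.integers(0, len(complexes)))]
            members.add(sorted(donor)[int(rng.integers(0, len(donor)))])
        while len(members) < size:
            members.add(_accession(next_id))
            next_id += 1
        complexes.append(frozenset(members))

    background = {_accession(next_id + i) for i in range(n_background_proteins)}
    proteome = set().union(*complexes) | background if complexes else set(background)
    return PlantedWorld(ComplexSet(complexes), proteome, seed)


def _draw_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    # shifted log-normal: positive scores with a spectral-count-like tail,
    # so that >2 / >4 presence cutoffs split the distribution non-trivially
    return 1.0 + rng.lognormal(mean=1.0, sigma=0.9, size=n)


def simulate_pulldowns(
    world: PlantedWorld,
    n_experiments: int,
    bait_policy: str = "uniform-over-complex-members",
    member_detect_prob: float = 0.9,
    contaminant_rate: float = 2.0,
    seed: int = 0,
    dataset: str = "synthetic_apms",
) -> ExperimentSet:
    """Simulate bait pull-down experiments over a planted world.

    Each experiment has one bait (always detected).  Every co-complex
    partner of the bait is detected with ``member_detect_prob``; a
    Poisson(``contaminant_rate``) number of spurious proteins is drawn
    uniformly from the whole proteome (complex members included, creating
    "frequent flyer" pressure).  Baits cycle round-robin over a seeded
    shuffle of all complex members so small runs still cover every complex.
    """
    if len(world.complexes) == 0:
        raise ValueError("world has no planted complexes")
    if not 0.0 <= member_detect_prob <= 1.0:
        raise ValueError("member_detect_prob must be in [0,1]")
    if contaminant_rate < 0:
        raise ValueError("contaminant_rate must be >= 0")
    if bait_policy != "uniform-over-complex-members":
        raise ValueError(f"unknown bait_policy: {bait_policy!r}")

    rng = np.random.default_rng(seed)
    membership = world.membership()
    bait_pool = sorted(world.complex_members)
    rng.shuffle(bait_pool)
    proteome = np.array(sorted(world.proteome))

    experiments = []
    for i in range(n_experiments):
        bait = bait_pool[i % len(bait_pool)]
        present = {bait}
        for ci in membership[bait]:
            # sorted: RNG consumption must not depend on set hash order
            for partner in sorted(world.complexes[ci]):
                if partner != bait and rng.random() < member_detect_prob:
                    present.add(partner)
        n_cont = int(rng.poisson(contaminant_rate))
        if n_cont:
            present.update(rng.choice(proteome, size=n_cont, replace=True).tolist())
        prots = sorted(present)
        abundances = _draw_abundance(rng, len(prots))
        experiments.append(
            Experiment(
                experiment_id=f"{dataset}_{i:05d}",
                dataset=dataset,
                observations=dict(zip(prots, abundances.tolist())),
                bait=bait,
            )
        )
    return ExperimentSet(experiments)


def simulate_elution_profiles(
    world: PlantedWorld,
    n_fractions: int = 60,
    peak_sd: float = 2.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a co-fractionation elution matrix (protein x fraction).

    Each complex draws a shared Gaussian peak center; members' profiles are
    that peak scaled by a per-protein amplitude with multiplicative
    log-normal noise (``noise_sd`` = sigma of log).  A protein in several
    complexes sums their peaks.  Background proteins get independent
    random centers.  All values are non-negative.
    """
    if n_fractions < 5:
        raise ValueError("n_fractions must be >= 5")
    rng = np.random.default_rng(seed)
    fractions = np.arange(n_fractions, dtype=float)
    centers = rng.uniform(peak_sd, n_fractions - 1 - peak_sd, size=len(world.complexes))

    def peak(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((fractions - center) / peak_sd) ** 2)

    membership = world.membership()
    proteins = sorted(world.proteome)
    rows = np.zeros((len(proteins), n_fractions))
    for r, prot in enumerate(proteins):
        if prot in membership:
            base = np.zeros(n_fractions)
            for ci in membership[prot]:
                base = base + peak(centers[ci])
        else:
            base = peak(float(rng.uniform(peak_sd, n_fractions - 1 - peak_sd)))
        amplitude = float(rng.lognormal(3.0, 0.5))
        noise = rng.lognormal(0.0, noise_sd, size=n_fractions) if noise_sd > 0 else 1.0
        rows[r] = amplitude * base * noise

    return pd.DataFrame(
        rows, index=proteins, columns=[f"frac_{i:03d}" for i in range(n_fractions)]
    )


def write_elution_matrix(elution: pd.DataFrame, path: str | Path) -> None:
    elution.to_csv(path, sep="\t", index_label="protein", float_format="%.6g")


def read_elution_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein")
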