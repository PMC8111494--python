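"""End-to-end orchestration: simulate -> features -> classify -> cluster
-> evaluate -> post-analysis.

A single :class:`PipelineConfig` drives the run; one top-level seed
deterministically derives a per-stage seed as
``(seed * 1000003 + stage_offset) % 2**31``, so one integer reproduces
the whole run.  Every stage writes plain text files and records them in a
JSON manifest with SHA-256 hashes; a re-run with an existing manifest
skips stages whose outputs are present and hash-clean (resume).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cofrac_features, synthetic_data, wmm_features
from .complex_clustering import (
    ClusteringParams,
    parameter_sweep,
    select_and_union,
    select_tiers,
)
from .copairs_classifier import cv_grid_search, precision_recall, train_and_score
from .core import ComplexSet, ExperimentSet, ScoredNetwork, read_complex_map, write_complex_map
from .feature_matrix import FeatureMatrix, assemble, attach_labels
from .gold_standard import LabeledPairs, derive_labeled_pairs, merge_redundant, split_train_test
from .kclique_eval import complex_recovery_rate, weighted_kpr
from .post_analysis import nonredundant_set, promiscuous_proteins

log = logging.getLogger("complexmap")

STAGES = ("simulate", "gold", "features", "train", "score", "sweep", "union", "evaluate", "postanalyze")
_STAGE_OFFSET = {name: i + 1 for i, name in enumerate(STAGES)}


def stage_seed(top_seed: int, stage: str) -> int:
    """Documented derivation of per-stage seeds from the top-level seed."""
    return (top_seed * 1000003 + _STAGE_OFFSET[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """All pipeline parameters with their packaged defaults.

    The gold-standard and model-selection defaults are the published
    procedure's printed values (split seed 1234, size threshold 30,
    large-complex pair subsample 0.1, merge threshold 0.6, the SVM C and
    gamma grids); simulation sizes default to a desk-scale compendium.
    """

    out_dir: str = "pipeline_out"
    seed: int = 1234

    # synthetic world / compendium
    n_complexes: int = 30
    size_min: int = 3
    size_max: int = 8
    overlap_fraction: float = 0.2
    n_background_proteins: int = 100
    n_experiments: int = 400
    member_detect_prob: float = 0.9
    contaminant_rate: float = 2.0
    n_fractions: int = 60
    peak_sd: float = 2.0
    noise_sd: float = 0.1

    # gold standard split
    merge_threshold: float = 0.6
    size_threshold: int = 30
    subsample_large_pairs: float = 0.1
    remove_large: bool = True
    remove_largest: bool = False

    # WMM presence cutoffs ("all" sentinel or numeric, strict >)
    wmm_cutoffs: list = field(default_factory=lambda: ["all", 2.0, 4.0])

    # classifier
    C_grid: list = field(default_factory=lambda: [2.0, 8.0, 32.0, 128.0, 512.0])
    gamma_grid: list = field(
        default_factory=lambda: [0.00048828125, 0.001953125, 0.0078125, 0.03125]
    )
    k_folds: int = 5

    # clustering sweep (reduced demo grid; full grids live in
    # complex_clustering defaults)
    sweep_thresholds: list = field(default_factory=lambda: [1.0, 0.9, 0.7, 0.5, 0.2, 0.05])
    sweep_densities: list = field(default_factory=lambda: [0.1, 0.4])
    sweep_overlaps: list = field(default_factory=lambda: [0.6, 0.8])
    sweep_inflations: list = field(default_factory=lambda: [2.0, 4.0, 9.0])
    n_tiers: int = 5
    kclique_max_samples: int = 10000

    # post-analysis
    sc_cutoff: float = 0.5
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Range/sanity checks; problems are returned, not raised."""
    problems = []
    if config.n_complexes < 1:
        problems.append("n_complexes must be >= 1")
    if config.size_min < 2 or config.size_max < config.size_min:
        problems.append("invalid complex size range")
    if not 0 <= config.overlap_fraction <= 1:
        problems.append("overlap_fraction must be in [0,1]")
    if not 0 <= config.member_detect_prob <= 1:
        problems.append("member_detect_prob must be in [0,1]")
    if config.contaminant_rate < 0:
        problems.append("contaminant_rate must be >= 0")
    if config.n_fractions < 5:
        problems.append("n_fractions must be >= 5")
    if not 0 < config.merge_threshold <= 1:
        problems.append("merge_threshold must be in (0,1]")
    if not (config.C_grid and config.gamma_grid):
        problems.append("empty SVM hyperparameter grid")
    if config.k_folds < 2:
        problems.append("k_folds must be >= 2")
    for name in ("sweep_thresholds", "sweep_densities", "sweep_overlaps", "sweep_inflations"):
        if not getattr(config, name):
            problems.append(f"{name} must be non-empty")
    for infl in config.sweep_inflations:
        if infl <= 1:
            problems.append(f"mcl inflation must be > 1 (got {infl})")
    for t in config.sweep_thresholds:
        if not 0 <= t <= 1:
            problems.append(f"score threshold out of [0,1]: {t}")
    if not 0 < config.sc_cutoff <= 1:
        problems.append("sc_cutoff must be in (0,1]")
    if not 0 < config.alpha < 1:
        problems.append("alpha must be in (0,1)")
    try:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        problems.append(f"out_dir not writable: {exc}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}, "metrics": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec:
            return False
        for fname, digest in rec["outputs"].items():
            p = self.path.parent / fname
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], metrics: dict | None = None) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        if metrics:
            self.data["metrics"].update(metrics)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _write_pairs(pairs: set, path: Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def _read_pairs(path: Path) -> set:
    out = set()
    with open(path) as fh:
        for line in fh:
            a, b = line.split()
            out.add((a, b))
    return out


def run_pipeline(config: PipelineConfig, resume: bool = True) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Stage outputs are plain files under ``config.out_dir``; completed
    stages with hash-clean outputs are skipped when ``resume``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    config.to_yaml(out / "config.yaml")

    def done(stage: str) -> bool:
        if resume and manifest.stage_done(stage):
            log.info("[%s] up to date, skipping", stage)
            return True
        log.info("[%s] running", stage)
        return False

    # ---- simulate -------------------------------------------------------
    if not done("simulate"):
        s = stage_seed(config.seed, "simulate")
        world = synthetic_data.generate_planted_complexes(
            config.n_complexes,
            (config.size_min, config.size_max),
            config.overlap_fraction,
            config.n_background_proteins,
            seed=s,
        )
        experiments = synthetic_data.simulate_pulldowns(
            world,
            config.n_experiments,
            member_detect_prob=config.member_detect_prob,
            contaminant_rate=config.contaminant_rate,
            seed=s + 1,
        )
        elution = synthetic_data.simulate_elution_profiles(
            world,
            n_fractions=config.n_fractions,
            peak_sd=config.peak_sd,
            noise_sd=config.noise_sd,
            seed=s + 2,
        )
        world.complexes.to_file(out / "planted_complexes.txt")
        (out / "planted_proteome.txt").write_text("\n".join(sorted(world.proteome)) + "\n")
        experiments.to_file(out / "experiments.tsv")
        synthetic_data.write_elution_matrix(elution, out / "elution.tsv")
        manifest.record(
            "simulate",
            [out / "planted_complexes.txt", out / "planted_proteome.txt",
             out / "experiments.tsv", out / "elution.tsv"],
            {"n_planted_complexes": len(world.complexes), "n_proteins": len(world.proteome)},
        )

    # ---- gold standard --------------------------------------------------
    if not done("gold"):
        planted = ComplexSet.from_file(out / "planted_complexes.txt")
        merged = merge_redundant(planted, config.merge_threshold)
        train_cs, test_cs = split_train_test(
            merged,
            seed=stage_seed(config.seed, "gold"),
            size_threshold=config.size_threshold,
            remove_large=config.remove_large,
            remove_largest=config.remove_largest,
        )
        train_cs.to_file(out / "train_complexes.txt")
        test_cs.to_file(out / "test_complexes.txt")
        gseed = stage_seed(config.seed, "gold")
        train_lab = derive_labeled_pairs(
            train_cs, merged, config.subsample_large_pairs, gseed,
            config.size_threshold, "train",
        )
        test_lab = derive_labeled_pairs(
            test_cs, merged, config.subsample_large_pairs, gseed,
            config.size_threshold, "test", exclude=train_lab,
        )
        _write_pairs(train_lab.positives, out / "train_pos_pairs.tsv")
        _write_pairs(train_lab.negatives, out / "train_neg_pairs.tsv")
        _write_pairs(test_lab.positives, out / "test_pos_pairs.tsv")
        _write_pairs(test_lab.negatives, out / "test_neg_pairs.tsv")
        manifest.record(
            "gold",
            [out / "train_complexes.txt", out / "test_complexes.txt",
             out / "train_pos_pairs.tsv", out / "train_neg_pairs.tsv",
             out / "test_pos_pairs.tsv", out / "test_neg_pairs.tsv"],
            {"n_train_complexes": len(train_cs), "n_test_complexes": len(test_cs),
             "n_train_pos": len(train_lab.positives), "n_test_pos": len(test_lab.positives)},
        )

    # ---- features -------------------------------------------------------
    if not done("features"):
        experiments = ExperimentSet.from_file(out / "experiments.tsv")
        elution = synthetic_data.read_elution_matrix(out / "elution.tsv")
        fragments = []
        for cutoff in config.wmm_cutoffs:
            tag = "all" if cutoff == "all" else f"gt{cutoff:g}".replace(".", "p")
            presence = wmm_features.call_presence(experiments, cutoff)
            fragments.append(
                wmm_features.wmm_feature_pairs(presence, feature_prefix=f"wmm_{tag}")
            )
        candidate_pairs = set()
        for frag in fragments:
            candidate_pairs.update(frag.index)
        train_lab = LabeledPairs(
            _read_pairs(out / "train_pos_pairs.tsv"),
            _read_pairs(out / "train_neg_pairs.tsv"),
            "train",
        )
        test_lab = LabeledPairs(
            _read_pairs(out / "test_pos_pairs.tsv"),
            _read_pairs(out / "test_neg_pairs.tsv"),
            "test",
        )
        candidate_pairs |= train_lab.positives | train_lab.negatives
        candidate_pairs |= test_lab.positives | test_lab.negatives
        fragments.append(
            cofrac_features.elution_features(
                elution,
                pairs=sorted(candidate_pairs),
                seed=stage_seed(config.seed, "features"),
            )
        )
        matrix = assemble(fragments)
        matrix = attach_labels(matrix, train_lab)
        matrix.to_tsv(out / "feature_matrix.tsv.gz")
        matrix.labels.to_csv(out / "train_labels.tsv", sep="\t", header=["label"])
        manifest.record(
            "features",
            [out / "feature_matrix.tsv.gz", out / "train_labels.tsv"],
            {"n_pairs": len(matrix), "n_features": len(matrix.feature_names)},
        )

    # ---- train (model selection) ---------------------------------------
    if not done("train"):
        matrix = _load_labeled_matrix(out)
        cv = cv_grid_search(
            matrix,
            tuple(config.C_grid),
            tuple(config.gamma_grid),
            k_folds=config.k_folds,
            seed=stage_seed(config.seed, "train"),
        )
        cv.table.to_csv(out / "cv_grid.tsv", sep="\t", index=False)
        (out / "chosen_params.json").write_text(
            json.dumps({"C": cv.best_C, "gamma": cv.best_gamma, "cv_auprc": cv.best_auprc})
            + "\n"
        )
        manifest.record(
            "train",
            [out / "cv_grid.tsv", out / "chosen_params.json"],
            {"chosen_C": cv.best_C, "chosen_gamma": cv.best_gamma, "cv_auprc": cv.best_auprc},
        )

    # ---- score ----------------------------------------------------------
    if not done("score"):
        matrix = _load_labeled_matrix(out)
        chosen = json.loads((out / "chosen_params.json").read_text())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            network = train_and_score(
                matrix, chosen["C"], chosen["gamma"], seed=stage_seed(config.seed, "score")
            )
        network.to_pairs_w_prob(out / "pairsWprob.gz")
        manifest.record("score", [out / "pairsWprob.gz"], {"n_scored_pairs": len(network)})

    # ---- sweep ----------------------------------------------------------
    if not done("sweep"):
        network = ScoredNetwork.from_pairs_w_prob(out / "pairsWprob.gz")
        train_cs = ComplexSet.from_file(out / "train_complexes.txt")
        sweep = parameter_sweep(
            network,
            train_cs,
            tuple(config.sweep_thresholds),
            tuple(config.sweep_overlaps),
            tuple(config.sweep_densities),
            tuple(config.sweep_inflations),
            max_samples=config.kclique_max_samples,
            seed=stage_seed(config.seed, "sweep"),
        )
        sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
        manifest.record("sweep", [out / "sweep.tsv"], {"n_sweep_rows": len(sweep)})

    # ---- union ----------------------------------------------------------
    if not done("union"):
        import pandas as pd

        network = ScoredNetwork.from_pairs_w_prob(out / "pairsWprob.gz")
        sweep = pd.read_csv(out / "sweep.tsv", sep="\t")
        selected = select_tiers(sweep, n_tiers=config.n_tiers)
        (out / "selected_params.tsv").write_text(
            "score_threshold\tc1_density\tc1_max_overlap\tmcl_inflation\n"
            + "\n".join(
                f"{p.score_threshold}\t{p.c1_density}\t{p.c1_max_overlap}\t{p.mcl_inflation}"
                for p in selected
            )
            + "\n"
        )
        final = select_and_union(network, tuple(selected))
        write_complex_map(final, out / "complex_map.tsv")
        manifest.record(
            "union",
            [out / "selected_params.tsv", out / "complex_map.tsv"],
            {"n_final_complexes": len(final)},
        )

    # ---- evaluate -------------------------------------------------------
    if not done("evaluate"):
        network = ScoredNetwork.from_pairs_w_prob(out / "pairsWprob.gz")
        final = read_complex_map(out / "complex_map.tsv")
        test_lab = LabeledPairs(
            _read_pairs(out / "test_pos_pairs.tsv"),
            _read_pairs(out / "test_neg_pairs.tsv"),
            "test",
        )
        train_lab = LabeledPairs(
            _read_pairs(out / "train_pos_pairs.tsv"),
            _read_pairs(out / "train_neg_pairs.tsv"),
            "train",
        )
        pr = precision_recall(network, test_lab, train_labels=train_lab)
        test_cs = ComplexSet.from_file(out / "test_complexes.txt")
        planted = ComplexSet.from_file(out / "planted_complexes.txt")
        kpr = weighted_kpr(
            final, test_cs, max_samples=config.kclique_max_samples,
            seed=stage_seed(config.seed, "evaluate"),
        )
        recovery = complex_recovery_rate(final, planted)
        kpr.to_file(out / "kclique_report.tsv")
        metrics = {
            "test_auprc": round(pr.auprc, 6),
            "kpr_precision": round(kpr.p_weighted, 6),
            "kpr_recall": round(kpr.r_weighted, 6),
            "planted_recovery": round(recovery, 6),
        }
        (out / "report.txt").write_text(
            "".join(f"{k}\t{v}\n" for k, v in sorted(metrics.items()))
        )
        manifest.record("evaluate", [out / "kclique_report.tsv", out / "report.txt"], metrics)

    # ---- postanalyze ----------------------------------------------------
    if not done("postanalyze"):
        final = read_complex_map(out / "complex_map.tsv")
        nonred = nonredundant_set(final, sc_cutoff=config.sc_cutoff)
        write_complex_map(nonred, out / "nonredundant_complexes.tsv")
        prom = promiscuous_proteins(nonred)
        with open(out / "promiscuous_proteins.tsv", "w") as fh:
            fh.write("protein\tn_complexes\n")
            for p, n in prom.items():
                fh.write(f"{p}\t{n}\n")
        manifest.record(
            "postanalyze",
            [out / "nonredundant_complexes.tsv", out / "promiscuous_proteins.tsv"],
            {"n_nonredundant": len(nonred), "n_promiscuous": len(prom),
             "max_memberships": max(prom.values()) if prom else 0},
        )

    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest.data


def _load_labeled_matrix(out: Path) -> FeatureMatrix:
    import pandas as pd

    matrix = FeatureMatrix.from_tsv(out / "feature_matrix.tsv.gz")
    labels = pd.read_csv(out / "train_labels.tsv", sep="\t", index_col=[0, 1])["label"]
    matrix.labels = labels.reindex(matrix.data.index).fillna(0).astype(int)
    return matrix
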