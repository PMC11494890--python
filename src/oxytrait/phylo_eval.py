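"""Phylogeny-aware evaluation.

Because traits and genome composition are both vertically inherited, a
random train/test split overstates how well a classifier extrapolates to
unseen clades. This module provides:

* a class-stratified test split (20% of the genomes within every
  phylogenetic class reserved for testing),
* a simple random validation split,
* grouped holdout splits in which whole taxa at a chosen rank are
  withheld together (no taxon straddles the train/held boundary),
* the "random relative" baseline — predict a query's phenotype by
  sampling the label of a random taxon-mate at a prescribed rank,
  abstaining when no relative exists — together with per-rank
  accuracy/coverage curves,
* grouped cross-validation of any feature set / model configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    EvalReport,
    TrainConfig,
    evaluate,
    train_logistic,
    train_mlp,
)
from .dataio import RANKS, Dataset
from .features import FeatureSpec, build_feature_matrix

__all__ = [
    "SplitPlan",
    "RelativeCurve",
    "ABSTAIN",
    "stratified_test_split",
    "validation_split",
    "group_holdout_splits",
    "random_relative_predict",
    "relative_curve",
    "phylo_cv",
]

ABSTAIN = "ABSTAIN"


@dataclass
class SplitPlan:
    """Leakage-free train/held-out genome id sets, optionally rank-grouped."""

    rank: str | None
    splits: list[tuple[list[str], list[str]]]
    fraction_held: float
    seed: int

    def __post_init__(self) -> None:
        for train_ids, held_ids in self.splits:
            overlap = set(train_ids) & set(held_ids)
            if overlap:
                raise ValueError(f"split leaks genome ids: {sorted(overlap)[:5]}")

    def assert_no_taxon_leakage(self, dataset: Dataset) -> None:
        """Raise if any taxon at the plan's rank appears on both sides."""
        if self.rank is None:
            return
        for train_ids, held_ids in self.splits:
            train_taxa = {dataset[g].taxonomy.at(self.rank) for g in train_ids}
            held_taxa = {dataset[g].taxonomy.at(self.rank) for g in held_ids}
            shared = (train_taxa & held_taxa) - {None}
            if shared:
                raise AssertionError(
                    f"taxon leakage at rank {self.rank!r}: {sorted(shared)[:5]}"
                )

    def to_tsv(self, path) -> None:
        rows = []
        for i, (train_ids, held_ids) in enumerate(self.splits):
            rows += [(g, i, "train") for g in train_ids]
            rows += [(g, i, "held") for g in held_ids]
        pd.DataFrame(rows, columns=["genome_id", "split_index", "role"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class RelativeCurve:
    """Per-rank (accuracy-on-covered, coverage) of the random-relative baseline."""

    per_rank: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, a, c) for r, (a, c) in self.per_rank.items()],
            columns=["rank", "accuracy_on_covered", "coverage"],
        )


def _require_labels(dataset: Dataset) -> None:
    unlabeled = [r.genome_id for r in dataset if r.label is None]
    if unlabeled:
        raise ValueError(
            f"dataset contains unlabeled genomes (e.g. {unlabeled[:3]})"
        )


def stratified_test_split(
    dataset: Dataset,
    fraction: float = 0.2,
    stratify_rank: str = "class",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Reserve ``fraction`` of genomes within every taxon at a rank.

    Within each taxon of size n >= 2, floor(fraction*n) genomes (at least
    one) are sampled without replacement into the test set; singleton
    taxa stay in training.
    """
    _require_labels(dataset)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    groups: dict[str | None, list[str]] = {}
    for rec in dataset:
        groups.setdefault(rec.taxonomy.at(stratify_rank), []).append(rec.genome_id)
    test: list[str] = []
    for taxon in sorted(groups, key=str):
        members = groups[taxon]
        if len(members) < 2:
            continue
        n_take = max(int(np.floor(fraction * len(members))), 1)
        test.extend(rng.choice(members, size=n_take, replace=False))
    test_set = set(test)
    train = [g for g in dataset.genome_ids if g not in test_set]
    return train, sorted(test)


def validation_split(
    train_ids: list[str], fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Unstratified random split of training ids into fit/validation sets."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    ids = list(train_ids)
    n_val = max(int(np.floor(fraction * len(ids))), 1)
    val = set(rng.choice(ids, size=n_val, replace=False))
    return [g for g in ids if g not in val], sorted(val)


def group_holdout_splits(
    dataset: Dataset,
    rank: str,
    n_splits: int = 5,
    fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Withhold whole taxa at ``rank`` until ~``fraction`` of genomes are held.

    Taxa are shuffled and accumulated greedily until the held genome count
    first reaches fraction * total. Genomes with no name at the rank are
    excluded (with a warning reporting how many).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    taxa: dict[str, list[str]] = {}
    n_missing = 0
    for rec in dataset:
        name = rec.taxonomy.at(rank)
        if name is None:
            n_missing += 1
            continue
        taxa.setdefault(name, []).append(rec.genome_id)
    if n_missing:
        warnings.warn(
            f"{n_missing} genomes lack a name at rank {rank!r} and were excluded"
        )
    total = sum(len(v) for v in taxa.values())
    if len(taxa) < 2:
        raise ValueError(f"cannot split: only {len(taxa)} taxon at rank {rank!r}")
    biggest = max(len(v) for v in taxa.values())
    if biggest > (1.0 - fraction) * total:
        raise ValueError(
            f"one taxon at rank {rank!r} holds {biggest}/{total} genomes; "
            f"no leakage-free ~{fraction:.0%} holdout exists"
        )
    rng = np.random.default_rng(seed)
    names = sorted(taxa)
    target = fraction * total
    splits: list[tuple[list[str], list[str]]] = []
    for _ in range(n_splits):
        order = rng.permutation(len(names))
        held_taxa: set[str] = set()
        held_n = 0
        for idx in order:
            name = names[idx]
            if len(taxa[name]) > (1.0 - fraction) * total:
                continue  # oversized taxon can never be held
            held_taxa.add(name)
            held_n += len(taxa[name])
            if held_n >= target:
                break
        held, train = [], []
        for name in names:
            (held if name in held_taxa else train).extend(taxa[name])
        splits.append((train, held))
    plan = SplitPlan(rank=rank, splits=splits, fraction_held=fraction, seed=seed)
    plan.assert_no_taxon_leakage(dataset)
    return plan


def random_relative_predict(
    query_id: str,
    reference: Dataset,
    rank: str,
    seed: int | np.random.Generator = 0,
) -> str:
    """Label of a uniformly sampled taxon-mate at ``rank``, or ABSTAIN.

    Abstains when the query has no taxonomy at the rank or no labeled
    relative (other than itself) shares its taxon name.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    query = reference[query_id]
    taxon = query.taxonomy.at(rank)
    if taxon is None:
        return ABSTAIN
    mates = [
        r
        for r in reference
        if r.genome_id != query_id
        and r.taxonomy.at(rank) == taxon
        and r.label is not None
    ]
    if not mates:
        return ABSTAIN
    return mates[rng.integers(len(mates))].label


def relative_curve(
    dataset: Dataset,
    ranks: tuple[str, ...] = RANKS[1:],
    n_repeats: int = 1,
    seed: int = 0,
) -> RelativeCurve:
    """Leave-one-out random-relative accuracy and coverage per rank.

    Accuracy is computed on covered queries only (those with at least one
    labeled relative); coverage is the covered fraction of all queries.
    Both are averaged over ``n_repeats`` random relative draws.
    """
    _require_labels(dataset)
    rng = np.random.default_rng(seed)
    curve = RelativeCurve()
    for rank in ranks:
        # index genomes by taxon once per rank
        acc_sum, cov_sum = 0.0, 0.0
        for _ in range(n_repeats):
            n_correct = n_covered = 0
            for rec in dataset:
                pred = random_relative_predict(rec.genome_id, dataset, rank, rng)
                if pred == ABSTAIN:
                    continue
                n_covered += 1
                n_correct += pred == rec.label
            cov_sum += n_covered / len(dataset)
            acc_sum += (n_correct / n_covered) if n_covered else np.nan
        curve.per_rank[rank] = (acc_sum / n_repeats, cov_sum / n_repeats)
    return curve


def phylo_cv(
    dataset: Dataset,
    feature_spec: FeatureSpec,
    config: TrainConfig,
    ranks: tuple[str, ...] = ("family", "order", "class"),
    n_splits: int = 5,
    fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, list[EvalReport]]:
    """Grouped cross-validation: per rank, train on non-held taxa and
    evaluate balanced accuracy on the withheld ones.

    The full feature matrix is built once and subset per split. For the
    MLP an internal 20% validation split of the training genomes drives
    epoch selection.
    """
    _require_labels(dataset)
    matrix = build_feature_matrix(dataset, feature_spec)
    labels = {r.genome_id: r.label for r in dataset}
    reports: dict[str, list[EvalReport]] = {}
    for rank in ranks:
        plan = group_holdout_splits(dataset, rank, n_splits, fraction, seed)
        plan.assert_no_taxon_leakage(dataset)
        rank_reports = []
        for split_i, (train_ids, held_ids) in enumerate(plan.splits):
            X_tr = matrix.subset(train_ids)
            X_te = matrix.subset(held_ids)
            y_tr = [labels[g] for g in train_ids]
            y_te = [labels[g] for g in held_ids]
            split_seed = (seed + 1009 * split_i) % (2**31)
            cfg = TrainConfig(**{**config.__dict__, "seed": split_seed})
            if config.model_kind == "mlp":
                fit_ids, val_ids = validation_split(train_ids, 0.2, split_seed)
                model = train_mlp(
                    matrix.subset(fit_ids),
                    [labels[g] for g in fit_ids],
                    matrix.subset(val_ids),
                    [labels[g] for g in val_ids],
                    cfg,
                )
            else:
                model = train_logistic(X_tr, y_tr, cfg)
            rank_reports.append(evaluate(model, X_te, y_te))
        reports[rank] = rank_reports
    return reports


def cv_summary(reports: dict[str, list[EvalReport]]) -> pd.DataFrame:
    """Mean and sd of balanced accuracy per rank."""
    rows = []
    for rank, reps in reports.items():
        accs = [r.balanced_accuracy for r in reps]
        rows.append((rank, float(np.mean(accs)), float(np.std(accs)), len(accs)))
    return pd.DataFrame(
        rows, columns=["rank", "balanced_accuracy_mean", "balanced_accuracy_sd", "n_splits"]
    )
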