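"""Restricted cross-validation of breeding-value prediction.

Implements 10-fold × 5-replicate cross-validation with three folding
schemes:

* ``random`` — individuals shuffled into k near-equal folds;
* ``family`` — whole OP families assigned to folds, so no family
  straddles training and validation (removes pedigree links between
  the two sets);
* ``block`` — leave-one-block-out validation; within each round the
  remaining blocks form the training population, which is additionally
  divided into k folds (one training model per left-out fold, the
  validation block's predictions averaged over the k models).  A
  simpler ``loo`` block mode trains a single model on all remaining
  blocks.

During a training fit, validation individuals keep their rows/columns
in the genomic kernels but lose their phenotypes, so marker-based
models can propagate information across families while the
pedigree-based model predicts through pedigree links only.

Accuracy is the Pearson correlation, per replication, between
predicted breeding values (PBV) of withheld individuals and the
reference EBV from the full-data fit; its standard error is the SD of
the replication-level correlations divided by sqrt(replications).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import RelationshipKernel
from .remlfit import FitOptions, REMLFit, fit, model_spec

__all__ = [
    "Split",
    "FoldingPlan",
    "CVResult",
    "make_folds",
    "cross_validate",
    "accuracy",
    "sem",
    "evaluate_accuracy",
    "consistency_matrix",
]

SCHEMES = ("random", "block", "family")


@dataclass(frozen=True)
class Split:
    """One training/validation partition within a replication."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    tag: str = ""


@dataclass
class FoldingPlan:
    scheme: str
    k: int
    replications: int
    seed: int
    block_mode: str
    splits: list[list[Split]]  # [replication][round]

    def assignment(self, replication: int) -> dict[str, int]:
        """id → validation-fold index (random/family schemes)."""
        if self.scheme == "block":
            raise ValueError("block scheme has no single-fold assignment")
        out: dict[str, int] = {}
        for f, split in enumerate(self.splits[replication]):
            for i in split.validation_ids:
                out[i] = f
        return out


@dataclass
class CVResult:
    """Replication-level accuracies for one (EBV model, PBV model, scheme)."""

    ebv_model: str
    pbv_model: str
    scheme: str
    correlations: list[float]

    @property
    def mean(self) -> float:
        vals = [c for c in self.correlations if np.isfinite(c)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sem(self) -> float:
        vals = [c for c in self.correlations if np.isfinite(c)]
        return sem(vals) if len(vals) >= 2 else float("nan")


def _partition(rng: np.random.Generator, items: Sequence[str], k: int) -> list[list[str]]:
    order = list(items)
    rng.shuffle(order)
    return [order[i::k] for i in range(k)]


def make_folds(
    ids: Sequence[str],
    families: Mapping[str, str],
    blocks: Mapping[str, str],
    scheme: str,
    k: int = 10,
    reps: int = 5,
    seed: int = 0,
    block_mode: str = "average",
) -> FoldingPlan:
    """Build the cross-validation design for one scheme.

    ``block_mode`` applies to the block scheme only: ``"average"``
    trains k models per validation block (each omitting one training
    fold) whose predictions are averaged; ``"loo"`` trains one model on
    all remaining blocks.
    """
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if block_mode not in ("average", "loo"):
        raise ValueError(f"unknown block_mode {block_mode!r}")
    missing = [i for i in ids if i not in families or i not in blocks]
    if missing:
        raise ValueError(f"family/block labels missing for {missing[:5]}")
    splits_all: list[list[Split]] = []
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        rounds: list[Split] = []
        if scheme == "random":
            folds = _partition(rng, ids, k)
            for f, val in enumerate(folds):
                train = [i for i in ids if i not in set(val)]
                rounds.append(Split(tuple(train), tuple(val), f"fold{f}"))
        elif scheme == "family":
            fams = sorted({families[i] for i in ids})
            if k > len(fams):
                raise ValueError(
                    f"k={k} exceeds the {len(fams)} families available"
                )
            fam_folds = _partition(rng, fams, k)
            for f, fam_set in enumerate(fam_folds):
                fs = set(fam_set)
                val = [i for i in ids if families[i] in fs]
                train = [i for i in ids if families[i] not in fs]
                rounds.append(Split(tuple(train), tuple(val), f"fold{f}"))
        else:  # block
            blk = sorted({blocks[i] for i in ids})
            if len(blk) < 2:
                raise ValueError("block scheme needs at least 2 blocks")
            for b in blk:
                val = [i for i in ids if blocks[i] == b]
                rest = [i for i in ids if blocks[i] != b]
                if block_mode == "loo":
                    rounds.append(Split(tuple(rest), tuple(val), f"block{b}"))
                else:
                    train_folds = _partition(rng, rest, k)
                    for f, omit in enumerate(train_folds):
                        train = [i for i in rest if i not in set(omit)]
                        rounds.append(
                            Split(tuple(train), tuple(val), f"block{b}_fold{f}")
                        )
        splits_all.append(rounds)
    return FoldingPlan(scheme, k, reps, seed, block_mode, splits_all)


def cross_validate(
    plan: FoldingPlan,
    model: str,
    phenotypes: pd.DataFrame,
    trait: str,
    kernels: Mapping[str, RelationshipKernel],
    transform: str = "none",
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Predicted breeding values (PBV) for withheld individuals.

    For every replication and round, the model is refit on training
    phenotypes only and the additive BLUPs of the validation
    individuals are recorded.  Returns a long table
    ``(replication, id, pbv)`` with one PBV per individual per
    replication (block-scheme predictions averaged across rounds).
    """
    spec = model_spec(model, trait, transform)
    records: list[tuple[int, str, float]] = []
    for rep, rounds in enumerate(plan.splits):
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for split in rounds:
            train = phenotypes[phenotypes["id"].astype(str).isin(split.train_ids)]
            fit_ = fit(spec, train, kernels, options, model=model)
            ebv = fit_.ebv
            for i in split.validation_ids:
                if i in ebv.index:
                    sums[i] = sums.get(i, 0.0) + float(ebv.loc[i])
                    counts[i] = counts.get(i, 0) + 1
        for i, s in sums.items():
            records.append((rep, i, s / counts[i]))
    return pd.DataFrame(records, columns=["replication", "id", "pbv"])


def accuracy(ebv: pd.Series, pbv: pd.Series) -> float:
    """Pearson correlation between reference EBVs and PBVs.

    Returns NaN when either vector is (numerically) constant — e.g. the
    pedigree model under family folding, where every PBV collapses to
    the model mean.
    """
    joined = pd.concat([ebv.rename("ebv"), pbv.rename("pbv")], axis=1).dropna()
    if len(joined) < 2:
        return float("nan")
    e, p = joined["ebv"].to_numpy(float), joined["pbv"].to_numpy(float)
    scale = max(np.abs(e).max(), np.abs(p).max(), 1.0)
    if e.std() <= 1e-12 * scale or p.std() <= 1e-12 * scale:
        return float("nan")
    return float(np.corrcoef(e, p)[0, 1])


def sem(correlations: Sequence[float]) -> float:
    """Standard error of the mean correlation: sd / sqrt(n)."""
    arr = np.asarray(list(correlations), dtype=float)
    if arr.size < 2:
        raise ValueError("SEM needs at least 2 replications")
    return float(np.std(arr, ddof=1) / np.sqrt(arr.size))


def evaluate_accuracy(
    ebv: pd.Series,
    pbv_table: pd.DataFrame,
    ebv_model: str = "",
    pbv_model: str = "",
    scheme: str = "",
) -> CVResult:
    """Replication-wise correlations of a PBV table against reference EBVs."""
    corrs = []
    for rep, grp in pbv_table.groupby("replication"):
        corrs.append(accuracy(ebv, grp.set_index("id")["pbv"]))
    return CVResult(ebv_model, pbv_model, scheme, corrs)


def consistency_matrix(
    ebvs: Mapping[str, pd.Series],
    pbv_tables: Mapping[str, pd.DataFrame],
    scheme: str,
) -> pd.DataFrame:
    """Within-model accuracies (diagonal) and cross-model consistencies.

    Rows are PBV models, columns EBV models; each cell holds the mean
    replication correlation with its SEM (NaN cells mark degenerate or
    missing combinations).
    """
    models_pbv = list(pbv_tables)
    models_ebv = list(ebvs)
    mean = pd.DataFrame(index=models_pbv, columns=models_ebv, dtype=float)
    sem_ = pd.DataFrame(index=models_pbv, columns=models_ebv, dtype=float)
    for pm in models_pbv:
        for em in models_ebv:
            res = evaluate_accuracy(ebvs[em], pbv_tables[pm], em, pm, scheme)
            mean.loc[pm, em] = res.mean
            sem_.loc[pm, em] = res.sem
    out = pd.concat({"mean": mean, "sem": sem_}, axis=1)
    out.index.name = "pbv_model"
    return out
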