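"""Leaf-grouped cross-validation and density-dependent training-set balancing.

Measurements (and all their interpolated versions) from one leaf are never
split between training and test: each cross-validation round holds out every
sample of a single leaf ("leaf-one-out" CV), mimicking prediction on a
completely new leaf. Because hydration states near full turgor dominate the
data, the training pool of each round is additionally balanced by equalizing
the RWC histogram: equal-width bins over the observed RWC range are randomly
downsampled to the size of the smallest non-empty bin. Discarded samples form
a pseudo-validation pool (they are not independent of the kept samples, being
interpolated siblings or same-leaf measurements).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, IntegrityError

__all__ = ["SplitPlan", "BalancedTrainSet", "leafoo_splits", "balance_training_set",
           "write_split_manifest"]


@dataclass(frozen=True)
class SplitPlan:
    """One fold per leaf: (test leaf, tuple of training leaves)."""

    folds: tuple[tuple[str, tuple[str, ...]], ...]

    def __len__(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class BalancedTrainSet:
    """Result of RWC-equalizing downsampling of one training pool."""

    kept_sample_ids: tuple
    pseudo_validation_ids: tuple
    bin_edges: np.ndarray
    seed: int


def leafoo_splits(leaf_ids: Sequence[str]) -> SplitPlan:
    """Leaf-one-out split plan: n_leaves folds, each testing on one held-out leaf.

    Deterministic in the input order. Every augmented sample inherits its
    leaf's fold assignment, so all seven interpolated versions of a
    measurement travel together.
    """
    ids = list(leaf_ids)
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 leaves to cross-validate")
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate leaf ids in dataset")
    folds = tuple(
        (test, tuple(other for other in ids if other != test)) for test in ids
    )
    return SplitPlan(folds=folds)


def balance_training_set(
    samples: Sequence[tuple[object, float]],
    n_bins: int = 10,
    seed: int = 0,
) -> BalancedTrainSet:
    """Equalize the RWC histogram of a training pool by random downsampling.

    ``samples`` is a sequence of ``(sample_id, rwc)``. Equal-width bins are
    laid over ``[min(rwc), max(rwc)]``; every non-empty bin is subsampled
    without replacement to the count of the smallest non-empty bin. The kept
    set is a pure function of ``(samples, n_bins, seed)``; everything else
    lands in the pseudo-validation pool.
    """
    if not samples:
        raise ConfigurationError("empty training pool")
    if n_bins < 2:
        raise ConfigurationError("need at least 2 bins")
    if n_bins > len(samples):
        raise ConfigurationError(f"n_bins {n_bins} exceeds sample count {len(samples)}")
    ids = [s[0] for s in samples]
    rwc = np.array([s[1] for s in samples], dtype=float)
    edges = np.linspace(rwc.min(), rwc.max(), n_bins + 1)
    # right-inclusive last bin so the maximum is not its own bin
    bin_idx = np.clip(np.digitize(rwc, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    target = int(counts[counts > 0].min())

    rng = np.random.default_rng(seed)
    kept: list = []
    for b in range(n_bins):
        members = np.flatnonzero(bin_idx == b)
        if members.size == 0:
            continue
        chosen = rng.choice(members, size=target, replace=False)
        kept.extend(int(i) for i in chosen)
    kept_set = set(kept)
    kept_ids = tuple(ids[i] for i in sorted(kept_set))
    pseudo = tuple(ids[i] for i in range(len(ids)) if i not in kept_set)
    return BalancedTrainSet(
        kept_sample_ids=kept_ids,
        pseudo_validation_ids=pseudo,
        bin_edges=edges,
        seed=seed,
    )


def write_split_manifest(
    plan: SplitPlan,
    balanced: Sequence[BalancedTrainSet],
    path: str | Path,
) -> None:
    """JSON manifest of the folds and their balanced kept sets, for exact reruns."""
    payload = {
        "folds": [
            {
                "test_leaf": test,
                "train_leaves": list(train),
                "seed": bal.seed,
                "kept_sample_ids": [list(i) if isinstance(i, tuple) else i
                                    for i in bal.kept_sample_ids],
            }
            for (test, train), bal in zip(plan.folds, balanced)
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))
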