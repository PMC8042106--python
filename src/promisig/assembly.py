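"""Target-pair dataset assembly: qualification, balancing, and trial splits.

A target pair qualifies for diagnostic modelling when at least 50 single-target
compounds are available for each target and at least 100 dual-target compounds
for the combination.  Qualifying sets are then balanced relative to the
limiting class count so that dual-target (DT) and single-target (ST) compounds
each make up half of the final dataset, and split ten times into random 50/50
train/test halves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TargetPair",
    "PairDataset",
    "SplitTrial",
    "QualificationError",
    "SplitError",
    "MIN_ST_PER_TARGET",
    "MIN_DT",
    "qualify_pair",
    "balance_dataset",
    "make_trials",
    "write_splits",
    "read_splits",
]

#: Minimum single-target compounds per target for a pair to qualify.
MIN_ST_PER_TARGET = 50
#: Minimum dual-target compounds for a pair to qualify.
MIN_DT = 100

CLASSES = ("ST_A", "ST_B", "DT")


class QualificationError(ValueError):
    """Input counts do not meet the qualification thresholds."""


class SplitError(ValueError):
    """A class is too small to be split between train and test."""


@dataclass(frozen=True)
class TargetPair:
    """An unordered combination of two distinct protein targets."""

    target_a: "Target"
    target_b: "Target"
    pair_id: str

    def __post_init__(self) -> None:
        if self.target_a.target_id == self.target_b.target_id:
            raise ValueError("a target pair needs two distinct targets")

    @property
    def families(self) -> frozenset[str]:
        return frozenset({self.target_a.family, self.target_b.family})


@dataclass
class PairDataset:
    """Balanced ST-A / ST-B / DT compound sets for one target pair."""

    pair: TargetPair
    st_a: list
    st_b: list
    dt: list
    balanced: bool = False

    @property
    def compounds(self) -> list:
        return list(self.st_a) + list(self.st_b) + list(self.dt)

    @property
    def n(self) -> int:
        return len(self.st_a) + len(self.st_b) + len(self.dt)

    def by_class(self) -> dict[str, list]:
        return {"ST_A": list(self.st_a), "ST_B": list(self.st_b), "DT": list(self.dt)}

    def check_balanced(self) -> None:
        if len(self.st_a) != len(self.st_b):
            raise ValueError("balanced dataset needs |ST_A| == |ST_B|")
        if len(self.st_a) + len(self.st_b) != len(self.dt):
            raise ValueError("balanced dataset needs |ST| == |DT|")


@dataclass(frozen=True)
class SplitTrial:
    """One random 50/50 train/test partition of a pair dataset."""

    trial_index: int
    seed: int
    train: frozenset[str]
    test: frozenset[str]

    def __post_init__(self) -> None:
        if self.train & self.test:
            raise SplitError("train and test sets overlap")


def qualify_pair(st_a_count: int, st_b_count: int, dt_count: int) -> bool:
    """True iff the class counts meet the qualification thresholds."""
    if min(st_a_count, st_b_count, dt_count) < 0:
        raise ValueError("counts must be non-negative")
    return (
        st_a_count >= MIN_ST_PER_TARGET
        and st_b_count >= MIN_ST_PER_TARGET
        and dt_count >= MIN_DT
    )


def _sample(rng: np.random.Generator, items: Sequence, k: int) -> list:
    if k == len(items):
        return list(items)
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def balance_dataset(
    pair: TargetPair,
    st_a: Sequence,
    st_b: Sequence,
    dt: Sequence,
    seed: int = 0,
) -> PairDataset:
    """Balance a qualifying pair's classes relative to the limiting count.

    With ``k = min(floor(|DT| / 2), |ST_A|, |ST_B|)`` the balanced dataset
    holds ``k`` compounds sampled from each single-target class and ``2k``
    dual-target compounds, so e.g. raw counts (150, 200, 110) yield a
    220-compound set composed 55 + 55 + 110.  Sampling is uniform without
    replacement; classes already at their target size are passed through
    unchanged.
    """
    if not qualify_pair(len(st_a), len(st_b), len(dt)):
        raise QualificationError(
            f"pair {pair.pair_id}: counts ({len(st_a)}, {len(st_b)}, {len(dt)}) "
            f"do not qualify (need >= {MIN_ST_PER_TARGET}/{MIN_ST_PER_TARGET}/{MIN_DT})"
        )
    k = min(len(dt) // 2, len(st_a), len(st_b))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ds = PairDataset(
        pair=pair,
        st_a=_sample(rng, st_a, k),
        st_b=_sample(rng, st_b, k),
        dt=_sample(rng, dt, 2 * k),
        balanced=True,
    )
    ds.check_balanced()
    return ds


def make_trials(
    dataset: PairDataset, n_trials: int = 10, master_seed: int = 0
) -> list[SplitTrial]:
    """Draw random 50/50 train/test splits, stratified by compound class.

    Each class (ST-A, ST-B, DT) is divided evenly between the halves; with an
    odd class count the extra compound goes to training.  Trial ``t`` uses a
    child seed spawned from ``master_seed``, so adding trials never changes
    earlier ones.
    """
    if not dataset.balanced:
        raise SplitError("make_trials expects a balanced dataset")
    dataset.check_balanced()
    by_class = dataset.by_class()
    for klass, members in by_class.items():
        if len(members) < 2:
            raise SplitError(f"class {klass} has fewer than 2 compounds")

    trials = []
    for t in range(n_trials):
        ss = np.random.SeedSequence(master_seed, spawn_key=(t,))
        seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(ss)
        train: set[str] = set()
        test: set[str] = set()
        for members in by_class.values():
            ids = [c.compound_id for c in members]
            order = rng.permutation(len(ids))
            n_train = math.ceil(len(ids) / 2)
            for j, pos in enumerate(order):
                (train if j < n_train else test).add(ids[pos])
        trials.append(
            SplitTrial(
                trial_index=t, seed=seed, train=frozenset(train), test=frozenset(test)
            )
        )
    return trials


def write_splits(path: str | Path, pair_id: str, trials: Iterable[SplitTrial]) -> None:
    """Write trial memberships as JSON (pair id, trial index, train/test ids)."""
    payload = [
        {
            "pair_id": pair_id,
            "trial_index": t.trial_index,
            "seed": t.seed,
            "train": sorted(t.train),
            "test": sorted(t.test),
        }
        for t in trials
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_splits(path: str | Path) -> list[SplitTrial]:
    payload = json.loads(Path(path).read_text())
    return [
        SplitTrial(
            trial_index=rec["trial_index"],
            seed=rec["seed"],
            train=frozenset(rec["train"]),
            test=frozenset(rec["test"]),
        )
        for rec in payload
    ]
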