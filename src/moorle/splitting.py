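"""Cross-validation split plans for pair-input data.

Two modes mirror the two application scenarios:

* ``random_pair`` — folds partition (sample, drug) pairs at random; a test
  pair's drug may appear in training with other cell lines. Models drug
  repurposing.
* ``drug_blind`` — folds partition *drugs*; every record inherits its
  drug's fold, so no drug ever spans train and test. Models virtual
  screening on novel compounds, where random-pair splits would leak drug
  identity and inflate scores.

Drug-blind folds are balanced on total pair counts by greedy largest-first
assignment (heaviest remaining drug into the currently lightest fold),
because long-tailed count profiles make drug-count balancing produce wildly
uneven test sizes. Plans serialize to two-column TSV so a fixed split can
be shared across experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DrugResponseTable


@dataclass
class SplitPlan:
    mode: str  # random_pair | drug_blind
    k: int
    fold_of_record: dict[int, int]
    fold_of_drug: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.fold_of_record.values():
            sizes[f] += 1
        return sizes

    def test_indices(self, fold: int) -> np.ndarray:
        return np.array(
            sorted(i for i, f in self.fold_of_record.items() if f == fold), dtype=int
        )

    def train_indices(self, fold: int) -> np.ndarray:
        return np.array(
            sorted(i for i, f in self.fold_of_record.items() if f != fold), dtype=int
        )


def random_pair_folds(table: DrugResponseTable, k: int, seed: int) -> SplitPlan:
    """Partition records into k near-equal folds by a seeded permutation."""
    n = len(table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of records ({n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of_record: dict[int, int] = {}
    for fold, chunk in enumerate(np.array_split(perm, k)):
        for idx in chunk:
            fold_of_record[int(idx)] = fold
    return SplitPlan(
        mode="random_pair", k=k, fold_of_record=fold_of_record, seed=seed
    )


def drug_blind_folds(table: DrugResponseTable, k: int, seed: int) -> SplitPlan:
    """Partition drugs into k folds balancing pair counts; records follow drugs.

    Greedy: drugs sorted by descending count (ties broken by a seeded
    shuffle), each assigned to the fold with the fewest pairs so far.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = table.drug_counts()
    if len(counts) < k:
        raise ValueError(f"drug_blind needs >= {k} drugs, found {len(counts)}")
    rng = np.random.default_rng(seed)
    drugs = list(counts)
    rng.shuffle(drugs)
    drugs.sort(key=lambda d: -counts[d])  # stable: shuffled order breaks ties
    load = [0] * k
    fold_of_drug: dict[str, int] = {}
    for d in drugs:
        fold = int(np.argmin(load))
        fold_of_drug[d] = fold
        load[fold] += counts[d]
    fold_of_record = {
        i: fold_of_drug[rec.drug_id] for i, rec in enumerate(table.records)
    }
    plan = SplitPlan(
        mode="drug_blind",
        k=k,
        fold_of_record=fold_of_record,
        fold_of_drug=fold_of_drug,
        seed=seed,
    )
    if 0 in plan.fold_sizes():
        raise ValueError("a fold received no records; reduce k")
    return plan


def validation_holdout(
    plan: SplitPlan,
    fold: int,
    fraction: float,
    seed: int,
    table: DrugResponseTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Carve a validation set out of the training portion of one fold rotation.

    In drug_blind mode the holdout is a set of whole drugs (requires
    ``table``), keeping validation as blind as the test set; in random_pair
    mode it is a record subset.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    train_idx = plan.train_indices(fold)
    rng = np.random.default_rng(seed)
    if plan.mode == "drug_blind":
        if table is None:
            raise ValueError("drug_blind holdout requires the response table")
        train_drugs = sorted(
            {d for d, f in plan.fold_of_drug.items() if f != fold}
        )
        n_val = max(1, round(fraction * len(train_drugs)))
        if n_val >= len(train_drugs):
            raise ValueError("fraction leaves no training drugs")
        val_drugs = set(rng.permutation(train_drugs)[:n_val].tolist())
        drug_of = {i: table.records[i].drug_id for i in train_idx}
        val = np.array([i for i in train_idx if drug_of[i] in val_drugs], dtype=int)
        train = np.array(
            [i for i in train_idx if drug_of[i] not in val_drugs], dtype=int
        )
    else:
        n_val = max(1, round(fraction * len(train_idx)))
        if n_val >= len(train_idx):
            raise ValueError("fraction leaves no training records")
        perm = rng.permutation(train_idx)
        val = np.sort(perm[:n_val])
        train = np.sort(perm[n_val:])
    if len(train) == 0 or len(val) == 0:
        raise ValueError("holdout produced an empty train or validation set")
    return train, val


def validate_plan(plan: SplitPlan, table: DrugResponseTable) -> list[str]:
    """Leakage/partition audit. Returns a list of violations (empty = valid)."""
    violations: list[str] = []
    n = len(table)
    assigned = set(plan.fold_of_record)
    if assigned != set(range(n)):
        missing = sorted(set(range(n)) - assigned)
        extra = sorted(assigned - set(range(n)))
        if missing:
            violations.append(f"records without fold assignment: {missing[:10]}")
        if extra:
            violations.append(f"fold assignments for unknown records: {extra[:10]}")
    for fold, size in enumerate(plan.fold_sizes()):
        if size == 0:
            violations.append(f"fold {fold} is empty")
    bad_folds = {f for f in plan.fold_of_record.values() if not 0 <= f < plan.k}
    if bad_folds:
        violations.append(f"fold ids out of range: {sorted(bad_folds)}")
    if plan.mode == "drug_blind":
        folds_of: dict[str, set[int]] = {}
        for i, rec in enumerate(table.records):
            if i in plan.fold_of_record:
                folds_of.setdefault(rec.drug_id, set()).add(plan.fold_of_record[i])
        for drug, folds in sorted(folds_of.items()):
            if len(folds) > 1:
                violations.append(
                    f"drug {drug!r} spans folds {sorted(folds)} (leakage)"
                )
            if drug in plan.fold_of_drug and folds != {plan.fold_of_drug[drug]}:
                violations.append(
                    f"drug {drug!r} records disagree with fold_of_drug"
                )
    return violations


def write_plan(plan: SplitPlan, path: str | Path) -> None:
    """Serialize a plan to TSV (record index -> fold; plus drug -> fold)."""
    rows = [("record", str(i), f) for i, f in sorted(plan.fold_of_record.items())]
    rows += [("drug", d, f) for d, f in sorted(plan.fold_of_drug.items())]
    df = pd.DataFrame(rows, columns=["scope", "key", "fold"])
    with open(path, "w") as fh:
        fh.write(f"# mode={plan.mode}\tk={plan.k}\tseed={plan.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_plan(path: str | Path) -> SplitPlan:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=") for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"key": str})
    records = df[df["scope"] == "record"]
    drugs = df[df["scope"] == "drug"]
    return SplitPlan(
        mode=meta["mode"],
        k=int(meta["k"]),
        fold_of_record={int(r.key): int(r.fold) for r in records.itertuples()},
        fold_of_drug={str(r.key): int(r.fold) for r in drugs.itertuples()},
        seed=int(meta["seed"]),
    )
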