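"""Dataset partitioning.

The evaluation protocol carves out an *independent ligand validation* set
first: roughly 10% of pairs, built from whole ligand groups so that none of
its ligands appears, on any receptor, in the remaining data. The remainder is
then randomly divided 80/10/10 into training, internal-validation and testing
sets, stratified by functional class. All sizes follow a single rounding
rule — round-half-up of fraction x n — which reproduces the reference
protocol's printed sizes (692/4,981/623/623 and 427/3,077/385/385).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from maap.io import InteractionTable


def holdout_size(n: int, fraction: float) -> int:
    """Round-half-up of fraction x n, clamped to [1, n-1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    size = int(math.floor(fraction * n + 0.5))
    return max(1, min(n - 1, size))


@dataclass
class DatasetSplits:
    """Index partition with ligand-disjointness metadata."""

    train: list[int]
    internal_val: list[int]
    test: list[int]
    independent: list[int]
    seed: int
    fractions: tuple[float, float, float, float] = (0.10, 0.80, 0.10, 0.10)
    independent_target_size: int | None = None
    ligand_disjoint: bool = True

    def all_indices(self) -> list[int]:
        return sorted(self.train + self.internal_val + self.test + self.independent)

    def validate(self, table: InteractionTable) -> None:
        n = len(table)
        if self.all_indices() != list(range(n)):
            raise ValueError("splits do not partition the row indices")
        ligands = table.ligand_ids()
        indep = {ligands[i] for i in self.independent}
        rest = {ligands[i] for i in self.train + self.internal_val + self.test}
        overlap = indep & rest
        if overlap:
            raise ValueError(
                f"ligand-disjointness violated: {sorted(overlap)[:5]} appear "
                "in both the independent set and another split"
            )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplits":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["fractions"] = tuple(d["fractions"])
        return cls(**d)


def ligand_disjoint_split(table: InteractionTable, fraction: float = 0.10,
                          seed: int = 0) -> tuple[list[int], list[int]]:
    """Hold out whole ligand groups totalling ~fraction of all pairs.

    Ligands are visited in a seeded random order; a ligand's whole pair group
    is added while the holdout stays at or below the target count
    ``holdout_size(n, fraction)``. A final swap pass exchanges one held-out
    ligand for one remaining ligand if that brings the achieved count closer
    to the target. Returns (independent indices, remainder indices) in row
    order.
    """
    n = len(table)
    ligands = table.ligand_ids()
    groups: dict[str, list[int]] = {}
    for i, lig in enumerate(ligands):
        groups.setdefault(lig, []).append(i)
    if len(groups) < 2:
        raise ValueError("need at least 2 distinct ligands for a disjoint split")

    target = holdout_size(n, fraction)
    rng = np.random.default_rng(seed)
    order = list(groups)
    rng.shuffle(order)

    held: list[str] = []
    total = 0
    for lig in order:
        size = len(groups[lig])
        if total + size <= target:
            held.append(lig)
            total += size
    if total == 0:  # every group overshoots: take the single closest group
        best = min(order, key=lambda l: (abs(len(groups[l]) - target), order.index(l)))
        held, total = [best], len(groups[best])

    # one swap pass: exchange a held ligand for an excluded one if it tightens
    held_set = set(held)
    excluded = [l for l in order if l not in held_set]
    best_gap = abs(total - target)
    best_swap = None
    for h in held:
        for e in excluded:
            cand = total - len(groups[h]) + len(groups[e])
            if 0 < cand < n and abs(cand - target) < best_gap:
                best_gap = abs(cand - target)
                best_swap = (h, e)
    if best_swap is not None:
        h, e = best_swap
        held_set.discard(h)
        held_set.add(e)
        total = total - len(groups[h]) + len(groups[e])

    if total >= n:
        raise ValueError(
            f"fraction {fraction} leaves no remainder ({total} of {n} pairs held out)"
        )
    independent = sorted(i for lig in held_set for i in groups[lig])
    remainder = [i for i in range(n) if i not in set(independent)]
    return independent, remainder


def _stratified_allocation(class_counts: dict[int, int], size: int) -> dict[int, int]:
    """Largest-remainder allocation of *size* slots proportional to class counts."""
    total = sum(class_counts.values())
    quotas = {c: size * cnt / total for c, cnt in class_counts.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = size - sum(alloc.values())
    remainders = sorted(quotas, key=lambda c: (quotas[c] - alloc[c], class_counts[c]),
                        reverse=True)
    for c in remainders[:short]:
        alloc[c] += 1
    return alloc


def random_split(indices: list[int], labels: np.ndarray,
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> tuple[list[int], list[int], list[int]]:
    """Split the remainder into (train, internal_val, test), stratified by class.

    Test and internal-validation sizes are each ``holdout_size(n, f)`` of the
    remainder; training takes what is left. Per-class allocations use the
    largest-remainder rule, keeping class proportions within one record of the
    global proportions in every split.
    """
    if not indices:
        raise ValueError("empty remainder")
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(indices)
    n_test = holdout_size(n, f_test)
    n_val = holdout_size(n, f_val)

    labels = np.asarray(labels)
    by_class: dict[int, list[int]] = {}
    for i in indices:
        by_class.setdefault(int(labels[i]), []).append(i)
    class_counts = {c: len(v) for c, v in by_class.items()}
    if min(class_counts.values()) < 3:
        raise ValueError(
            f"every class needs >= 3 records to appear in all splits; got {class_counts}"
        )

    test_alloc = _stratified_allocation(class_counts, n_test)
    val_alloc = _stratified_allocation(class_counts, n_val)

    rng = np.random.default_rng(seed)
    test, val, train = [], [], []
    for c in sorted(by_class):
        pool = np.array(by_class[c])
        rng.shuffle(pool)
        t, v = test_alloc[c], val_alloc[c]
        test.extend(pool[:t].tolist())
        val.extend(pool[t:t + v].tolist())
        train.extend(pool[t + v:].tolist())
    return sorted(train), sorted(val), sorted(test)


def make_splits(table: InteractionTable, seed: int = 0,
                independent_fraction: float = 0.10,
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> DatasetSplits:
    """Full protocol: ligand-disjoint holdout, then stratified 80/10/10."""
    independent, remainder = ligand_disjoint_split(table, independent_fraction, seed)
    labels = table.labels()
    train, val, test = random_split(remainder, labels, fractions, seed)
    splits = DatasetSplits(
        train=train, internal_val=val, test=test, independent=independent,
        seed=seed,
        fractions=(independent_fraction, *fractions),
        independent_target_size=holdout_size(len(table), independent_fraction),
    )
    splits.validate(table)
    return splits
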