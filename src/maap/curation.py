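"""Dataset cleaning: Ki replicate deduplication, label-conflict resolution,
and zero-variance descriptor filtering.

Replicated Ki measurements for one ligand-receptor complex are collapsed to a
single representative value by z-scoring the replicates against their own mean
and standard deviation, discarding values whose |z| exceeds a threshold
(default 1), and retaining the survivor whose z-score is closest to zero,
i.e. closest to the mean. Descriptor columns that are constant across the
curated dataset carry no discriminative signal and are removed before
splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from maap.io import FeatureMatrix, InteractionRecord, InteractionTable, canonicalize_table

logger = logging.getLogger(__name__)

CONFLICT_POLICIES = ("error", "majority", "priority_file")


class LabelConflictError(ValueError):
    """Rows for one (ligand, receptor) key disagree on the functional class."""


@dataclass
class KiGroup:
    """Replicate Ki measurements for one complex with their z-scores."""

    key: tuple[str, str]
    ki_values_nM: list[float]
    mean: float
    std: float
    zscores: list[float]

    @classmethod
    def from_values(cls, key: tuple[str, str], values: list[float],
                    ddof: int = 0) -> "KiGroup":
        arr = np.asarray(values, dtype=float)
        mu = float(arr.mean())
        sigma = float(arr.std(ddof=ddof)) if len(arr) > ddof else 0.0
        if sigma > 0:
            z = ((arr - mu) / sigma).tolist()
        else:
            z = [0.0] * len(arr)
        return cls(key=key, ki_values_nM=list(values), mean=mu, std=sigma, zscores=z)


@dataclass
class CurationReport:
    n_in: int = 0
    n_out: int = 0
    n_ki_outliers_removed: int = 0
    n_label_conflicts: int = 0
    n_smiles_dropped: int = 0
    n_dropped_no_ki: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def dedup_ki(values: list[float], threshold: float = 1.0, ddof: int = 0,
             _report: CurationReport | None = None) -> float:
    """Collapse replicate Ki measurements (nM) to one representative value.

    The mean and standard deviation (population by default, ``ddof=1`` for the
    sample convention) are computed once over the input. Values with
    |z| strictly greater than *threshold* are discarded; among the survivors
    the value with minimal |z| is returned. Ties on |z| break toward the
    smaller Ki, then first occurrence. Degenerate cases: a single value or a
    zero-spread group returns the common value; if every value is flagged, the
    one with minimal |z| among the originals is returned.
    """
    if not values:
        raise ValueError("dedup_ki requires a non-empty list of Ki values")
    for v in values:
        if not (v > 0):
            raise ValueError(f"Ki values must be positive, got {v!r}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    group = KiGroup.from_values(("", ""), values, ddof=ddof)
    if group.std == 0.0:
        return float(values[0])

    z = np.asarray(group.zscores)
    # strict |z| > threshold removes; the epsilon absorbs float rounding so a
    # two-replicate group (z exactly +/-1) is never flagged at threshold 1
    survivors = np.flatnonzero(np.abs(z) <= threshold + 1e-9)
    if survivors.size == 0:
        survivors = np.arange(len(values))
    elif _report is not None:
        _report.n_ki_outliers_removed += len(values) - survivors.size

    vals = np.asarray(values, dtype=float)
    # minimal |z| wins; |z| values within 1e-9 count as tied (so the exact
    # +/-1 two-replicate case stays a tie under float rounding), ties break
    # toward the smaller Ki, then first occurrence
    za = np.abs(z[survivors])
    tied = survivors[za <= za.min() + 1e-9]
    best = min(tied, key=lambda i: (vals[i], i))
    return float(vals[best])


def _resolve_label(labels: list[int], key: tuple[str, str], policy: str,
                   priorities: dict[tuple[str, str], int] | None) -> tuple[int, bool]:
    """Return (label, had_conflict). Majority ties keep the earliest row's label."""
    distinct = set(labels)
    if len(distinct) == 1:
        return labels[0], False
    if policy == "error":
        raise LabelConflictError(
            f"conflicting action classes {sorted(distinct)} for key {key}"
        )
    if policy == "priority_file":
        if priorities is None or key not in priorities:
            raise LabelConflictError(
                f"priority_file policy needs an entry for conflicted key {key}"
            )
        return priorities[key], True
    if policy == "majority":
        counts: dict[int, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        if len(winners) == 1:
            return winners[0], True
        for lab in labels:  # tie: earliest observed row wins (stable)
            if lab in winners:
                return lab, True
    raise ValueError(f"unknown conflict_policy {policy!r}; allowed: {CONFLICT_POLICIES}")


def curate(table: InteractionTable, ki_filter: bool = False,
           conflict_policy: str = "error",
           priorities: dict[tuple[str, str], int] | None = None,
           ki_threshold: float = 1.0, ki_ddof: int = 0,
           canonicalize: bool = True) -> tuple[InteractionTable, CurationReport]:
    """Collapse an ingest table to one record per (ligand, receptor).

    Rows sharing a key are merged: their Ki measurements pool into one
    replicate group and label disagreements are resolved per *conflict_policy*
    ('error' | 'majority' | 'priority_file'). With *ki_filter*, records without
    any Ki measurement are dropped and each survivor carries exactly one
    deduplicated Ki. SMILES are canonicalized first; unparseable ones are
    dropped and counted.
    """
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(f"unknown conflict_policy {conflict_policy!r}; allowed: {CONFLICT_POLICIES}")

    report = CurationReport(n_in=len(table))
    if canonicalize:
        table, dropped = canonicalize_table(table)
        report.n_smiles_dropped = len(dropped)

    grouped: dict[tuple[str, str], list[InteractionRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in table.records:
        key = (r.ligand_id, r.receptor_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(r)

    out: list[InteractionRecord] = []
    for key in order:
        rows = grouped[key]
        label, conflicted = _resolve_label(
            [r.action_class for r in rows], key, conflict_policy, priorities
        )
        if conflicted:
            report.n_label_conflicts += 1
        ki_pool = [v for r in rows for v in r.ki_values_nM]
        if ki_filter:
            if not ki_pool:
                report.n_dropped_no_ki += 1
                continue
            ki_values = [dedup_ki(ki_pool, threshold=ki_threshold, ddof=ki_ddof,
                                  _report=report)]
        else:
            ki_values = ki_pool
        first = rows[0]
        out.append(
            InteractionRecord(first.ligand_id, first.smiles, first.receptor_id,
                              label, first.action_raw, ki_values, first.source)
        )
    report.n_out = len(out)
    return InteractionTable(out), report


def filter_zero_variance(m: FeatureMatrix, scope: str = "descriptor",
                         tol: float = 0.0) -> FeatureMatrix:
    """Drop columns of the given role whose variance over all rows is <= *tol*.

    Other roles are untouched and survivor order is preserved. Removing every
    column of the scoped role is treated as a degenerate design and raises.
    """
    if m.shape[0] == 0:
        raise ValueError("cannot assess variance on an empty matrix")
    scoped = m.columns_with_role(scope)
    if not scoped:
        return m
    variances = m.values[:, scoped].var(axis=0)
    drop = {scoped[i] for i in range(len(scoped)) if variances[i] <= tol}
    if len(drop) == len(scoped):
        raise ValueError(
            f"all {len(scoped)} columns of role {scope!r} have zero variance"
        )
    keep = [i for i in range(m.shape[1]) if i not in drop]
    if drop:
        logger.info("zero-variance filter: removed %d of %d %s columns",
                    len(drop), len(scoped), scope)
    return m.select_columns(keep)
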