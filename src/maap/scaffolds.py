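"""Scaffold-diversity auditing.

Chemical-series diversity of a ligand set is summarized over Bemis-Murcko
scaffolds (ring systems plus linkers, side chains removed). For scaffold
relative frequencies p_i over M unique scaffolds, Shannon entropy
H = -sum_i p_i log2 p_i quantifies spread, and H / log2 M normalizes it to
[0, 1], with 1 meaning a perfectly even scaffold distribution. Novelty of a
query set against a reference is the fraction of its unique scaffolds absent
from the reference; the overlap score between two sets is the Pearson
correlation of their frequency vectors over the scaffold union.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from maap.io import SmilesError


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES; acyclic molecules map to the empty string."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem.Scaffolds import MurckoScaffold

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(core) if core.GetNumAtoms() else ""


@dataclass
class ScaffoldProfile:
    """Scaffold counts with their entropy summary."""

    scaffold_counts: dict[str, int]

    @property
    def M(self) -> int:
        return len(self.scaffold_counts)

    @property
    def total(self) -> int:
        return sum(self.scaffold_counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        return {s: c / t for s, c in self.scaffold_counts.items()}

    @property
    def entropy_bits(self) -> float:
        H = -sum(p * math.log2(p) for p in self.frequencies.values() if p > 0)
        return max(0.0, H)  # guard -0.0

    @property
    def normalized_entropy(self) -> float:
        if self.M <= 1:
            return 0.0
        return self.entropy_bits / math.log2(self.M)

    @property
    def unique_total_ratio(self) -> float:
        return self.M / self.total

    def as_dict(self) -> dict:
        return {
            "n_unique_scaffolds": self.M,
            "n_total": self.total,
            "entropy_bits": self.entropy_bits,
            "normalized_entropy": self.normalized_entropy,
            "unique_total_ratio": self.unique_total_ratio,
        }


def profile_from_counts(counts: Mapping[str, int]) -> ScaffoldProfile:
    if not counts or any(c <= 0 for c in counts.values()):
        raise ValueError("scaffold counts must be positive and non-empty")
    return ScaffoldProfile(dict(counts))


def scaffold_profile(smiles_list: Sequence[str]) -> ScaffoldProfile:
    """Profile a list of (canonical) SMILES; unparseable entries are skipped,
    and the profile errors only if nothing parses."""
    counts: Counter[str] = Counter()
    for smi in smiles_list:
        try:
            counts[murcko_scaffold(smi)] += 1
        except SmilesError:
            continue
    if not counts:
        raise ValueError("no parseable SMILES to profile")
    return ScaffoldProfile(dict(counts))


def scaffold_novelty(query: ScaffoldProfile, reference: ScaffoldProfile) -> float:
    """Fraction of the query's unique scaffolds absent from the reference."""
    q = set(query.scaffold_counts)
    r = set(reference.scaffold_counts)
    if not q or not r:
        raise ValueError("both profiles must be non-empty")
    return len(q - r) / len(q)


def scaffold_overlap_score(a: ScaffoldProfile, b: ScaffoldProfile) -> float:
    """Pearson correlation of relative-frequency vectors over the scaffold union.

    A scaffold absent from one profile contributes frequency 0 there. Returns
    NaN when either vector is constant over the union (correlation undefined).
    """
    union = sorted(set(a.scaffold_counts) | set(b.scaffold_counts))
    fa, fb = a.frequencies, b.frequencies
    va = np.array([fa.get(s, 0.0) for s in union])
    vb = np.array([fb.get(s, 0.0) for s in union])
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
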