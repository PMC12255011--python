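"""Synthetic fixture datasets with the statistical structure the pipeline assumes.

The generator emulates a multi-source receptor-ligand interaction table:
replicate Ki measurements with occasional gross outliers, occasional
conflicting class annotations, a descriptor block containing exactly-constant
columns, receptor-specific embedding vectors, class imbalance, and a planted
class signal that depends *jointly* on ligand and receptor features (the same
ligand can carry different labels on different receptors).

Label model. Each ligand gets an archetype encoded as a signed mean-shift
pattern on a few "informative" descriptor dimensions (plus Gaussian noise);
each receptor gets a Gaussian embedding centroid. The bilinear interaction
``d_sel^T W_c e_sel`` between each archetype's (noise-free) pattern and the
selected embedding dimensions scores every (receptor, archetype) cell per
class. A global archetype -> class base map honours largest-remainder quotas
on the class mix, and each receptor swaps the classes of the one archetype
pair its bilinear scores favour most — so every receptor keeps the same class
composition (its label marginal approximates the global mix and receptor
identity alone carries almost no class information) while the label genuinely
depends on the ligand-receptor combination. The observed label is one
categorical draw from ``softmax(log(class_mix) + signal_strength x
onehot(assigned class))``: signal 0 reduces to the bare class mix, large
signal is near-deterministic.

Ki model. Replicates are lognormal around a class-dependent log10 mean
(antagonists bind tightest here), so the deduplicated Ki is genuinely
informative for the Ki-filtered pipeline variant. Clean replicate sets have
exactly two measurements: with the population z-score and a strict |z| > 1
rule, any near-even set of three or more values necessarily flags an extreme
(the z-scores must satisfy sum z^2 = n), while a duplicate pair sits exactly
at z = +/-1 and is never flagged. Outlier-bearing sets therefore have 3-4
replicates, one multiplied by 10, which is always the single flagged value —
making the curation report's outlier count an exact bookkeeping oracle.

SMILES are assembled from a bank of parseable templates grouped into scaffold
families so the scaffold code paths run; the chemistry is decorative and
carries no signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from maap.io import InteractionRecord, InteractionTable

# Ring cores (scaffold families) and acyclic chains for the SMILES bank.
_CORES = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C1CCNCC1", "C1CCCCC1",
    "c1ccc2[nH]ccc2c1", "c1ccoc1", "c1ccsc1", "C1CCOC1", "c1cnc2ccccc2n1",
    "C1CCNC1", "c1ccc(-c2ccccc2)cc1",
]
_HEADS = ["", "O", "N", "OC", "NC", "FC", "ClC", "OCC"]
_ACYCLIC_TAILS = ["CO", "CN", "CCO", "C(=O)O", "CC(=O)N", "CCN"]

# Class-dependent log10 Ki means (nM): antagonist < agonist < modulator here.
_KI_LOG10_MEAN = {0: 1.2, 1: 2.2, 2: 3.2}


def smiles_bank(n: int) -> list[str]:
    """Deterministic bank of >= n distinct parseable SMILES across scaffold
    families, including an acyclic (empty-scaffold) family."""
    bank: list[str] = []
    seen = set()
    for length in range(0, 10):
        chain = "C" * length
        for head in _HEADS:
            for core in _CORES:
                smi = head + chain + core
                if smi not in seen:
                    seen.add(smi)
                    bank.append(smi)
            for tail in _ACYCLIC_TAILS:
                smi = head + chain + tail
                if len(smi) > 1 and smi not in seen:
                    seen.add(smi)
                    bank.append(smi)
            if len(bank) >= n:
                return bank[:n]
    if len(bank) < n:
        raise ValueError(f"SMILES bank exhausted at {len(bank)} < {n}")
    return bank[:n]


@dataclass
class SynthConfig:
    """Generator settings; defaults are the study conditions for fixtures."""

    n_receptors: int = 21
    n_ligands: int = 400
    n_pairs: int = 1200
    class_mix: tuple[float, float, float] = (0.53, 0.27, 0.20)
    n_descriptors: int = 60
    n_constant_descriptors: int = 8
    n_embedding_dims: int = 64
    signal_strength: float = 40.0
    ki_noise_sd: float = 0.1
    dup_rate: float = 0.3
    outlier_rate: float = 0.2
    conflict_rate: float = 0.02
    ki_missing_rate: float = 0.35
    n_archetypes: int = 4
    n_informative_descriptors: int = 6
    n_informative_embedding_dims: int = 8
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for name in ("dup_rate", "outlier_rate", "conflict_rate", "ki_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if self.n_pairs > self.n_ligands * self.n_receptors:
            raise ValueError(
                f"n_pairs={self.n_pairs} exceeds n_ligands x n_receptors "
                f"= {self.n_ligands * self.n_receptors}"
            )
        if self.n_constant_descriptors >= self.n_descriptors:
            raise ValueError("need at least one non-constant descriptor")


def paper_shape_preset() -> SynthConfig:
    """Scaled-down preset mirroring the reference dataset's shape: 21 receptors,
    400 ligands, 1,200 pairs, class mix 3677/1870/1372 of 6919, a descriptor
    block with planted constant columns, and 64 embedding dimensions."""
    total = 3677 + 1870 + 1372
    return SynthConfig(
        n_receptors=21, n_ligands=400, n_pairs=1200,
        class_mix=(3677 / total, 1870 / total, 1372 / total),
        n_descriptors=60, n_constant_descriptors=8, n_embedding_dims=64,
    )


def generate(config: SynthConfig
             ) -> tuple[InteractionTable, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (interaction table, descriptor table, embedding table, truth).

    Same seed, same config: byte-identical outputs. The truth record stores
    every planted quantity a test might audit: archetypes, informative
    dimensions, constant columns, per-pair planted labels and label
    probabilities, outlier and conflict bookkeeping.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    receptor_ids = [f"R{i:02d}" for i in range(config.n_receptors)]
    ligand_ids = [f"L{i:04d}" for i in range(config.n_ligands)]
    smiles = smiles_bank(config.n_ligands)

    # Receptor embeddings: distinct Gaussian centroids.
    centroids = rng.normal(size=(config.n_receptors, config.n_embedding_dims))
    embeddings = pd.DataFrame(
        centroids, index=receptor_ids,
        columns=[f"E{i:04d}" for i in range(config.n_embedding_dims)])
    embeddings.index.name = "receptor_id"

    # Ligand descriptors: archetype mean-shift pattern on the informative
    # dims, Gaussian noise elsewhere, exactly n_constant_descriptors constant.
    k_d = config.n_informative_descriptors
    k_e = config.n_informative_embedding_dims
    n_var = config.n_descriptors - config.n_constant_descriptors
    if k_d > n_var:
        raise ValueError("more informative descriptors than variable columns")
    archetypes = rng.integers(config.n_archetypes, size=config.n_ligands)
    patterns = rng.choice([-1.0, 1.0], size=(config.n_archetypes, k_d))
    desc = rng.normal(size=(config.n_ligands, n_var))
    desc[:, :k_d] += 2.0 * patterns[archetypes]
    const_block = np.ones((config.n_ligands, config.n_constant_descriptors))
    desc_all = np.hstack([desc, const_block])
    desc_names = [f"D{i:03d}" for i in range(n_var)] + \
                 [f"DC{i:03d}" for i in range(config.n_constant_descriptors)]
    descriptors = pd.DataFrame(desc_all, index=ligand_ids, columns=desc_names)
    descriptors.index.name = "ligand_id"

    # Sample n_pairs distinct (ligand, receptor) combinations.
    total_combos = config.n_ligands * config.n_receptors
    combo_idx = rng.choice(total_combos, size=config.n_pairs, replace=False)
    pair_l = combo_idx // config.n_receptors
    pair_r = combo_idx % config.n_receptors

    # Planted labels. The bilinear interaction between each archetype's
    # (noise-free) descriptor pattern and each receptor's embedding dims
    # scores every (receptor, archetype) cell per class. Within a receptor,
    # cells are allocated to classes integrally — largest-remainder quotas on
    # class_mix, greedily by bilinear preference — so every receptor's label
    # marginal approximates the global mix (receptor identity alone carries
    # almost no class information; the per-receptor frequency baseline stays
    # at class-mix chance level) while cells themselves stay class-pure.
    # The label is one categorical draw from
    # softmax(log(class_mix) + signal_strength x onehot(assigned class)):
    # signal 0 reduces to the bare class mix, large signal is deterministic.
    mix = np.asarray(config.class_mix)
    W = rng.normal(size=(3, k_d, k_e))
    cell_u = np.einsum("ki,cij,rj->rkc", 2.0 * patterns, W, centroids[:, :k_e])
    cell_u = (cell_u - cell_u.mean()) / (cell_u.std() if cell_u.std() > 0 else 1.0)

    K = config.n_archetypes
    quota_base = np.floor(mix * K).astype(int)
    remainder_order = np.argsort(-(mix * K - quota_base), kind="stable")
    for c in remainder_order[: K - quota_base.sum()]:
        quota_base[c] += 1

    # Global archetype -> class base map honouring the quotas, plus exactly
    # one receptor-specific swap of two archetypes' classes (the pair the
    # receptor's bilinear scores favour most). Every receptor keeps the same
    # class composition — marginals stay at the mix — but deviates from the
    # base map in its own way, so the label genuinely needs both the ligand
    # archetype and the receptor.
    base_map = rng.permutation(np.repeat(np.arange(3), quota_base))
    assignment = np.tile(base_map, (config.n_receptors, 1))
    swap_pairs = [(k1, k2) for k1 in range(K) for k2 in range(k1 + 1, K)
                  if base_map[k1] != base_map[k2]]
    for r in range(config.n_receptors):
        gains = [cell_u[r, k1, base_map[k2]] + cell_u[r, k2, base_map[k1]]
                 - cell_u[r, k1, base_map[k1]] - cell_u[r, k2, base_map[k2]]
                 for k1, k2 in swap_pairs]
        k1, k2 = swap_pairs[int(np.argmax(gains))]
        assignment[r, k1], assignment[r, k2] = base_map[k2], base_map[k1]

    assigned = assignment[pair_r, archetypes[pair_l]]
    logits = np.log(mix)[None, :] + config.signal_strength * np.eye(3)[assigned]
    logits -= logits.max(axis=1, keepdims=True)
    proba = np.exp(logits)
    proba /= proba.sum(axis=1, keepdims=True)
    draws = rng.random(config.n_pairs)
    labels = (draws[:, None] > np.cumsum(proba, axis=1)).sum(axis=1)

    # Ki measurements, replicate structure, outliers, conflicts.
    has_ki = rng.random(config.n_pairs) >= config.ki_missing_rate
    duplicated = has_ki & (rng.random(config.n_pairs) < config.dup_rate)
    outlier = duplicated & (rng.random(config.n_pairs) < config.outlier_rate)
    conflicted = rng.random(config.n_pairs) < config.conflict_rate

    records: list[InteractionRecord] = []
    outlier_keys: list[tuple[str, str]] = []
    conflict_keys: list[tuple[str, str]] = []
    for i in range(config.n_pairs):
        lid, rid = ligand_ids[pair_l[i]], receptor_ids[pair_r[i]]
        label = int(labels[i])
        ki_values: list[list[float]] = []
        if has_ki[i]:
            if duplicated[i]:
                if outlier[i]:
                    n_rep = int(rng.integers(3, 5))  # 2-3 clean + 1 gross outlier
                    clean = n_rep - 1
                else:
                    n_rep, clean = 2, 2
            else:
                n_rep, clean = 1, 1
            # pair-level affinity spread (0.4 log10 units) on top of the class
            # mean; replicate-level spread is the (smaller) ki_noise_sd
            mu = _KI_LOG10_MEAN[label] + 0.4 * rng.normal()
            reps = 10 ** (mu + config.ki_noise_sd * rng.normal(size=clean))
            ki_values = [[float(v)] for v in reps]
            if duplicated[i] and outlier[i]:
                ki_values.append([float(reps[0] * 10.0)])
                outlier_keys.append((lid, rid))
        base = dict(ligand_id=lid, smiles=smiles[pair_l[i]], receptor_id=rid,
                    source="synth")
        if ki_values:
            for kv in ki_values:
                records.append(InteractionRecord(action_class=label,
                                                 ki_values_nM=kv, **base))
        else:
            records.append(InteractionRecord(action_class=label, **base))
        if conflicted[i]:
            other = [c for c in (0, 1, 2) if c != label]
            wrong = int(other[int(rng.integers(2))])
            records.append(InteractionRecord(action_class=wrong, **base))
            conflict_keys.append((lid, rid))

    truth = {
        "config": asdict(config),
        "archetype_by_ligand": {ligand_ids[i]: int(archetypes[i])
                                for i in range(config.n_ligands)},
        "informative_descriptor_columns": desc_names[:k_d],
        "constant_descriptor_columns": desc_names[n_var:],
        "pair_keys": [(ligand_ids[pair_l[i]], receptor_ids[pair_r[i]])
                      for i in range(config.n_pairs)],
        "planted_labels": labels.tolist(),
        "planted_label_proba": proba.tolist(),
        "n_outlier_sets": len(outlier_keys),
        "outlier_keys": outlier_keys,
        "n_conflicts": len(conflict_keys),
        "conflict_keys": conflict_keys,
    }
    return InteractionTable(records), descriptors, embeddings, truth
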