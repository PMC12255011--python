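"""Per-receptor comparison baselines.

Two intentionally simple references bracket what receptor identity and ligand
similarity alone can achieve. The *frequency-aware random classifier* draws
each test pair's label from its receptor's training class frequencies (global
prior for unseen receptors); its expected accuracy has the closed form
sum_c p_c q_c per receptor, with p the test class distribution and q the
training frequencies, aggregated by test support. The *similarity baseline*
predicts the label of the most Tanimoto-similar training ligand of the same
receptor (Morgan circular fingerprints), falling back to a global search for
unseen receptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from maap.io import InteractionTable, SmilesError
from maap.metrics import EvaluationReport, evaluate

logger = logging.getLogger(__name__)

N_CLASSES = 3


def _class_freq(labels: list[int]) -> np.ndarray:
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=N_CLASSES)
    return counts / counts.sum()


class ReceptorFrequencyClassifier(BaseEstimator, ClassifierMixin):
    """Draws labels from per-receptor training class frequencies.

    ``fit`` takes receptor ids and labels; ``predict`` draws one seeded sample
    per row. ``expected_accuracy`` gives the closed form sum_c p_c q_c
    aggregated over receptors by test support.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, receptor_ids, y):
        y = np.asarray(y, dtype=int)
        if len(y) == 0:
            raise ValueError("empty training data")
        self.global_prior_ = _class_freq(y.tolist())
        self.priors_ = {}
        by_receptor: dict[str, list[int]] = {}
        for rid, lab in zip(receptor_ids, y):
            by_receptor.setdefault(str(rid), []).append(int(lab))
        for rid, labs in by_receptor.items():
            self.priors_[rid] = _class_freq(labs)
        self.classes_ = np.arange(N_CLASSES)
        return self

    def prior_for(self, receptor_id: str) -> np.ndarray:
        return self.priors_.get(str(receptor_id), self.global_prior_)

    def predict_proba(self, receptor_ids):
        return np.vstack([self.prior_for(r) for r in receptor_ids])

    def predict(self, receptor_ids):
        rng = np.random.default_rng(self.seed)
        proba = self.predict_proba(receptor_ids)
        cum = np.cumsum(proba, axis=1)
        u = rng.random(len(proba))
        return (u[:, None] > cum).sum(axis=1)

    def expected_accuracy(self, receptor_ids, y_true) -> float:
        y_true = np.asarray(y_true, dtype=int)
        by_receptor: dict[str, list[int]] = {}
        for rid, lab in zip(receptor_ids, y_true):
            by_receptor.setdefault(str(rid), []).append(int(lab))
        total = len(y_true)
        acc = 0.0
        for rid, labs in by_receptor.items():
            p = _class_freq(labs)
            q = self.prior_for(rid)
            acc += len(labs) / total * float(p @ q)
        return acc


def frequency_baseline(train_table: InteractionTable, test_table: InteractionTable,
                       seed: int = 0, mode: str = "sample"):
    """Run the frequency baseline on interaction tables.

    mode 'sample' returns an EvaluationReport of one seeded draw; mode
    'expected' returns the closed-form expected accuracy (float).
    """
    if len(train_table) == 0:
        raise ValueError("empty training table")
    clf = ReceptorFrequencyClassifier(seed=seed)
    clf.fit([r.receptor_id for r in train_table], train_table.labels())
    test_receptors = [r.receptor_id for r in test_table]
    if mode == "expected":
        return clf.expected_accuracy(test_receptors, test_table.labels())
    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}; use 'sample' or 'expected'")
    y_pred = clf.predict(test_receptors)
    return evaluate(test_table.labels(), y_pred,
                    scores=clf.predict_proba(test_receptors))


def _morgan_fp(smiles: str, radius: int, n_bits: int):
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


class ReceptorSimilarityClassifier(BaseEstimator, ClassifierMixin):
    """1-nearest-neighbour by Tanimoto similarity within the same receptor.

    Similarity ties take the majority label among tied neighbours, then the
    lowest class index; training-set row order never affects predictions.
    """

    def __init__(self, k: int = 1, radius: int = 2, n_bits: int = 2048):
        self.k = k
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, table: InteractionTable):
        if len(table) == 0:
            raise ValueError("empty training table")
        self.entries_ = []  # (receptor_id, fingerprint, label)
        for r in table:
            try:
                fp = _morgan_fp(r.smiles, self.radius, self.n_bits)
            except SmilesError:
                logger.warning("skipping training record with bad SMILES %r", r.smiles)
                continue
            self.entries_.append((r.receptor_id, fp, r.action_class))
        if not self.entries_:
            raise ValueError("no parseable training SMILES")
        self.classes_ = np.arange(N_CLASSES)
        return self

    def _predict_one(self, receptor_id: str, smiles: str) -> int:
        from rdkit import DataStructs

        fp = _morgan_fp(smiles, self.radius, self.n_bits)
        pool = [e for e in self.entries_ if e[0] == receptor_id]
        if not pool:
            pool = self.entries_  # unseen receptor: global search fallback
        sims = np.array([DataStructs.TanimotoSimilarity(fp, e[1]) for e in pool])
        best = sims.max()
        tied = [pool[i][2] for i in np.flatnonzero(sims == best)]
        counts = np.bincount(tied, minlength=N_CLASSES)
        return int(np.argmax(counts))  # majority, then lowest class index

    def predict(self, table: InteractionTable) -> tuple[np.ndarray, list[int]]:
        """Predict labels for a test table; returns (labels, rejected row indices).

        Rows with unparseable SMILES are rejected (label -1) and counted.
        """
        labels = np.full(len(table), -1, dtype=int)
        rejected = []
        for i, r in enumerate(table):
            try:
                labels[i] = self._predict_one(r.receptor_id, r.smiles)
            except SmilesError:
                rejected.append(i)
        return labels, rejected


def similarity_baseline(train_table: InteractionTable, test_table: InteractionTable,
                        k: int = 1, radius: int = 2, n_bits: int = 2048
                        ) -> tuple[np.ndarray, list[int], EvaluationReport]:
    """Fit and run the similarity baseline; returns (predictions, rejected, report)."""
    clf = ReceptorSimilarityClassifier(k=k, radius=radius, n_bits=n_bits).fit(train_table)
    y_pred, rejected = clf.predict(test_table)
    keep = [i for i in range(len(test_table)) if i not in set(rejected)]
    report = evaluate(test_table.labels()[keep], y_pred[keep])
    return y_pred, rejected, report
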