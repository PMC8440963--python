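"""Cross-validation protocol, accuracy, Cohen's kappa and the paired t-test.

All trials (both recording sessions pooled) are shuffled once with a seeded
permutation and split into k contiguous folds whose sizes differ by at most
one; each fold serves once as validation while the other nine train.  Kappa is
reported both per fold and from the pooled confusion matrix; stages are
compared with a classical two-tailed paired t-test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sstats

from .io import EpochSet, N_CLASSES
from .network import MultiBranchModel, NetworkParams, train
from .representation import build_tensor, electrode_stats, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "FoldResult",
    "StageReport",
    "TTestResult",
    "cohen_kappa",
    "confusion_matrix",
    "crossvalidate",
    "make_folds",
    "paired_ttest",
]


@dataclass
class FoldAssignment:
    fold_of_trial: dict[str, int]
    n_folds: int
    seed: int

    def fold_indices(self, eset: EpochSet) -> list[np.ndarray]:
        """Per-fold epoch indices in eset order."""
        out = [[] for _ in range(self.n_folds)]
        for i, e in enumerate(eset):
            out[self.fold_of_trial[e.trial_id]].append(i)
        return [np.array(ix, dtype=np.int64) for ix in out]


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    kappa: float
    confusion: np.ndarray
    seed: int = 0


@dataclass
class StageReport:
    subject_id: str
    stage: int
    fold_results: list[FoldResult]
    mean_accuracy: float
    std_accuracy: float
    mean_kappa: float
    pooled_kappa: float
    filter_frequencies: list[int] = field(default_factory=list)

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([fr.accuracy for fr in self.fold_results])

    def to_dict(self) -> dict:
        d = asdict(self)
        for fr in d["fold_results"]:
            fr["confusion"] = np.asarray(fr["confusion"]).astype(int).tolist()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class TTestResult:
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def make_folds(eset: EpochSet, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded uniform shuffle, then contiguous split into k folds.

    Fold sizes differ by at most one (576 trials -> six folds of 58 and four
    of 57); deterministic given the seed.
    """
    n = len(eset)
    if n < k:
        raise ValueError(f"{n} trials cannot fill {k} folds")
    ids = [e.trial_id for e in eset]
    if len(set(ids)) != n:
        raise ValueError("trial ids must be unique for fold bookkeeping")
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    assignment: dict[str, int] = {}
    pos = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        for i in perm[pos:pos + size]:
            assignment[ids[i]] = fold
        pos += size
    return FoldAssignment(assignment, k, seed)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e).

    For balanced four-class folds this reduces to (accuracy - 0.25) / 0.75.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    n = cm.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def paired_ttest(a, b) -> TTestResult:
    """Two-tailed paired t-test on per-unit score pairs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D score vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return TTestResult(0.0, 1.0, n, degenerate=False)
        # identical nonzero differences: infinitely significant, flagged
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(float(t), 1e-300, n, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), float(p), n)


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------

def fold_seed(master_seed: int, fold: int) -> int:
    """Deterministic per-fold seed below 2**31."""
    return int((np.uint32(master_seed) * np.uint32(1000003) + np.uint32(fold + 1))
               % np.uint32(2**31 - 1))


def run_fold(
    train_set: EpochSet,
    test_set: EpochSet,
    spec: NetworkParams,
    seed: int,
    fold: int,
) -> tuple[FoldResult, MultiBranchModel]:
    """Train on one fold split (training-fold z-scoring stats) and score it."""
    import dataclasses

    train_b = build_tensor(train_set)
    test_b = build_tensor(test_set)
    stats = electrode_stats(train_b, train_set.electrodes)
    train_b = standardize(train_b, stats, train_set.electrodes)
    test_b = standardize(test_b, stats, test_set.electrodes)
    fspec = dataclasses.replace(spec, seed=seed)
    model = train(fspec, train_b, test_b)
    y_pred = model.predict(test_b.data)
    cm = confusion_matrix(test_b.class_ids, y_pred)
    acc = float(np.trace(cm) / cm.sum())
    return FoldResult(fold=fold, accuracy=acc, kappa=cohen_kappa(cm),
                      confusion=cm, seed=seed), model


def crossvalidate(
    eset: EpochSet,
    spec: NetworkParams,
    folds: FoldAssignment,
    *,
    subject_id: str = "synthetic",
    stage: int = 1,
) -> StageReport:
    """Plain k-fold cross-validation of the network on one epoch set."""
    indices = folds.fold_indices(eset)
    results: list[FoldResult] = []
    pooled = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for fold, test_ix in enumerate(indices):
        train_ix = np.concatenate([ix for f, ix in enumerate(indices) if f != fold])
        fr, _ = run_fold(
            eset.subset(train_ix), eset.subset(test_ix),
            spec, fold_seed(spec.seed, fold), fold,
        )
        pooled += fr.confusion
        results.append(fr)
        logger.info("fold %d: accuracy %.3f kappa %.3f", fold, fr.accuracy, fr.kappa)
    accs = np.array([fr.accuracy for fr in results])
    kappas = np.array([fr.kappa for fr in results])
    return StageReport(
        subject_id=subject_id,
        stage=stage,
        fold_results=results,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_kappa=float(kappas.mean()),
        pooled_kappa=cohen_kappa(pooled),
    )
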