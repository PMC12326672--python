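"""Evaluation protocol: metrics, splits and imbalance construction.

AUROC uses the rank-sum (half-credit ties) convention; AUPR is the area
under the precision-recall step curve without interpolation — interpolated
AUPR inflates scores exactly in the imbalanced regime this method targets.
Test-set imbalance is constructed by augmenting the test positives with
negatives drawn from pairs unseen in ALL splits, to positive-to-negative
ratios of 1:10, 1:100 or 1:1000.

Split modes: random 7:1:2 over pairs, or cold-start (unseen-drug /
unseen-protein) holding out 20% of entities and routing all their pairs to
test/validation at 70/30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from gbadti.errors import UndefinedMetricError, ValidationError
from gbadti.io import InteractionSet

MODE_RANDOM = "random"
MODE_UNSEEN_DRUG = "unseen_drug"
MODE_UNSEEN_PROTEIN = "unseen_protein"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "metric undefined: labels contain a single class"
        )
    return labels


def auroc(scores, labels) -> float:
    """P(random positive outranks random negative), ties count half."""
    labels = _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (no interpolation)."""
    labels = _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def accuracy_f1(scores, labels, threshold: float) -> tuple[float, float]:
    """Accuracy and F1 at ``score >= threshold``; F1 is 0 by convention when
    nothing is predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return float(acc), float(f1)


def best_f1_threshold(scores, labels) -> float:
    """Threshold maximizing F1 over the observed scores (validation tuning)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best_t, best_f1 = 0.5, -1.0
    for t in np.unique(scores):
        _, f1 = accuracy_f1(scores, labels, t)
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def topk_positive_count(scores, labels, ks=(10, 100, 1000, 10000),
                        ids=None) -> dict[int, int]:
    """Positives among the k highest-scoring items, for each k.

    Ties are broken deterministically by id (lexicographic) when ids are
    given, by original position otherwise.  ks larger than the item count
    are truncated with a warning.
    """
    import warnings
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(scores)
    if ids is None:
        ids = [f"{i:012d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (-scores[i], str(ids[i])))
    ranked_labels = labels[order]
    cum = np.concatenate([[0], np.cumsum(ranked_labels)])
    out = {}
    for k in ks:
        kk = min(int(k), n)
        if kk < k:
            warnings.warn(f"top-{k} truncated to {kk} items")
        out[int(k)] = int(cum[kk])
    return out


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    accuracy: float
    f1: float
    threshold: float
    ratio: float                       # positive : negative ratio as 1:r
    topk_counts: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = dict(auroc=self.auroc, aupr=self.aupr, accuracy=self.accuracy,
                 f1=self.f1, threshold=self.threshold, ratio=self.ratio)
        d.update({f"top{k}": v for k, v in self.topk_counts.items()})
        return d


def evaluate_predictions(scores, labels, threshold: float | None = None,
                         val_scores=None, val_labels=None,
                         ks=(10, 100, 1000, 10000), ids=None) -> EvalReport:
    """Full metric panel for one scored test set.

    The Accuracy/F1 threshold is, in order of preference: the explicit
    ``threshold``, the validation-set F1-maximizing score, or 0.5.
    """
    labels_arr = _check_two_class(labels)
    if threshold is None:
        if val_scores is not None and val_labels is not None:
            threshold = best_f1_threshold(val_scores, val_labels)
        else:
            threshold = 0.5
    acc, f1 = accuracy_f1(scores, labels_arr, threshold)
    n_pos = int(labels_arr.sum())
    n_neg = len(labels_arr) - n_pos
    return EvalReport(
        auroc=auroc(scores, labels_arr),
        aupr=aupr(scores, labels_arr),
        accuracy=acc, f1=f1, threshold=float(threshold),
        ratio=n_neg / n_pos,
        topk_counts=topk_positive_count(scores, labels_arr, ks, ids),
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def make_split(interactions: InteractionSet, mode: str, seed: int,
               fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
               holdout_fraction: float = 0.2,
               ) -> tuple[InteractionSet, InteractionSet, InteractionSet]:
    """Partition labeled pairs into (train, val, test).

    random: pairs shuffled and cut 7:1:2.  unseen_drug / unseen_protein:
    ``holdout_fraction`` of entities are held out; all their pairs go to
    test (70%) and validation (30%); the remaining pairs train.
    """
    rng = np.random.default_rng(seed)
    pairs = list(interactions.pairs)
    if mode == MODE_RANDOM:
        ft, fv, fe = fractions
        if abs(ft + fv + fe - 1) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        order = rng.permutation(len(pairs))
        n = len(pairs)
        n_train, n_val = int(round(ft * n)), int(round(fv * n))
        idx_train = order[:n_train]
        idx_val = order[n_train:n_train + n_val]
        idx_test = order[n_train + n_val:]
        mk = lambda idx: InteractionSet(pairs=[pairs[i] for i in sorted(idx)])
        return mk(idx_train), mk(idx_val), mk(idx_test)

    if mode not in (MODE_UNSEEN_DRUG, MODE_UNSEEN_PROTEIN):
        raise ValidationError(f"unknown split mode {mode!r}")
    entity_pos = 0 if mode == MODE_UNSEEN_DRUG else 1
    entities = sorted({p[entity_pos] for p in pairs})
    n_hold = int(round(holdout_fraction * len(entities)))
    if n_hold == 0:
        raise ValidationError("holdout would be empty; too few entities")
    held = set(rng.permutation(entities)[:n_hold].tolist())
    held_pairs = [p for p in pairs if p[entity_pos] in held]
    train_pairs = [p for p in pairs if p[entity_pos] not in held]
    if not train_pairs:
        raise ValidationError("cold-start holdout empties the training set")
    order = rng.permutation(len(held_pairs))
    n_test = int(round(0.7 * len(held_pairs)))
    idx_test = sorted(order[:n_test])
    idx_val = sorted(order[n_test:])
    return (InteractionSet(pairs=train_pairs),
            InteractionSet(pairs=[held_pairs[i] for i in idx_val]),
            InteractionSet(pairs=[held_pairs[i] for i in idx_test]))


def augment_test_negatives(test: InteractionSet, drug_ids: list[str],
                           protein_ids: list[str], ratio: int, seed: int,
                           known_pairs: set[tuple[str, str]] | None = None
                           ) -> InteractionSet:
    """Extend the test set with unseen-pair negatives to exactly 1:ratio.

    Existing test negatives are retained and count toward the ratio.
    ``known_pairs`` must contain every labeled pair of every split so no
    augmented negative collides with anything seen elsewhere.
    """
    n_pos = len(test.positives())
    if n_pos == 0:
        raise ValidationError("test set has no positives to augment around")
    existing_neg = len(test.negatives())
    target_neg = ratio * n_pos
    if existing_neg > target_neg:
        raise ValidationError(
            f"test set already has {existing_neg} negatives; cannot reach "
            f"ratio 1:{ratio} with {n_pos} positives"
        )
    need = target_neg - existing_neg
    forbidden = {(d, p) for d, p, _ in test.pairs} | (known_pairs or set())
    m, n = len(drug_ids), len(protein_ids)
    universe = m * n - len({fp for fp in forbidden
                            if fp[0] in set(drug_ids) and fp[1] in set(protein_ids)})
    if need > universe:
        raise ValidationError(
            f"cannot augment to 1:{ratio}: need {need} unseen negatives but "
            f"only {universe} unlabeled pairs exist (short by {need - universe})"
        )
    sampled = _sample_unlabeled(drug_ids, protein_ids, need, seed, forbidden)
    return InteractionSet(pairs=list(test.pairs) + [(d, p, 0) for d, p in sampled])


def _sample_unlabeled(drug_ids, protein_ids, need, seed,
                      forbidden: set[tuple[str, str]]) -> list[tuple[str, str]]:
    rng = np.random.default_rng(seed)
    m, n = len(drug_ids), len(protein_ids)
    dmap = {d: i for i, d in enumerate(drug_ids)}
    pmap = {p: j for j, p in enumerate(protein_ids)}
    forbidden_flat = {dmap[d] * n + pmap[p] for d, p in forbidden
                      if d in dmap and p in pmap}
    if m * n <= 2_000_000:
        allowed = np.setdiff1d(np.arange(m * n),
                               np.fromiter(forbidden_flat, dtype=int,
                                           count=len(forbidden_flat)))
        chosen = rng.choice(allowed, size=need, replace=False)
    else:
        chosen_set: set[int] = set()
        while len(chosen_set) < need:
            for f in rng.integers(0, m * n, size=2 * (need - len(chosen_set))):
                f = int(f)
                if f not in forbidden_flat and f not in chosen_set:
                    chosen_set.add(f)
                    if len(chosen_set) == need:
                        break
        chosen = np.fromiter(chosen_set, dtype=int, count=need)
    return [(drug_ids[f // n], protein_ids[f % n])
            for f in sorted(map(int, chosen))]
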