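"""End-to-end planted-structure experiments.

One call runs the full pipeline on a synthetic block dataset: generate,
split, sample negatives, build the relative-distance bundle, train, and
evaluate on a held-out set both balanced (1:1) and at a requested
positive-to-negative imbalance, with negatives drawn from pairs unseen in
any split.

At the default study size (200 drugs x 100 proteins) the pair universe is
20,000, so a 1:r imbalanced test set cannot retain every test positive
(r * positives would exceed the unseen-pair pool); the study keeps a seeded
subsample of test positives sized to the largest count the pool supports
and augments to the exact ratio around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gbadti.config import RunConfig
from gbadti.evaluate import (
    augment_test_negatives,
    aupr,
    auroc,
    make_split,
    topk_positive_count,
)
from gbadti.featurize import SimilarityMatrix, KIND_DRUG_DICE, feature_similarity_matrix
from gbadti.io import InteractionSet
from gbadti.reldist import build_bundle
from gbadti.simulate import BlockModelSpec, generate_block_dataset
from gbadti.train import _score_pairs, sample_negatives, train


def dice_from_bits(X: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    """Dice similarity of stacked binary feature vectors."""
    B = (np.asarray(X) > 0).astype(np.int64)
    counts = B.sum(axis=1).astype(float)
    inter = (B @ B.T).astype(float)
    denom = counts[:, None] + counts[None, :]
    S = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(ids), KIND_DRUG_DICE)


@dataclass
class StudyResult:
    seed: int
    loss_kind: str
    auroc_balanced: float
    aupr_balanced: float
    aupr_imbalanced: float
    ratio: int
    n_test_positives_imbalanced: int
    topk: dict[int, int]
    n_drugs: int
    n_proteins: int
    n_train_pairs: int


def planted_study(seed: int, loss_kind: str = "gba",
                  spec: BlockModelSpec | None = None,
                  config: RunConfig | None = None,
                  split_mode: str = "random",
                  ratio: int = 100) -> StudyResult:
    """Run the pipeline once on a planted block dataset and evaluate held-out
    performance balanced and at 1:ratio imbalance."""
    spec = spec if spec is not None else BlockModelSpec(seed=seed)
    cfg = (config if config is not None else RunConfig.small()).replace(seed=seed)
    ds = generate_block_dataset(spec)
    s_r = dice_from_bits(ds.drug_features, ds.drug_ids)
    s_p = feature_similarity_matrix(ds.protein_features, ds.protein_ids)

    tr, va, te = make_split(ds.interactions, split_mode, seed)
    known = {(d, p) for part in (tr, va, te) for d, p, _ in part.pairs}
    trn = sample_negatives(tr, ds.drug_ids, ds.protein_ids, cfg.neg_ratio,
                           seed + 1, exclude=known)
    known |= {(d, p) for d, p, _ in trn.pairs}
    van = sample_negatives(va, ds.drug_ids, ds.protein_ids, 1, seed + 2,
                           exclude=known)
    known |= {(d, p) for d, p, _ in van.pairs}
    train_set = InteractionSet(pairs=tr.pairs + trn.pairs)
    val_set = InteractionSet(pairs=va.pairs + van.pairs)

    bundle = build_bundle(s_r, s_p, train_set, cfg.t_root)
    result = train(ds.drug_features, ds.protein_features, bundle, train_set,
                   cfg, loss_kind=loss_kind, val_set=val_set)

    dmap, pmap = bundle.drug_index, bundle.protein_index

    def score(iset: InteractionSet):
        idx = [(dmap[d], pmap[p]) for d, p, _ in iset.pairs]
        scores = _score_pairs(result.model, ds.drug_features,
                              ds.protein_features, idx)
        return scores, np.array([y for _, _, y in iset.pairs])

    # balanced held-out evaluation: test positives + fresh 1:1 negatives
    ten = sample_negatives(te, ds.drug_ids, ds.protein_ids, 1, seed + 3,
                           exclude=known)
    known |= {(d, p) for d, p, _ in ten.pairs}
    s_bal, y_bal = score(InteractionSet(pairs=te.pairs + ten.pairs))

    # imbalanced: subsample test positives to what the unseen pool supports
    pos = te.positives()
    m, n = len(ds.drug_ids), len(ds.protein_ids)
    pool = m * n - len(known)
    n_pos = min(len(pos), pool // ratio)
    if n_pos < 1:
        raise ValueError(f"unseen-pair pool too small for ratio 1:{ratio}")
    rng = np.random.default_rng(seed + 5)
    keep = rng.choice(len(pos), size=n_pos, replace=False)
    sub = InteractionSet(pairs=[(pos[i][0], pos[i][1], 1) for i in keep])
    imb = augment_test_negatives(sub, ds.drug_ids, ds.protein_ids, ratio,
                                 seed + 6, known_pairs=known)
    s_imb, y_imb = score(imb)

    return StudyResult(
        seed=seed, loss_kind=loss_kind,
        auroc_balanced=auroc(s_bal, y_bal),
        aupr_balanced=aupr(s_bal, y_bal),
        aupr_imbalanced=aupr(s_imb, y_imb),
        ratio=ratio,
        n_test_positives_imbalanced=n_pos,
        topk=topk_positive_count(s_imb, y_imb, ks=(10, 100, 1000),
                                 ids=[f"{d}|{p}" for d, p, _ in imb.pairs]),
        n_drugs=m, n_proteins=n,
        n_train_pairs=len(train_set),
    )
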