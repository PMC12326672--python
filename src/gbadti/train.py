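"""Guilt-by-association training.

The loss aligns embedding-space cosine distances Phi with the relative
distances RD of the heterogeneous network::

    L = L_drug + L_protein + lambda * L_interaction
    L_drug        = mean over ordered in-batch drug pairs    (Phi - RD)^2
    L_protein     = mean over ordered in-batch protein pairs (Phi - RD)^2
    L_interaction = mean over the batch's labeled pairs      (Phi - RD)^2

The loss is defined as full sums over all m^2 / n^2 pairs; evaluating the
three terms inside each mini-batch (means, so lambda's effect is
batch-size-stable) is the standard mini-batch estimator for pairwise
losses.  The interaction term runs over the training pair set — positives
plus 1:1 sampled negatives — not over all m*n pairs.

The OI (only-interaction) ablation keeps just the third term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gbadti.config import RunConfig
from gbadti.errors import ValidationError
from gbadti.io import InteractionSet
from gbadti.model import TwoTowerModel
from gbadti.reldist import RelativeDistanceBundle


@dataclass
class TrainingBatch:
    """Unique in-batch entity indices plus labeled pairs in local coordinates."""

    drug_indices: np.ndarray       # global drug indices, unique
    protein_indices: np.ndarray    # global protein indices, unique
    pair_drug: np.ndarray          # local (in-batch) drug index per pair
    pair_protein: np.ndarray       # local protein index per pair
    pair_rd: np.ndarray            # RD in {0,1} per pair (1 - y)

    def __post_init__(self):
        self.drug_indices = np.asarray(self.drug_indices, dtype=int)
        self.protein_indices = np.asarray(self.protein_indices, dtype=int)
        self.pair_drug = np.asarray(self.pair_drug, dtype=int)
        self.pair_protein = np.asarray(self.pair_protein, dtype=int)
        self.pair_rd = np.asarray(self.pair_rd, dtype=float)
        if len(np.unique(self.drug_indices)) != len(self.drug_indices):
            raise ValidationError("batch drug indices must be unique")
        if len(np.unique(self.protein_indices)) != len(self.protein_indices):
            raise ValidationError("batch protein indices must be unique")
        if len(self.drug_indices) < 2 or len(self.protein_indices) < 2:
            raise ValidationError("a batch needs >= 2 drugs and >= 2 proteins")
        if self.pair_drug.size and (self.pair_drug.max() >= len(self.drug_indices)
                                    or self.pair_protein.max() >= len(self.protein_indices)):
            raise ValidationError("pair refers to an entity outside the batch")

    def __len__(self) -> int:
        return len(self.pair_rd)


@dataclass
class LossReport:
    l_drug: float
    l_protein: float
    l_interaction: float
    lambda_weight: float

    @property
    def total(self) -> float:
        return self.l_drug + self.l_protein + self.lambda_weight * self.l_interaction


def _pairwise_term(Z: np.ndarray, RD: np.ndarray):
    """Mean squared (Phi - RD) over ordered off-diagonal pairs; returns the
    loss and dL/dU premultiplied pieces (U = row-normalized Z)."""
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    U = Z / norms
    C = U @ U.T
    Phi = 1.0 - C
    B = Z.shape[0]
    n_pairs = B * (B - 1)
    mask = 1.0 - np.eye(B)
    resid = (Phi - RD) * mask
    loss = float((resid ** 2).sum() / n_pairs)
    # dL/dC = -2 resid / n_pairs ; C = U U^T  =>  dL/dU = (G + G^T) U
    G = -2.0 * resid / n_pairs
    dU = (G + G.T) @ U
    return loss, U, dU, norms


def _project_unit_grad(dU: np.ndarray, U: np.ndarray, norms: np.ndarray) -> np.ndarray:
    """Backprop through row normalization U = Z / ||Z||."""
    return (dU - U * (dU * U).sum(axis=1, keepdims=True)) / norms


def gba_loss(Zd: np.ndarray, Zp: np.ndarray, RDd: np.ndarray, RDp: np.ndarray,
             batch_pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
             lambda_weight: float,
             with_grad: bool = False):
    """GBA loss over one batch of embeddings.

    Parameters are the in-batch drug/protein embeddings, the RD submatrices
    restricted to the batch, and the labeled pairs as (local drug idx,
    local protein idx, rd) arrays.  Returns a LossReport, plus (dZd, dZp)
    when ``with_grad``.
    """
    pi, pj, rd = (np.asarray(a) for a in batch_pairs)
    if Zd.shape[0] < 2 or Zp.shape[0] < 2:
        raise ValidationError("gba_loss needs >= 2 drugs and >= 2 proteins")
    l_drug, Ud, dUd, nd = _pairwise_term(Zd, RDd)
    l_protein, Up, dUp, np_ = _pairwise_term(Zp, RDp)

    if len(rd) == 0:
        l_int = 0.0
    else:
        c = (Ud[pi] * Up[pj]).sum(axis=1)
        phi = 1.0 - c
        resid = phi - rd
        l_int = float(np.mean(resid ** 2))
        if with_grad and lambda_weight != 0.0:
            dc = -2.0 * lambda_weight * resid / len(rd)
            np.add.at(dUd, pi, dc[:, None] * Up[pj])
            np.add.at(dUp, pj, dc[:, None] * Ud[pi])

    report = LossReport(l_drug, l_protein, l_int, lambda_weight)
    if not with_grad:
        return report
    dZd = _project_unit_grad(dUd, Ud, nd)
    dZp = _project_unit_grad(dUp, Up, np_)
    return report, dZd, dZp


def oi_loss(Zd: np.ndarray, Zp: np.ndarray,
            batch_pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
            with_grad: bool = False):
    """Only-interaction ablation: the label-alignment term alone."""
    pi, pj, rd = (np.asarray(a) for a in batch_pairs)
    norms_d = np.linalg.norm(Zd, axis=1, keepdims=True)
    norms_p = np.linalg.norm(Zp, axis=1, keepdims=True)
    Ud, Up = Zd / norms_d, Zp / norms_p
    c = (Ud[pi] * Up[pj]).sum(axis=1)
    resid = (1.0 - c) - rd
    l_int = float(np.mean(resid ** 2)) if len(rd) else 0.0
    report = LossReport(0.0, 0.0, l_int, 1.0)
    if not with_grad:
        return report
    dUd = np.zeros_like(Ud)
    dUp = np.zeros_like(Up)
    if len(rd):
        dc = -2.0 * resid / len(rd)
        np.add.at(dUd, pi, dc[:, None] * Up[pj])
        np.add.at(dUp, pj, dc[:, None] * Ud[pi])
    dZd = _project_unit_grad(dUd, Ud, norms_d)
    dZp = _project_unit_grad(dUp, Up, norms_p)
    return report, dZd, dZp


# ---------------------------------------------------------------------------
# sampling and batching
# ---------------------------------------------------------------------------

def sample_negatives(positives: InteractionSet, drug_ids: list[str],
                     protein_ids: list[str], ratio: int,
                     seed: int, exclude: set[tuple[str, str]] | None = None
                     ) -> InteractionSet:
    """Uniform sample (without replacement) of ratio * |positives| unlabeled
    pairs from the drug x protein universe, avoiding positives and any
    extra excluded pairs.  Deterministic per seed."""
    pos = set(positives.positives())
    forbidden = pos | {(d, p) for d, p, _ in positives.pairs} | (exclude or set())
    m, n = len(drug_ids), len(protein_ids)
    need = ratio * len(pos)
    universe_size = m * n - len({fp for fp in forbidden
                                 if fp[0] in set(drug_ids) and fp[1] in set(protein_ids)})
    if need > universe_size:
        raise ValidationError(
            f"cannot sample {need} negatives: only {universe_size} unlabeled "
            "pairs available"
        )
    rng = np.random.default_rng(seed)
    dmap = {d: i for i, d in enumerate(drug_ids)}
    pmap = {p: j for j, p in enumerate(protein_ids)}
    forbidden_flat_set = {dmap[d] * n + pmap[p] for d, p in forbidden
                          if d in dmap and p in pmap}
    if m * n <= 2_000_000:
        # enumerate the complement exactly
        forbidden_flat = np.fromiter(forbidden_flat_set, dtype=int,
                                     count=len(forbidden_flat_set))
        allowed = np.setdiff1d(np.arange(m * n), forbidden_flat)
        chosen = rng.choice(allowed, size=need, replace=False)
    else:
        # rejection sampling for large universes
        chosen_set: set[int] = set()
        while len(chosen_set) < need:
            draw = rng.integers(0, m * n, size=2 * (need - len(chosen_set)))
            for f in draw:
                f = int(f)
                if f not in forbidden_flat_set and f not in chosen_set:
                    chosen_set.add(f)
                    if len(chosen_set) == need:
                        break
        chosen = np.fromiter(chosen_set, dtype=int, count=need)
    pairs = [(drug_ids[f // n], protein_ids[f % n], 0) for f in sorted(map(int, chosen))]
    return InteractionSet(pairs=pairs)


def make_batches(pairs: list[tuple[int, int, float]], batch_size: int,
                 rng: np.random.Generator) -> list[TrainingBatch]:
    """Shuffle labeled (drug idx, protein idx, rd) triples into batches.

    A trailing chunk smaller than ``batch_size`` is merged into the previous
    batch, so batch sizes are batch_size except possibly the last (up to
    2 * batch_size - 1), or a single batch when there are fewer pairs.
    """
    if batch_size < 2:
        raise ValidationError("batch_size must be >= 2")
    n_drugs = len({d for d, _, _ in pairs})
    n_prots = len({p for _, p, _ in pairs})
    if n_drugs < 2 or n_prots < 2:
        raise ValidationError("need >= 2 distinct drugs and proteins to batch")
    order = rng.permutation(len(pairs))
    chunks = [order[i:i + batch_size] for i in range(0, len(pairs), batch_size)]
    if len(chunks) > 1 and len(chunks[-1]) < batch_size:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    batches = []
    for chunk in chunks:
        sub = [pairs[i] for i in chunk]
        drugs = sorted({d for d, _, _ in sub})
        prots = sorted({p for _, p, _ in sub})
        dloc = {g: l for l, g in enumerate(drugs)}
        ploc = {g: l for l, g in enumerate(prots)}
        batches.append(TrainingBatch(
            drug_indices=np.array(drugs),
            protein_indices=np.array(prots),
            pair_drug=np.array([dloc[d] for d, _, _ in sub]),
            pair_protein=np.array([ploc[p] for _, p, _ in sub]),
            pair_rd=np.array([rd for _, _, rd in sub]),
        ))
    return batches


# ---------------------------------------------------------------------------
# optimizer and training loop
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, towers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.towers = towers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in tw.params().items()}
                  for tw in towers]
        self.v = [{k: np.zeros_like(v) for k, v in tw.params().items()}
                  for tw in towers]

    def step(self, grads_per_tower) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for tw, grads, m, v in zip(self.towers, grads_per_tower, self.m, self.v):
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                m_hat = m[k] / (1 - b1 ** self.t)
                v_hat = v[k] / (1 - b2 ** self.t)
                setattr(tw, k, getattr(tw, k)
                        - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


@dataclass
class TrainResult:
    model: TwoTowerModel
    log: list[dict] = field(default_factory=list)
    best_iteration: int = -1
    best_val_aupr: float = float("nan")


def train(drug_features: np.ndarray, protein_features: np.ndarray,
          bundle: RelativeDistanceBundle, train_set: InteractionSet,
          config: RunConfig, loss_kind: str = "gba",
          val_set: InteractionSet | None = None,
          eval_every: int = 25) -> TrainResult:
    """Adam-optimize both towers against the GBA (or OI) loss.

    ``train_set`` holds the labeled training pairs (positives plus sampled
    negatives).  ``val_set``, when given, is scored every ``eval_every``
    steps and the best-validation-AUPR checkpoint is restored at the end.
    Fully seeded; "iterations" are mini-batch optimization steps.
    """
    if loss_kind not in ("gba", "oi"):
        raise ValidationError(f"loss_kind must be 'gba' or 'oi', got {loss_kind!r}")
    from gbadti.evaluate import aupr, auroc  # local to avoid a cycle at import

    cfg = config
    model = TwoTowerModel(cfg)
    d_index, p_index = bundle.drug_index, bundle.protein_index
    pairs = [(d_index[d], p_index[p], 1.0 - y) for d, p, y in train_set.pairs]
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam([model.drug_tower, model.protein_tower], lr=cfg.learning_rate)

    val_pairs = None
    if val_set is not None:
        val_pairs = ([(d_index[d], p_index[p]) for d, p, _ in val_set.pairs],
                     np.array([y for _, _, y in val_set.pairs]))

    log: list[dict] = []
    best = dict(aupr=-np.inf, iteration=-1, state=None)
    step = 0
    while step < cfg.max_iterations:
        for batch in make_batches(pairs, cfg.batch_size, rng):
            if step >= cfg.max_iterations:
                break
            Xd = drug_features[batch.drug_indices]
            Xp = protein_features[batch.protein_indices]
            Zd = model.encode_drugs(Xd, training=True)
            Zp = model.encode_proteins(Xp, training=True)
            bp = (batch.pair_drug, batch.pair_protein, batch.pair_rd)
            if loss_kind == "gba":
                RDd = bundle.rd_drug[np.ix_(batch.drug_indices, batch.drug_indices)]
                RDp = bundle.rd_protein[np.ix_(batch.protein_indices,
                                               batch.protein_indices)]
                report, dZd, dZp = gba_loss(Zd, Zp, RDd, RDp, bp,
                                            cfg.lambda_weight, with_grad=True)
            else:
                report, dZd, dZp = oi_loss(Zd, Zp, bp, with_grad=True)
            if not np.isfinite(report.total):
                raise ValidationError(
                    f"non-finite loss at iteration {step} "
                    f"(lr={cfg.learning_rate}, batch drugs="
                    f"{batch.drug_indices[:5].tolist()}...)"
                )
            gd = model.drug_tower.backward(dZd)
            gp = model.protein_tower.backward(dZp)
            opt.step([gd, gp])

            entry = dict(iteration=step, l_drug=report.l_drug,
                         l_protein=report.l_protein,
                         l_interaction=report.l_interaction,
                         total=report.total)
            if val_pairs is not None and (step % eval_every == 0
                                          or step == cfg.max_iterations - 1):
                scores = _score_pairs(model, drug_features, protein_features,
                                      val_pairs[0])
                labels = val_pairs[1]
                if labels.min() != labels.max():
                    entry["val_auroc"] = auroc(scores, labels)
                    entry["val_aupr"] = aupr(scores, labels)
                    if entry["val_aupr"] > best["aupr"]:
                        best = dict(aupr=entry["val_aupr"], iteration=step,
                                    state=(model.drug_tower.state(),
                                           model.protein_tower.state()))
            log.append(entry)
            step += 1

    if best["state"] is not None:
        model.drug_tower.load_state(best["state"][0])
        model.protein_tower.load_state(best["state"][1])
    return TrainResult(model=model, log=log,
                       best_iteration=best["iteration"],
                       best_val_aupr=best["aupr"] if best["state"] else float("nan"))


def _score_pairs(model: TwoTowerModel, drug_features, protein_features,
                 index_pairs: list[tuple[int, int]]) -> np.ndarray:
    """Embed once, score the listed (drug idx, protein idx) pairs."""
    d_idx = sorted({d for d, _ in index_pairs})
    p_idx = sorted({p for _, p in index_pairs})
    Zd = model.encode_drugs(drug_features[d_idx], training=False)
    Zp = model.encode_proteins(protein_features[p_idx], training=False)
    dmap = {g: l for l, g in enumerate(d_idx)}
    pmap = {g: l for l, g in enumerate(p_idx)}
    nd = np.linalg.norm(Zd, axis=1)
    npn = np.linalg.norm(Zp, axis=1)
    Ud = Zd / np.maximum(nd, 1e-12)[:, None]
    Up = Zp / np.maximum(npn, 1e-12)[:, None]
    return np.array([float(Ud[dmap[d]] @ Up[pmap[p]]) for d, p in index_pairs])
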