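"""Relative distances of the drug-protein heterogeneous network.

Three ingredients define the target geometry of the embedding space:

* drug-drug:      RD(d1, d2) = 1 - S_r(d1, d2)           (Dice similarity)
* protein-protein RD(p1, p2) = 1 - S_p'(p1, p2), where S_p' replaces each
  raw Smith-Waterman score by the reciprocal of its within-row rank taken
  to the 1/t power — raw alignment scores are sparse and on an arbitrary
  scale, the rank-reciprocal t-th-root transform makes them commensurate
  with Dice similarities while preserving within-row order;
* drug-protein:   RD(d, p) = 1 - y for labeled pairs only.

The transform ranks each row independently (self excluded, dense ranks for
ties), so S_p' is generally asymmetric; the training loss sums over ordered
pairs, which is equivalent to regressing the symmetric cosine distance onto
the mean of RD_ij and RD_ji.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gbadti.errors import ValidationError
from gbadti.featurize import (
    KIND_DRUG_DICE,
    KIND_PROTEIN_SW_RAW,
    KIND_PROTEIN_TRANSFORMED,
    SimilarityMatrix,
)
from gbadti.io import InteractionSet


def rank_reciprocal_transform(s_p: SimilarityMatrix, t: float) -> SimilarityMatrix:
    """Per-row rank-reciprocal t-th-root transform of a raw similarity matrix.

    For each row i, the other entities are ranked by descending raw
    similarity (dense ranks: ties share a rank, the self-entry is excluded)
    and entry (i, j) becomes (1 / rank_i(j)) ** (1/t).  The diagonal is set
    to 1 (an entity is maximally similar to itself).  Outputs lie in (0, 1].
    """
    if t < 1:
        raise ValidationError(f"t must be >= 1, got {t}")
    S = np.asarray(s_p.values, dtype=float)
    n = S.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        if others.size == 0:
            continue
        sims = S[i, others]
        # dense rank by descending similarity: highest value -> rank 1
        order = np.unique(-sims)          # ascending of negated = descending sims
        rank_of = {v: r + 1 for r, v in enumerate(order)}
        ranks = np.array([rank_of[-s] for s in sims], dtype=float)
        out[i, others] = (1.0 / ranks) ** (1.0 / t)
    return SimilarityMatrix(out, list(s_p.entity_ids), KIND_PROTEIN_TRANSFORMED)


def drug_relative_distance(s_r: SimilarityMatrix) -> np.ndarray:
    """RD = 1 - S_r; symmetric with zero diagonal."""
    if s_r.kind != KIND_DRUG_DICE:
        raise ValidationError(f"expected a {KIND_DRUG_DICE} matrix, got {s_r.kind}")
    rd = 1.0 - np.asarray(s_r.values, dtype=float)
    np.fill_diagonal(rd, 0.0)
    return rd


def protein_relative_distance(s_p_prime: SimilarityMatrix) -> np.ndarray:
    """RD = 1 - S_p'; zero diagonal, values in [0, 1)."""
    if s_p_prime.kind != KIND_PROTEIN_TRANSFORMED:
        raise ValidationError(
            f"expected a {KIND_PROTEIN_TRANSFORMED} matrix, got {s_p_prime.kind}"
        )
    rd = 1.0 - np.asarray(s_p_prime.values, dtype=float)
    np.fill_diagonal(rd, 0.0)
    return rd


def pair_relative_distance(interactions: InteractionSet,
                           drug_ids=None, protein_ids=None
                           ) -> dict[tuple[str, str], int]:
    """RD(d, p) = 1 - y over the labeled pairs only.

    Unlabeled pairs are deliberately absent (not treated as distance 1):
    the interaction loss runs over the training pair set of positives plus
    sampled negatives, never over all m*n pairs.
    """
    if drug_ids is not None and protein_ids is not None:
        interactions.resolve_against(drug_ids, protein_ids)
    return {(d, p): 1 - y for d, p, y in interactions.pairs}


@dataclass
class RelativeDistanceBundle:
    """RD matrices for drugs and proteins plus the labeled-pair RD map."""

    rd_drug: np.ndarray                       # m x m, symmetric, zero diag
    rd_protein: np.ndarray                    # n x n, zero diag (directed)
    rd_pair: dict[tuple[str, str], int]       # (drug_id, protein_id) -> {0,1}
    drug_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self):
        rd, rp = np.asarray(self.rd_drug), np.asarray(self.rd_protein)
        if rd.shape != (len(self.drug_ids),) * 2:
            raise ValidationError("rd_drug shape does not match drug_ids")
        if rp.shape != (len(self.protein_ids),) * 2:
            raise ValidationError("rd_protein shape does not match protein_ids")
        for M, name in ((rd, "rd_drug"), (rp, "rd_protein")):
            if np.any(M < 0) or np.any(M > 1):
                raise ValidationError(f"{name} values must lie in [0,1]")
            if np.any(np.diagonal(M) != 0):
                raise ValidationError(f"{name} diagonal must be zero")
        if not np.allclose(rd, rd.T):
            raise ValidationError("rd_drug must be symmetric")
        for v in self.rd_pair.values():
            if v not in (0, 1):
                raise ValidationError("rd_pair values must be 0 or 1")

    @property
    def drug_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}

    @property
    def protein_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.protein_ids)}


def build_bundle(s_r: SimilarityMatrix, s_p_raw: SimilarityMatrix,
                 interactions: InteractionSet, t: float) -> RelativeDistanceBundle:
    """Assemble the three relative-distance components with consistent
    entity orderings taken from the similarity matrices."""
    if s_p_raw.kind != KIND_PROTEIN_SW_RAW:
        raise ValidationError(
            f"expected a {KIND_PROTEIN_SW_RAW} matrix, got {s_p_raw.kind}"
        )
    rd_drug = drug_relative_distance(s_r)
    s_p_prime = rank_reciprocal_transform(s_p_raw, t)
    rd_protein = protein_relative_distance(s_p_prime)
    rd_pair = pair_relative_distance(interactions, s_r.entity_ids,
                                     s_p_raw.entity_ids)
    return RelativeDistanceBundle(
        rd_drug=rd_drug, rd_protein=rd_protein, rd_pair=rd_pair,
        drug_ids=list(s_r.entity_ids), protein_ids=list(s_p_raw.entity_ids),
    )
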