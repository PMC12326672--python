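"""Initial feature vectors and raw similarity matrices.

Drugs: Morgan fingerprints (radius 2, ECFP4-equivalent; 1024 bits by
default) and pairwise Dice similarity, giving the drug similarity network
S_r with values in [0, 1] and unit diagonal.

Proteins: Smith-Waterman local-alignment scores (BLOSUM62, affine gaps
open 10 / extend 1) give the raw similarity network S_p.  Raw scores are
never used directly downstream — only their within-row rank order matters,
so the substitution/gap choice affects ties only.  Feature vectors come
from a pluggable featurizer: a protein-language-model adapter (mean-pooled
per-residue embeddings, 1280-dim) when available, or a hashed k-mer
composition that needs no external model.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from gbadti.errors import FeaturizationError, ValidationError
from gbadti.io import AMINO_ALPHABET, DrugRecord, ProteinRecord

KIND_DRUG_DICE = "drug_dice"
KIND_PROTEIN_SW_RAW = "protein_sw_raw"
KIND_PROTEIN_TRANSFORMED = "protein_transformed"


@dataclass
class SimilarityMatrix:
    """Square pairwise-similarity matrix over an ordered entity list."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {self.values.shape}")
        if self.values.shape[0] != len(self.entity_ids):
            raise ValidationError("entity_ids length does not match matrix size")
        if self.kind == KIND_DRUG_DICE:
            if not np.allclose(self.values, self.values.T):
                raise ValidationError("drug Dice similarity matrix must be symmetric")
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValidationError("drug Dice similarities must lie in [0,1]")
        elif self.kind == KIND_PROTEIN_SW_RAW:
            if np.any(self.values < 0):
                raise ValidationError("Smith-Waterman scores must be non-negative")


# ---------------------------------------------------------------------------
# drugs
# ---------------------------------------------------------------------------

def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024,
                       drug_id: str | None = None) -> np.ndarray:
    """Binary Morgan (circular) fingerprint of a SMILES string."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(
            f"unparseable SMILES {smiles!r}"
            + (f" for drug {drug_id!r}" if drug_id else ""),
            entity_id=drug_id,
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|a∧b| / (|a|+|b|) of two equal-length bit vectors.

    Two all-zero vectors share nothing with anything: returns 0 with a
    warning (an all-zero fingerprint usually signals a featurization
    problem upstream).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError(f"bit vectors differ in length: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice similarity of two all-zero bit vectors; returning 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def drug_features(drugs: list[DrugRecord], radius: int = 2,
                  n_bits: int = 1024) -> np.ndarray:
    """Stack fingerprints (or precomputed features) for a drug list."""
    rows = []
    for d in drugs:
        if d.features is not None:
            rows.append(np.asarray(d.features, dtype=float))
        else:
            rows.append(morgan_fingerprint(d.smiles, radius, n_bits,
                                           drug_id=d.drug_id).astype(float))
    out = np.vstack(rows)
    if len({r.shape for r in map(np.asarray, rows)}) > 1:
        raise ValidationError("drug feature vectors have inconsistent lengths")
    return out


def drug_similarity_matrix(drugs: list[DrugRecord], radius: int = 2,
                           n_bits: int = 1024) -> SimilarityMatrix:
    """m x m Dice similarity of drug fingerprints; symmetric, unit diagonal."""
    X = drug_features(drugs, radius, n_bits)
    B = X > 0
    counts = B.sum(axis=1).astype(float)
    inter = (B.astype(np.int64) @ B.T.astype(np.int64)).astype(float)
    denom = counts[:, None] + counts[None, :]
    if np.any(counts == 0):
        warnings.warn("all-zero fingerprint(s) present; their Dice rows are 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, np.where(counts > 0, 1.0, 0.0))
    # all-zero fingerprints: define self-similarity 1 so diag invariant holds
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, [d.drug_id for d in drugs], KIND_DRUG_DICE)


# ---------------------------------------------------------------------------
# proteins: Smith-Waterman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentParams:
    """Local-alignment scoring scheme (affine: gap of length L costs
    gap_open + (L-1) * gap_extend)."""
    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1


def smith_waterman_score(seq_a: str, seq_b: str,
                         params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal local-alignment score of two protein sequences (>= 0)."""
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    if params.matrix != "BLOSUM62":
        raise ValidationError(f"unsupported substitution matrix {params.matrix!r}")
    mat = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62
    alns = align_optimal(
        ProteinSequence(seq_a), ProteinSequence(seq_b), mat,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=True, max_number=1,
    )
    score = alns[0].score if alns else 0
    return float(max(score, 0))


def protein_similarity_matrix(proteins: list[ProteinRecord],
                              params: AlignmentParams = AlignmentParams()
                              ) -> SimilarityMatrix:
    """n x n Smith-Waterman score matrix; symmetric, non-negative diagonal
    holds each sequence's self-score."""
    for p in proteins:
        if p.sequence is None:
            raise ValidationError(f"protein {p.protein_id!r} has no sequence")
    n = len(proteins)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = smith_waterman_score(proteins[i].sequence, proteins[j].sequence,
                                     params)
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(S, [p.protein_id for p in proteins],
                            KIND_PROTEIN_SW_RAW)


def feature_similarity_matrix(features: np.ndarray, ids: list[str]
                              ) -> SimilarityMatrix:
    """Raw protein similarity from feature vectors (cosine similarity).

    Used when proteins carry precomputed/synthetic feature vectors instead
    of sequences.  Only the within-row order matters downstream (the rank
    transform discards scale), so any monotone similarity works here; shift
    to [0, 2] to keep the non-negativity contract.
    """
    X = np.asarray(features, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("zero-norm feature vector in similarity computation")
    U = X / norms
    S = U @ U.T + 1.0  # cosine in [-1,1] shifted to [0,2]
    return SimilarityMatrix(S, list(ids), KIND_PROTEIN_SW_RAW)


# ---------------------------------------------------------------------------
# protein feature vectors
# ---------------------------------------------------------------------------

_KMER_ALPHABET = AMINO_ALPHABET + "X"
_KMER_INDEX = {c: i for i, c in enumerate(_KMER_ALPHABET)}


def kmer_features(sequence: str, k: int = 3, d_t: int = 1280) -> np.ndarray:
    """L1-normalized k-mer composition, direct-indexed when the k-mer space
    fits in d_t and CRC32-hashed otherwise.  Deterministic per (sequence, k,
    d_t); similar sequences map to similar vectors."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(sequence) < k:
        raise ValidationError(f"sequence shorter than k={k}")
    v = np.zeros(d_t)
    n_symbols = len(_KMER_ALPHABET)
    direct = n_symbols ** k <= d_t
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i:i + k]
        if direct:
            idx = 0
            for c in kmer:
                idx = idx * n_symbols + _KMER_INDEX.get(c, _KMER_INDEX["X"])
        else:
            idx = zlib.crc32(kmer.encode()) % d_t
        v[idx] += 1.0
    total = v.sum()
    return v / total


class PLMAdapter:
    """Adapter for a pre-trained protein language model (mean-pooled
    per-residue embeddings).

    Requires the model weights and a deep-learning runtime, neither of which
    this package bundles; constructing one without them raises with a
    pointer to the k-mer featurizer and the precomputed-features path.
    """

    def __init__(self, name: str = "esm2_t33_650M_UR50D", pooling: str = "mean"):
        self.name = name
        self.pooling = pooling
        try:
            import esm  # noqa: F401
        except ImportError as exc:
            raise FeaturizationError(
                f"protein language model {name!r} is unavailable in this "
                "environment; use the k-mer featurizer (protein_features with "
                "kind='kmer') or supply precomputed feature vectors"
            ) from exc


@dataclass(frozen=True)
class FeaturizerSpec:
    """Which featurizers produce D0 and P0 and at what dimensions."""
    drug_radius: int = 2
    d_m: int = 1024
    protein_kind: str = "kmer"   # {"kmer", "plm"}
    kmer_k: int = 3
    d_t: int = 1280
    plm_name: str = "esm2_t33_650M_UR50D"
    plm_pooling: str = "mean"


def protein_features(record: ProteinRecord,
                     spec: FeaturizerSpec = FeaturizerSpec()) -> np.ndarray:
    """Feature vector of length d_t for one protein."""
    if record.features is not None:
        f = np.asarray(record.features, dtype=float)
        if f.shape != (spec.d_t,):
            raise ValidationError(
                f"protein {record.protein_id!r}: precomputed features have "
                f"length {f.shape}, expected ({spec.d_t},)"
            )
        return f
    if record.sequence is None:
        raise ValidationError(f"protein {record.protein_id!r} has neither "
                              "sequence nor features")
    if spec.protein_kind == "kmer":
        return kmer_features(record.sequence, spec.kmer_k, spec.d_t)
    if spec.protein_kind == "plm":
        adapter = PLMAdapter(spec.plm_name, spec.plm_pooling)
        raise FeaturizationError("PLM adapter loaded but embedding is not "
                                 "implemented offline")  # pragma: no cover
    raise ValidationError(f"unknown protein featurizer kind {spec.protein_kind!r}")


def protein_feature_matrix(proteins: list[ProteinRecord],
                           spec: FeaturizerSpec = FeaturizerSpec()) -> np.ndarray:
    return np.vstack([protein_features(p, spec) for p in proteins])
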