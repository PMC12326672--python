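"""Planted-structure synthetic datasets.

The generator emulates the one statistical property the guilt-by-
association prior exploits: similar drugs interact with similar proteins.
Drugs fall into K clusters, each with a binary fingerprint template whose
copies receive independent bit flips; proteins fall into L clusters as
Gaussian perturbations of cluster centers (block model) or as point-mutated
copies of a cluster ancestor sequence (sequence model).  A cluster
interaction matrix B in {0,1}^{K x L} decides which (drug cluster, protein
cluster) blocks interact; individual labels follow B with an optional flip
(label-noise) rate.

Everything is deterministic per seed.  What this does NOT emulate: real
chemical space, binding-affinity structure, degree heterogeneity of real
interaction networks, or homology structure beyond single-ancestor
families — tests passing on these fixtures show the machinery recovers
planted block structure, not performance on benchmark data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from gbadti.errors import ValidationError
from gbadti.io import AMINO_ALPHABET, DrugRecord, InteractionSet, ProteinRecord


@dataclass
class BlockModelSpec:
    """Configuration of the planted block model.

    Defaults give the desk-scale study condition used throughout the test
    suite: 200 drugs x 100 proteins in 4x4 clusters with low noise.
    """

    n_drug_clusters: int = 4
    n_protein_clusters: int = 4
    drugs_per_cluster: int = 50
    proteins_per_cluster: int = 25
    interaction_blocks: np.ndarray | None = None   # K x L over {0,1}; default identity
    d_m: int = 64                   # fingerprint length
    d_t: int = 32                   # protein feature length
    template_density: float = 0.25  # fraction of bits set in a cluster template
    bit_flip_rate: float = 0.02     # per-bit flip probability within a cluster
    center_spread: float = 1.0      # std of protein cluster centers
    feature_noise: float = 0.1      # within-cluster protein feature noise std
    label_noise: float = 0.01       # per-pair label flip probability
    seed: int = 0

    def __post_init__(self):
        if self.interaction_blocks is None:
            K, L = self.n_drug_clusters, self.n_protein_clusters
            self.interaction_blocks = np.eye(K, L, dtype=int)
        self.interaction_blocks = np.asarray(self.interaction_blocks, dtype=int)
        K, L = self.n_drug_clusters, self.n_protein_clusters
        if self.interaction_blocks.shape != (K, L):
            raise ValidationError(f"interaction_blocks must be {K}x{L}")
        B = self.interaction_blocks
        if not (B.min() >= 0 and B.max() <= 1):
            raise ValidationError("interaction_blocks must be binary")
        if B.sum() == 0 or B.sum() == B.size:
            raise ValidationError("interaction_blocks needs at least one 1 and one 0")
        for name in ("bit_flip_rate", "label_noise"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValidationError(f"{name} must lie in [0, 0.5), got {v}")
        if self.drugs_per_cluster < 1 or self.proteins_per_cluster < 1:
            raise ValidationError("every cluster must be non-empty")


@dataclass
class SyntheticDataset:
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    interactions: InteractionSet            # positives only
    drug_clusters: np.ndarray
    protein_clusters: np.ndarray
    all_labels: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def drug_features(self) -> np.ndarray:
        return np.vstack([d.features for d in self.drugs])

    @property
    def protein_features(self) -> np.ndarray:
        return np.vstack([p.features for p in self.proteins])

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]


def generate_block_dataset(spec: BlockModelSpec) -> SyntheticDataset:
    """Sample a planted-block dataset: clustered bit-vector drugs, clustered
    Gaussian-feature proteins, and block-determined positive pairs."""
    rng = np.random.default_rng(spec.seed)
    K, L = spec.n_drug_clusters, spec.n_protein_clusters
    m = K * spec.drugs_per_cluster
    n = L * spec.proteins_per_cluster

    templates = (rng.random((K, spec.d_m)) < spec.template_density).astype(np.uint8)
    drug_clusters = np.repeat(np.arange(K), spec.drugs_per_cluster)
    flips = rng.random((m, spec.d_m)) < spec.bit_flip_rate
    fingerprints = templates[drug_clusters] ^ flips.astype(np.uint8)
    drugs = [DrugRecord(drug_id=f"d{i:04d}", features=fingerprints[i].astype(float))
             for i in range(m)]

    centers = rng.normal(0.0, spec.center_spread, size=(L, spec.d_t))
    protein_clusters = np.repeat(np.arange(L), spec.proteins_per_cluster)
    feats = centers[protein_clusters] + rng.normal(
        0.0, spec.feature_noise, size=(n, spec.d_t))
    proteins = [ProteinRecord(protein_id=f"p{j:04d}", features=feats[j])
                for j in range(n)]

    B = spec.interaction_blocks
    base = B[drug_clusters][:, protein_clusters].astype(int)   # m x n
    flips = rng.random((m, n)) < spec.label_noise
    labels = base ^ flips.astype(int)
    pos_i, pos_j = np.nonzero(labels)
    if pos_i.size == 0:
        raise ValidationError("spec produced zero positive pairs")
    positives = InteractionSet(pairs=[
        (drugs[i].drug_id, proteins[j].protein_id, 1)
        for i, j in zip(pos_i.tolist(), pos_j.tolist())
    ])
    all_labels = {(drugs[i].drug_id, proteins[j].protein_id): int(labels[i, j])
                  for i in range(m) for j in range(n)}
    return SyntheticDataset(drugs, proteins, positives,
                            drug_clusters, protein_clusters, all_labels)


def generate_sequence_dataset(spec: BlockModelSpec, ancestor_length: int = 120,
                              mutation_rate: float = 0.05,
                              alphabet: str = AMINO_ALPHABET) -> SyntheticDataset:
    """Block dataset whose proteins are SEQUENCES: each cluster descends from
    an independent random ancestor by i.i.d. point mutations, exercising the
    Smith-Waterman / rank-transform path end to end."""
    if not 0 <= mutation_rate < 0.5:
        raise ValidationError("mutation_rate must lie in [0, 0.5)")
    if ancestor_length < 20:
        raise ValidationError("ancestor_length must be >= 20")
    base = generate_block_dataset(spec)
    rng = np.random.default_rng(spec.seed + 101)
    L = spec.n_protein_clusters
    letters = np.array(list(alphabet))
    ancestors = [letters[rng.integers(0, len(letters), size=ancestor_length)]
                 for _ in range(L)]
    proteins = []
    for j, cluster in enumerate(base.protein_clusters):
        seq = ancestors[cluster].copy()
        mut = rng.random(ancestor_length) < mutation_rate
        seq[mut] = letters[rng.integers(0, len(letters), size=int(mut.sum()))]
        proteins.append(ProteinRecord(protein_id=base.proteins[j].protein_id,
                                      sequence="".join(seq),
                                      features=base.proteins[j].features))
    return SyntheticDataset(base.drugs, proteins, base.interactions,
                            base.drug_clusters, base.protein_clusters,
                            base.all_labels)


# ---------------------------------------------------------------------------
# canonical tiny fixture (checked-in files)
# ---------------------------------------------------------------------------

FIXTURE_SPEC = BlockModelSpec(
    n_drug_clusters=2, n_protein_clusters=2,
    drugs_per_cluster=3, proteins_per_cluster=3,
    d_m=64, d_t=32, bit_flip_rate=0.0, feature_noise=0.05,
    label_noise=0.0, seed=7,
)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write a synthetic dataset as plain-text TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from gbadti.io import write_interaction_edges, write_matrix
    write_matrix(ds.drug_features.astype(int), ds.drug_ids,
                 [f"b{k}" for k in range(ds.drug_features.shape[1])],
                 outdir / "drug_features.tsv")
    write_matrix(np.round(ds.protein_features, 6), ds.protein_ids,
                 [f"f{k}" for k in range(ds.protein_features.shape[1])],
                 outdir / "protein_features.tsv")
    write_interaction_edges(ds.interactions, outdir / "edges.tsv")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("entity_id\tkind\tcluster\n")
        for did, c in zip(ds.drug_ids, ds.drug_clusters):
            fh.write(f"{did}\tdrug\t{c}\n")
        for pid, c in zip(ds.protein_ids, ds.protein_clusters):
            fh.write(f"{pid}\tprotein\t{c}\n")


def load_dataset(indir: str | Path) -> SyntheticDataset:
    from gbadti.io import read_interaction_edges, read_matrix
    indir = Path(indir)
    Xd, drug_ids, _ = read_matrix(indir / "drug_features.tsv")
    Xp, protein_ids, _ = read_matrix(indir / "protein_features.tsv")
    inter = read_interaction_edges(indir / "edges.tsv")
    dclu, pclu = {}, {}
    with open(indir / "clusters.tsv") as fh:
        next(fh)
        for line in fh:
            eid, kind, c = line.split()
            (dclu if kind == "drug" else pclu)[eid] = int(c)
    drugs = [DrugRecord(drug_id=d, features=Xd[i]) for i, d in enumerate(drug_ids)]
    proteins = [ProteinRecord(protein_id=p, features=Xp[j])
                for j, p in enumerate(protein_ids)]
    return SyntheticDataset(
        drugs, proteins, inter,
        np.array([dclu[d] for d in drug_ids]),
        np.array([pclu[p] for p in protein_ids]),
    )


def fixture_small() -> SyntheticDataset:
    """The canonical checked-in tiny dataset (6 drugs, 6 proteins, 2x2
    blocks) shared across the test suite; loaded from packaged files."""
    with resources.as_file(resources.files("gbadti") / "data" / "fixture_small") as p:
        return load_dataset(p)
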