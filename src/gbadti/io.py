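"""Readers and writers for the on-disk formats the pipeline touches.

TSV is the canonical dialect for drug tables, edge lists, matrices and
predictions (SMILES may contain commas in extensions; tabs are safer); CSV
is accepted where a dialect flag exists.  Proteins travel as FASTA.  All
readers accept LF and CRLF line endings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from gbadti.errors import FormatError, ValidationError

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DrugRecord:
    """A drug: opaque id plus a SMILES string and/or a precomputed feature vector."""

    drug_id: str
    smiles: str | None = None
    features: np.ndarray | None = None

    def __post_init__(self):
        if not self.drug_id:
            raise ValidationError("drug_id must be non-empty")
        if self.smiles is None and self.features is None:
            raise ValidationError(
                f"drug {self.drug_id!r}: need at least one of smiles/features"
            )


@dataclass
class ProteinRecord:
    """A protein: opaque id plus an amino-acid sequence and/or a feature vector."""

    protein_id: str
    sequence: str | None = None
    features: np.ndarray | None = None

    def __post_init__(self):
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.sequence is None and self.features is None:
            raise ValidationError(
                f"protein {self.protein_id!r}: need at least one of sequence/features"
            )


@dataclass
class InteractionSet:
    """Deduplicated labeled (drug, protein) pairs with distinct-entity counts."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[tuple[str, str], int] = {}
        for d, p, y in self.pairs:
            if y not in (0, 1):
                raise ValidationError(f"label for ({d},{p}) must be 0 or 1, got {y!r}")
            if (d, p) in seen and seen[(d, p)] != y:
                raise ValidationError(
                    f"conflicting labels for pair ({d},{p}): {seen[(d, p)]} vs {y}"
                )
            seen[(d, p)] = y
        # keep first-occurrence order, duplicates collapsed
        dedup, emitted = [], set()
        for d, p, y in self.pairs:
            if (d, p) not in emitted:
                dedup.append((d, p, int(y)))
                emitted.add((d, p))
        self.pairs = dedup

    @property
    def m(self) -> int:
        return len({d for d, _, _ in self.pairs})

    @property
    def n(self) -> int:
        return len({p for _, p, _ in self.pairs})

    @property
    def drug_ids(self) -> list[str]:
        out, seen = [], set()
        for d, _, _ in self.pairs:
            if d not in seen:
                out.append(d)
                seen.add(d)
        return out

    @property
    def protein_ids(self) -> list[str]:
        out, seen = [], set()
        for _, p, _ in self.pairs:
            if p not in seen:
                out.append(p)
                seen.add(p)
        return out

    def positives(self) -> list[tuple[str, str]]:
        return [(d, p) for d, p, y in self.pairs if y == 1]

    def negatives(self) -> list[tuple[str, str]]:
        return [(d, p) for d, p, y in self.pairs if y == 0]

    def __len__(self) -> int:
        return len(self.pairs)

    def resolve_against(self, drug_ids, protein_ids) -> None:
        """Check every edge id against the entity tables."""
        dset, pset = set(drug_ids), set(protein_ids)
        for d, p, _ in self.pairs:
            if d not in dset:
                raise ValidationError(f"edge references unknown drug id {d!r}")
            if p not in pset:
                raise ValidationError(f"edge references unknown protein id {p!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def read_drug_table(path: str | Path, dialect: str = "tsv") -> list[DrugRecord]:
    """Read a drug table with an id column and a smiles column.

    Column names are matched case-insensitively against {drug_id, id} and
    {smiles}.  Duplicate ids are rejected.
    """
    sep = _SEPS.get(dialect)
    if sep is None:
        raise ValidationError(f"dialect must be tsv or csv, got {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("drug_id") or cols.get("id")
    smiles_col = cols.get("smiles")
    if id_col is None or smiles_col is None:
        raise FormatError(
            f"{path}: need an id column (drug_id/id) and a smiles column; "
            f"found {list(df.columns)}"
        )
    records, seen = [], set()
    for _, row in df.iterrows():
        did = row[id_col].strip()
        if did in seen:
            raise ValidationError(f"{path}: duplicate drug_id {did!r}")
        seen.add(did)
        records.append(DrugRecord(drug_id=did, smiles=row[smiles_col].strip()))
    return records


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; the header token before whitespace is the id.

    Sequences are uppercased and line wrapping removed.  Characters outside
    the 20-letter alphabet plus X trigger a warning but are retained.
    """
    records, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        pid = rec.id
        if not seq:
            raise ValidationError(f"{path}: protein {pid!r} has an empty sequence")
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        unknown = set(seq) - set(AMINO_ALPHABET) - {"X"}
        if unknown:
            warnings.warn(
                f"protein {pid!r} contains non-standard residues "
                f"{sorted(unknown)}; retained as-is"
            )
        records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records


def read_interaction_edges(path: str | Path, dialect: str = "tsv") -> InteractionSet:
    """Read a 3-column (drug_id, protein_id, label) edge list.

    Exact duplicates are collapsed; conflicting labels for the same pair
    raise; labels must parse to 0/1.
    """
    sep = _SEPS.get(dialect)
    if sep is None:
        raise ValidationError(f"dialect must be tsv or csv, got {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    try:
        d_col, p_col, y_col = cols["drug_id"], cols["protein_id"], cols["label"]
    except KeyError:
        raise FormatError(
            f"{path}: need columns drug_id, protein_id, label; found {list(df.columns)}"
        ) from None
    pairs = []
    for _, row in df.iterrows():
        raw = row[y_col].strip()
        if raw not in ("0", "1"):
            raise FormatError(f"{path}: label {raw!r} for "
                              f"({row[d_col]},{row[p_col]}) is not 0/1")
        pairs.append((row[d_col].strip(), row[p_col].strip(), int(raw)))
    return InteractionSet(pairs=pairs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_interaction_edges(interactions: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\tlabel\n")
        for d, p, y in interactions.pairs:
            fh.write(f"{d}\t{p}\t{y}\n")


def write_predictions(table: list[tuple[str, str, float]], path: str | Path) -> None:
    """Write scored (drug_id, protein_id, score) triples as TSV.

    Rows are sorted by descending score, ties broken lexicographically by
    (drug_id, protein_id); scores are printed with 6 decimals.
    """
    if not table:
        raise ValidationError("prediction table is empty")
    rows = sorted(table, key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\tscore\n")
        for d, p, s in rows:
            fh.write(f"{d}\t{p}\t{s:.6f}\n")


def read_predictions(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "protein_id": str})
    return [(r.drug_id, r.protein_id, float(r.score)) for r in df.itertuples()]


def write_matrix(values: np.ndarray, row_ids, col_ids, path: str | Path) -> None:
    """Write a labeled matrix (similarity/feature) as TSV with id headers."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep="\t", index_label="id")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
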