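"""Data model and I/O for drug-target affinity (DTA) datasets.

A dataset is a bipartite collection: a registry of drugs (SMILES strings), a
registry of proteins (amino-acid sequences), and an ordered list of observed
(drug, protein, affinity) triples.  Affinities live on a transformed scale --
pKd for Kd-type data (``pkd_transform``), or an integrated bioactivity score
(KIBA-style) passed through unchanged.

Readers accept two table dialects:

``generic_csv``
    Columns ``drug_id, smiles, protein_id, sequence, label``.
``tdc_dti``
    The Therapeutics Data Commons DTI layout:
    ``Drug_ID, Drug, Target_ID, Target, Y``.

Delimiter is sniffed from the file extension (``.tsv`` -> tab, else comma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Drug",
    "Protein",
    "DTAPair",
    "DTADataset",
    "DatasetStats",
    "SchemaError",
    "DuplicatePairError",
    "LabelParseError",
    "DimensionMismatchError",
    "UndefinedStatisticError",
    "read_affinity_table",
    "write_affinity_table",
    "load_fasta_sequences",
    "pkd_transform",
    "dataset_stats",
    "read_embedding_archive",
    "write_embedding_archive",
    "DIALECT_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing from an affinity table."""


class DuplicatePairError(ValueError):
    """The same (drug, protein) combination appears on more than one row."""


class LabelParseError(ValueError):
    """A label cell does not parse as a finite real number."""


class DimensionMismatchError(ValueError):
    """Embedding matrices in one archive disagree on their width."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested on a dataset for which it is undefined."""


@dataclass(frozen=True)
class Drug:
    id: str
    smiles: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("drug id must be non-empty")


@dataclass(frozen=True)
class Protein:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class DTAPair:
    drug_id: str
    protein_id: str
    label: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.label):
            raise ValueError(
                f"pair ({self.drug_id}, {self.protein_id}): label must be finite"
            )


@dataclass
class DTADataset:
    """Registries of entities plus the ordered list of observed pairs."""

    drugs: dict[str, Drug] = field(default_factory=dict)
    proteins: dict[str, Protein] = field(default_factory=dict)
    pairs: list[DTAPair] = field(default_factory=list)
    label_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for k, p in enumerate(self.pairs):
            if p.drug_id not in self.drugs:
                raise ValueError(f"pair {k}: unregistered drug {p.drug_id!r}")
            if p.protein_id not in self.proteins:
                raise ValueError(f"pair {k}: unregistered protein {p.protein_id!r}")
            key = (p.drug_id, p.protein_id)
            if key in seen:
                raise DuplicatePairError(f"duplicate pair {key} at index {k}")
            seen.add(key)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.pairs)


DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    # canonical role -> column name in the file
    "generic_csv": {
        "drug_id": "drug_id",
        "smiles": "smiles",
        "protein_id": "protein_id",
        "sequence": "sequence",
        "label": "label",
    },
    "tdc_dti": {
        "drug_id": "Drug_ID",
        "smiles": "Drug",
        "protein_id": "Target_ID",
        "sequence": "Target",
        "label": "Y",
    },
}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_affinity_table(
    path: str | Path,
    dialect: str = "generic_csv",
    columns: Mapping[str, str] | None = None,
    fasta: str | Path | None = None,
) -> DTADataset:
    """Read an affinity table into a :class:`DTADataset`.

    Parameters
    ----------
    path
        CSV/TSV file with one observed drug-protein pair per row.
    dialect
        ``generic_csv`` or ``tdc_dti`` (see :data:`DIALECT_COLUMNS`).
    columns
        Optional role -> column-name overrides on top of the dialect.
    fasta
        Optional FASTA file supplying protein sequences; record ids must
        match the table's protein ids.  Sequences from the FASTA take
        precedence over (possibly empty) table cells.
    """
    path = Path(path)
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = dict(DIALECT_COLUMNS[dialect])
    if columns:
        colmap.update(columns)

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    fasta_seqs = load_fasta_sequences(fasta) if fasta is not None else {}

    drugs: dict[str, Drug] = {}
    proteins: dict[str, Protein] = {}
    pairs: list[DTAPair] = []
    seen: dict[tuple[str, str], int] = {}
    for row_no, row in enumerate(df.to_dict("records"), start=2):  # row 1 = header
        rec = {role: row[col] for role, col in colmap.items()}
        try:
            label = float(rec["label"])
        except ValueError as exc:
            raise LabelParseError(
                f"{path.name} row {row_no}: cannot parse label {rec['label']!r}"
            ) from exc
        if not math.isfinite(label):
            raise LabelParseError(f"{path.name} row {row_no}: non-finite label")
        d_id, p_id = rec["drug_id"], rec["protein_id"]
        key = (d_id, p_id)
        if key in seen:
            raise DuplicatePairError(
                f"{path.name}: pair {key} duplicated on rows {seen[key]} and {row_no}"
            )
        seen[key] = row_no
        if d_id not in drugs:
            drugs[d_id] = Drug(id=d_id, smiles=rec["smiles"])
        seq = fasta_seqs.get(p_id, rec["sequence"])
        if p_id not in proteins:
            proteins[p_id] = Protein(id=p_id, sequence=seq)
        pairs.append(DTAPair(drug_id=d_id, protein_id=p_id, label=label))

    return DTADataset(drugs=drugs, proteins=proteins, pairs=pairs)


def write_affinity_table(ds: DTADataset, path: str | Path) -> None:
    """Write a dataset in the ``generic_csv`` dialect (round-trips exactly)."""
    path = Path(path)
    rows = [
        {
            "drug_id": p.drug_id,
            "smiles": ds.drugs[p.drug_id].smiles,
            "protein_id": p.protein_id,
            "sequence": ds.proteins[p.protein_id].sequence,
            # repr of a Python float round-trips float64 exactly
            "label": repr(float(p.label)),
        }
        for p in ds.pairs
    ]
    cols = list(DIALECT_COLUMNS["generic_csv"].values())
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False)


def load_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def pkd_transform(kd_nanomolar, cap_nanomolar: float = 10_000.0):
    """Harmonize a dissociation constant (nM) to the pKd scale.

    Values are capped at ``cap_nanomolar`` before the log transform, so the
    result has a hard floor at ``-log10(cap * 1e-9)`` -- with the default
    10 uM cap that floor is exactly 5.0, the pile-up value seen in
    Kd-type kinase panels.

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    kd = np.asarray(kd_nanomolar, dtype=np.float64)
    if np.any(kd <= 0) or cap_nanomolar <= 0:
        raise ValueError("Kd and cap must be strictly positive (nanomolar)")
    out = -np.log10(np.minimum(kd, cap_nanomolar) * 1e-9)
    return float(out) if np.isscalar(kd_nanomolar) else out


@dataclass(frozen=True)
class DatasetStats:
    n_pairs: int
    n_drugs: int
    n_proteins: int
    frac_in_range: float
    label_min: float
    label_max: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_drugs": self.n_drugs,
            "n_proteins": self.n_proteins,
            "frac_in_range": self.frac_in_range,
            "label_min": self.label_min,
            "label_max": self.label_max,
        }


def dataset_stats(ds: DTADataset, lo: float, hi: float) -> DatasetStats:
    """Counts plus the fraction of labels inside the closed interval [lo, hi].

    The in-range fraction is the label-concentration statistic used to
    quantify sparsity of an affinity panel (e.g. the share of a Kd panel
    sitting in the overpopulated low-affinity band).
    """
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    if ds.n_pairs == 0:
        raise UndefinedStatisticError("frac_in_range is undefined on an empty dataset")
    y = ds.labels()
    frac = float(np.mean((y >= lo) & (y <= hi)))
    return DatasetStats(
        n_pairs=ds.n_pairs,
        n_drugs=len(ds.drugs),
        n_proteins=len(ds.proteins),
        frac_in_range=frac,
        label_min=float(y.min()),
        label_max=float(y.max()),
    )


def read_embedding_archive(path: str | Path) -> dict[str, np.ndarray]:
    """Read an HDF5 archive of per-entity token-embedding matrices.

    Every dataset in the file must be a 2-D real array of shape
    ``(T_entity, d)`` with a single shared width ``d`` across entities.
    """
    out: dict[str, np.ndarray] = {}
    d: int | None = None
    with h5py.File(path, "r") as f:
        for key in f.keys():
            arr = np.asarray(f[key], dtype=np.float64)
            if arr.ndim != 2:
                raise DimensionMismatchError(
                    f"entry {key!r}: expected a 2-D array, got ndim={arr.ndim}"
                )
            if d is None:
                d = arr.shape[1]
            elif arr.shape[1] != d:
                raise DimensionMismatchError(
                    f"entry {key!r}: width {arr.shape[1]} != {d} of earlier entries"
                )
            out[key] = arr
    return out


def write_embedding_archive(
    path: str | Path, matrices: Mapping[str, np.ndarray]
) -> None:
    with h5py.File(path, "w") as f:
        for key, arr in matrices.items():
            f.create_dataset(key, data=np.asarray(arr, dtype=np.float64))
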