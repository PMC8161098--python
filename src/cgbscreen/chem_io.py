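"""Readers and writers for the formats the screening pipeline touches.

Compounds arrive as SMILES (``.smi``) or SDF, protein targets as FASTA,
compound-protein interaction (CPI) labels as TSV, and intermediate
score matrices as CSV with id headers. All readers preserve input order
and all round trips are exact (ids) or exact-to-float-repr (values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

#: the 20 standard amino-acid one-letter codes
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: ambiguity / nonstandard letters that are dropped on ingest
NONSTANDARD_AA = set("BJOUXZ")


class EmptyInputError(ValueError):
    """A file parsed cleanly but yielded zero usable records."""


class DuplicateIdError(ValueError):
    """Two records share an identifier that must be unique."""


class MatrixCorruptionError(ValueError):
    """A persisted matrix failed its shape/id consistency checks."""


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string; raises ``ValueError`` if unparsable.

    Canonicalization is idempotent: ``canonical_smiles(canonical_smiles(s))
    == canonical_smiles(s)``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Compound:
    """A small molecule with a stable id and canonical SMILES."""

    id: str
    smiles: str
    name: str | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # cannot happen for instances built via from_smiles
            raise ValueError(f"compound {self.id}: invalid SMILES {self.smiles!r}")
        return m

    @classmethod
    def from_smiles(cls, id: str, smiles: str, name: str | None = None) -> "Compound":
        if not id:
            raise ValueError("compound id must be non-empty")
        return cls(id=id, smiles=canonical_smiles(smiles), name=name)


@dataclass(frozen=True)
class ProteinTarget:
    """A protein target identified by id, with a sanitized sequence.

    The sequence is restricted to the 20 standard letters; descriptor
    code relies on that alphabet being exact. Sequences shorter than 30
    residues are rejected because the distribution descriptor needs
    enough positions for its quantiles to be meaningful.
    """

    id: str
    sequence: str

    MIN_LENGTH = 30

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("target id must be non-empty")
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"target {self.id}: nonstandard letters {sorted(bad)}")
        if len(self.sequence) < self.MIN_LENGTH:
            raise ValueError(
                f"target {self.id}: sequence length {len(self.sequence)} < "
                f"{self.MIN_LENGTH}"
            )


@dataclass(frozen=True)
class CPIRecord:
    """One labelled compound-protein pair: 1 = binding, 0 = non-binding."""

    compound_id: str
    target_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class FingerprintMatrix:
    """Dense matrix of binding-probability scores, rows=compounds, cols=targets."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.row_ids)}, {len(self.col_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        _check_unique(self.row_ids, "row id")
        _check_unique(self.col_ids, "column id")

    def row(self, compound_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(compound_id)]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate {what}: {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# molecule input


def read_molecules(path: str | Path, format: str | None = None) -> list[Compound]:
    """Read compounds from a ``.smi`` or SDF file, preserving input order.

    ``.smi`` lines are whitespace-separated ``SMILES id`` (id optional; a
    positional id ``mol<K>`` is assigned when missing). Records whose
    structure does not parse are skipped with a logged warning; duplicate
    ids raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smi"
    if format not in ("smi", "sdf"):
        raise ValueError(f"unsupported format {format!r}")

    compounds: list[Compound] = []
    n_skipped = 0
    RDLogger.DisableLog("rdApp.error")
    try:
        if format == "smi":
            for k, line in enumerate(path.read_text().splitlines()):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                cid = parts[1].strip() if len(parts) > 1 else f"mol{k + 1}"
                try:
                    compounds.append(Compound.from_smiles(cid, smiles))
                except ValueError:
                    n_skipped += 1
                    logger.warning("skipping unparsable SMILES record %r", line)
        else:
            supplier = Chem.SDMolSupplier(str(path), sanitize=True)
            for k, mol in enumerate(supplier):
                if mol is None:
                    n_skipped += 1
                    logger.warning("skipping unreadable SDF record %d", k + 1)
                    continue
                cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
                cid = cid or f"mol{k + 1}"
                compounds.append(Compound(id=cid, smiles=Chem.MolToSmiles(mol)))
    finally:
        RDLogger.EnableLog("rdApp.error")

    _check_unique([c.id for c in compounds], "compound id")
    if not compounds:
        raise EmptyInputError(f"no valid molecules in {path}")
    if n_skipped:
        logger.warning("%s: skipped %d invalid record(s)", path, n_skipped)
    return compounds


def write_molecules(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write compounds as a ``.smi`` file (``SMILES id`` per line)."""
    with open(path, "w") as fh:
        for c in compounds:
            fh.write(f"{c.smiles} {c.id}\n")


# ---------------------------------------------------------------------------
# protein input


def read_fasta(path: str | Path) -> list[ProteinTarget]:
    """Read protein targets from FASTA, in file order.

    The id is the header token up to the first whitespace. Sequences are
    uppercased; nonstandard letters (B, J, O, U, X, Z) and gaps are
    dropped with a logged count, which keeps the 20-letter descriptor
    algebra exact.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    targets: list[ProteinTarget] = []
    for rec in records:
        seq = str(rec.seq).upper()
        kept = "".join(ch for ch in seq if ch in STANDARD_AA)
        n_dropped = len(seq) - len(kept)
        if n_dropped:
            logger.warning("%s: dropped %d nonstandard position(s)", rec.id, n_dropped)
        targets.append(ProteinTarget(id=rec.id, sequence=kept))
    _check_unique([t.id for t in targets], "target id")
    return targets


def write_fasta(targets: Iterable[ProteinTarget], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CPI tables


def read_cpi_table(
    path: str | Path,
    compounds: Sequence[Compound] | None = None,
    targets: Sequence[ProteinTarget] | None = None,
) -> list[CPIRecord]:
    """Read a labelled CPI table.

    The interchange format is a UTF-8 TSV with header columns
    ``compound_id``, ``target_id``, ``label`` (an optional ``affinity_nM``
    column is accepted and ignored). Labels must be 0/1; duplicated
    (compound, target) pairs are a hard error — silent deduplication of a
    training table hides upstream bugs. When compound/target collections
    are supplied, every id must resolve against them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound_id", "target_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    records: list[CPIRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        raw = str(row.label).strip()
        try:
            label = int(float(raw))
        except ValueError:
            raise ValueError(f"label {raw!r} is not 0/1") from None
        if label not in (0, 1) or float(raw) != label:
            raise ValueError(f"label {raw!r} is not 0/1")
        key = (row.compound_id, row.target_id)
        if key in seen:
            raise DuplicateIdError(f"duplicate CPI pair {key}")
        seen.add(key)
        records.append(CPIRecord(row.compound_id, row.target_id, label))

    if compounds is not None:
        known = {c.id for c in compounds}
        dangling = sorted({r.compound_id for r in records} - known)
        if dangling:
            raise ValueError(f"unknown compound id(s): {dangling[:5]}")
    if targets is not None:
        known = {t.id for t in targets}
        dangling = sorted({r.target_id for r in records} - known)
        if dangling:
            raise ValueError(f"unknown target id(s): {dangling[:5]}")
    return records


def write_cpi_table(records: Iterable[CPIRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\ttarget_id\tlabel\n")
        for r in records:
            fh.write(f"{r.compound_id}\t{r.target_id}\t{r.label}\n")


# ---------------------------------------------------------------------------
# matrix persistence


def save_matrix(m: FingerprintMatrix, path: str | Path) -> None:
    """Persist a fingerprint matrix as CSV (id header row and column).

    Values are written with ``repr``-style shortest round-trip floats, so
    load/save round trips are value-identical. A ``#shape=`` marker line
    lets the loader detect truncated files.
    """
    df = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids)
    df.index.name = "compound_id"
    with open(path, "w") as fh:
        fh.write(f"#shape={len(m.row_ids)},{len(m.col_ids)}\n")
        df.to_csv(fh)


def load_matrix(path: str | Path) -> FingerprintMatrix:
    expected_shape = None
    try:
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#shape="):
                r, c = first.removeprefix("#shape=").strip().split(",")
                expected_shape = (int(r), int(c))
            else:
                fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MatrixCorruptionError(f"{path}: {exc}") from exc
    if expected_shape is not None and values.shape != expected_shape:
        raise MatrixCorruptionError(
            f"{path}: shape {values.shape} != declared {expected_shape} (truncated?)"
        )
    try:
        return FingerprintMatrix(
            row_ids=[str(i) for i in df.index],
            col_ids=[str(c) for c in df.columns],
            values=values,
        )
    except ValueError as exc:
        raise MatrixCorruptionError(f"{path}: {exc}") from exc
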