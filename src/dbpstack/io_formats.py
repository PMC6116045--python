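"""Readers and writers for the formats the pipeline touches.

Protein sequences arrive as FASTA; per-protein evolutionary profiles as
PSI-BLAST ASCII position-specific scoring matrices (PSSM, L rows by 20
residue types, log-odds in the first numeric block); per-protein secondary
structure as PSIPRED ``.ss2`` files (three state probabilities per residue).
Feature matrices are persisted as plain TSV with one column per feature
dimension, written with full float repr so that a read/write round trip is
bit-exact.

Internal conventions fixed here and relied on by every downstream module:

* PSSM columns are kept in PSI-BLAST file order (``ARNDCQEGHILKMFPSTWYV``).
* Secondary-structure columns are stored in (helix, strand, coil) order;
  ``.ss2`` files list them as (coil, helix, strand) and are remapped on load.
* All text I/O is UTF-8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

from .errors import FormatError, ProfileError, SchemaError

logger = logging.getLogger(__name__)

#: The 20 standard residues in PSI-BLAST PSSM column order.
PSSM_ALPHABET: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: The 20 standard residues in alphabetical order (composition features).
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

STANDARD_RESIDUES = frozenset(ALPHABET)

#: Internal secondary-structure state order: helix, strand, coil.
SS_STATES: tuple[str, ...] = ("H", "E", "C")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional binary DNA-binding label."""

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, eq=False)
class PssmProfile:
    """An L x 20 log-odds score matrix tied to a sequence."""

    record_id: str
    scores: np.ndarray
    column_order: tuple[str, ...] = PSSM_ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ProfileError(
                f"profile {self.record_id!r}: expected L x 20 scores, got "
                f"shape {scores.shape}"
            )
        if len(self.column_order) != 20:
            raise ProfileError(
                f"profile {self.record_id!r}: column order must name 20 residues"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True, eq=False)
class SsProfile:
    """Per-residue 3-state secondary-structure probabilities (H, E, C)."""

    record_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ProfileError(
                f"profile {self.record_id!r}: expected L x 3 probabilities"
            )
        if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
            raise ProfileError(
                f"profile {self.record_id!r}: probabilities outside [0, 1]"
            )
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ProfileError(
                f"profile {self.record_id!r}: row sums deviate from 1 by more "
                f"than 1e-3 (renormalize on load)"
            )

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True, eq=False)
class FeatureBlock:
    """A named fixed-length feature vector with per-dimension labels."""

    block_name: str
    values: np.ndarray
    dim_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dim_labels", tuple(self.dim_labels))
        if values.ndim != 1 or values.shape[0] != len(self.dim_labels):
            raise SchemaError(
                f"block {self.block_name!r}: {values.shape[0]} values but "
                f"{len(self.dim_labels)} labels"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Headers are parsed up to the first whitespace as the record id; entries
    containing non-standard residues (e.g. ``X``) are skipped with a logged
    warning rather than aborting the batch.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: line 1: empty or not FASTA-formatted")
    records: list[ProteinRecord] = []
    for entry in entries:
        if not entry.id:
            raise FormatError(f"{path}: entry with empty header id")
        try:
            records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
        except ValueError as exc:
            logger.warning("skipping %s: %s", entry.id, exc)
    return records


def _is_int_token(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def read_pssm(path, expected_length: Optional[int] = None) -> PssmProfile:
    """Read a PSI-BLAST ASCII PSSM; only the first 20 (log-odds) columns
    of each residue row are retained, percentages and footer statistics are
    ignored."""
    path = Path(path)
    column_order: Optional[tuple[str, ...]] = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not _is_int_token(tokens[0]):
                if (
                    column_order is None
                    and not rows
                    and len(tokens) >= 20
                    and all(len(t) == 1 and t.isalpha() for t in tokens)
                ):
                    column_order = tuple(tokens[:20])
                continue  # header or footer line
            if len(tokens) < 22:
                raise ProfileError(
                    f"{path}: line {lineno}: residue row has fewer than 20 "
                    f"score columns"
                )
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})")
    if not rows:
        raise FormatError(f"{path}: no residue rows found")
    if expected_length is not None and len(rows) != expected_length:
        raise ProfileError(
            f"{path}: {len(rows)} rows but expected length {expected_length}"
        )
    return PssmProfile(
        record_id=path.stem,
        scores=np.array(rows, dtype=float),
        column_order=column_order or PSSM_ALPHABET,
    )


def read_ss2(path, expected_length: Optional[int] = None) -> SsProfile:
    """Read a PSIPRED ``.ss2`` file into internal (helix, strand, coil) order.

    ``.ss2`` rows list probabilities as (coil, helix, strand); rows are
    renormalized to sum to 1 on load. Negative probabilities or a row sum
    deviating from 1 by more than 0.05 raise :class:`ProfileError`.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected index, residue, state "
                    f"and three probabilities"
                )
            try:
                coil, helix, strand = (float(t) for t in tokens[3:6])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})")
            if min(coil, helix, strand) < 0:
                raise ProfileError(f"{path}: line {lineno}: negative probability")
            total = coil + helix + strand
            if abs(total - 1.0) > 0.05:
                raise ProfileError(
                    f"{path}: line {lineno}: row sum {total:.3f} deviates from "
                    f"1 by more than 0.05"
                )
            rows.append((helix / total, strand / total, coil / total))
    if not rows:
        raise FormatError(f"{path}: no data rows found")
    if expected_length is not None and len(rows) != expected_length:
        raise ProfileError(
            f"{path}: {len(rows)} rows but expected length {expected_length}"
        )
    return SsProfile(record_id=path.stem, probs=np.array(rows, dtype=float))


def _check_block_structure(
    blocks_per_record: Mapping[str, Sequence[FeatureBlock]],
) -> list[tuple[str, tuple[str, ...]]]:
    structures = {}
    for rid, blocks in blocks_per_record.items():
        structures[rid] = [(b.block_name, b.dim_labels) for b in blocks]
    ref_rid = next(iter(structures))
    ref = structures[ref_rid]
    for rid, struct in structures.items():
        if struct != ref:
            raise SchemaError(
                f"record {rid!r} has a block structure different from "
                f"record {ref_rid!r}"
            )
    return ref


def write_feature_table(
    blocks_per_record: Mapping[str, Sequence[FeatureBlock]],
    path,
    labels: Optional[Mapping[str, int]] = None,
) -> None:
    """Write per-record feature blocks to TSV.

    Columns: ``id``, optionally ``label``, then one column per feature
    dimension with headers ``<block_name>:<dim_label>``. Values are written
    with full float repr (shortest round-tripping representation), so
    :func:`read_feature_table` recovers them bit-exactly.
    """
    path = Path(path)
    if not blocks_per_record:
        path.write_text("id\n", encoding="utf-8")
        return
    structure = _check_block_structure(blocks_per_record)
    header = ["id"]
    if labels is not None:
        header.append("label")
    for block_name, dim_labels in structure:
        header.extend(f"{block_name}:{lab}" for lab in dim_labels)
    lines = ["\t".join(header)]
    for rid, blocks in blocks_per_record.items():
        cells = [rid]
        if labels is not None:
            cells.append(str(int(labels[rid])))
        for block in blocks:
            if not np.all(np.isfinite(block.values)):
                raise ValueError(
                    f"record {rid!r} block {block.block_name!r}: non-finite "
                    f"feature values cannot be written"
                )
            cells.extend(repr(float(v)) for v in block.values)
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_feature_table(path):
    """Read a TSV written by :func:`write_feature_table`.

    Returns ``(blocks_per_record, labels)``; ``labels`` is ``None`` when the
    table carries no label column.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "id":
        raise FormatError(f"{path}: first column must be 'id'")
    has_labels = len(header) > 1 and header[1] == "label"
    feature_cols = header[2:] if has_labels else header[1:]
    # group consecutive columns by block name
    structure: list[tuple[str, list[str]]] = []
    for col in feature_cols:
        if ":" not in col:
            raise FormatError(f"{path}: malformed feature column {col!r}")
        block_name, dim_label = col.split(":", 1)
        if structure and structure[-1][0] == block_name:
            structure[-1][1].append(dim_label)
        else:
            structure.append((block_name, [dim_label]))
    blocks_per_record: dict[str, list[FeatureBlock]] = {}
    labels: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: {len(cells)} cells but "
                f"{len(header)} header columns"
            )
        rid = cells[0]
        offset = 1
        if has_labels:
            labels[rid] = int(cells[1])
            offset = 2
        blocks: list[FeatureBlock] = []
        for block_name, dim_labels in structure:
            values = np.array(
                [float(c) for c in cells[offset : offset + len(dim_labels)]]
            )
            offset += len(dim_labels)
            blocks.append(FeatureBlock(block_name, values, tuple(dim_labels)))
        blocks_per_record[rid] = blocks
    return blocks_per_record, (labels if has_labels else None)


def read_labels(path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` file."""
    out: dict[str, int] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: line {lineno}: expected id<TAB>label")
        if parts[0] == "id" and lineno == 1:
            continue
        out[parts[0]] = int(parts[1])
    return out


def load_dataset_tree(root):
    """Load a fixture tree: ``dataset.fasta``, ``pssm/<id>.pssm``,
    ``ss2/<id>.ss2`` and ``labels.tsv`` (labels optional).

    Returns ``(records, pssms, ss_profiles)`` where the two profile maps are
    keyed by record id; records missing either profile are dropped with a
    warning.
    """
    root = Path(root)
    records = read_fasta(root / "dataset.fasta")
    labels_path = root / "labels.tsv"
    labels = read_labels(labels_path) if labels_path.exists() else {}
    out_records: list[ProteinRecord] = []
    pssms: dict[str, PssmProfile] = {}
    ss_profiles: dict[str, SsProfile] = {}
    for rec in records:
        pssm_path = root / "pssm" / f"{rec.id}.pssm"
        ss2_path = root / "ss2" / f"{rec.id}.ss2"
        if not pssm_path.exists() or not ss2_path.exists():
            logger.warning("skipping %s: missing PSSM or ss2 profile", rec.id)
            continue
        try:
            pssms[rec.id] = read_pssm(pssm_path, expected_length=len(rec))
            ss_profiles[rec.id] = read_ss2(ss2_path, expected_length=len(rec))
        except (FormatError, ProfileError) as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
            pssms.pop(rec.id, None)
            continue
        if rec.id in labels:
            rec = ProteinRecord(rec.id, rec.sequence, labels[rec.id])
        out_records.append(rec)
    return out_records, pssms, ss_profiles
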