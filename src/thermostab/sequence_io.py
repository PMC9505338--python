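"""Reading, validating and splitting (sequence, Tm) data sets.

The training tables are delimited text with a header row and columns
``id``, ``sequence``, ``tm`` plus optional ``species`` and ``ogt``. Sequences
are validated against the 20 standard amino-acid letters; records carrying
ambiguous residues (B, J, O, U, X, Z, ``*``, ``-`` or anything else outside
the standard alphabet) are deleted, not masked, mirroring the curation
policy used to assemble cellular melting-temperature data sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError, FastaParseError, SequenceValidationError
from .tables import STANDARD_AA

logger = logging.getLogger(__name__)

_STANDARD_SET = frozenset(STANDARD_AA)

#: Plausibility window for melting temperatures (°C).
TM_RANGE = (0.0, 150.0)

#: Minimum sequence length admitted into data sets. Sequence-order
#: descriptors with the default lag of 30 need length > 30.
MIN_SEQUENCE_LENGTH = 31


@dataclass
class ProteinRecord:
    """One protein sequence with optional annotations.

    Attributes
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    sequence : str
        Uppercase sequence over the 20 standard amino-acid letters.
    species : str, optional
        Source organism.
    ogt : float, optional
        Optimal growth temperature of the organism (°C).
    tm : float, optional
        Experimental melting temperature (°C) — the regression target.
    """

    id: str
    sequence: str
    species: str | None = None
    ogt: float | None = None
    tm: float | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of records, all carrying a Tm value."""

    records: list[ProteinRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [""] * len(self.records)
        if len(self.provenance) != len(self.records):
            raise DataError("provenance labels must align with records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def tm_values(self) -> np.ndarray:
        return np.array([r.tm for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "species": [r.species for r in self.records],
                "ogt": [r.ogt for r in self.records],
                "tm": [r.tm for r in self.records],
            }
        )


def validate_sequence(
    raw: str, policy: Literal["reject", "drop_record"] = "reject"
) -> str | None:
    """Validate and uppercase a raw sequence.

    Returns the uppercased sequence if every character is one of the 20
    standard letters. Under ``policy="reject"`` an invalid sequence raises
    :class:`SequenceValidationError`; under ``"drop_record"`` it returns
    ``None`` so the caller can exclude the record.
    """
    if not isinstance(raw, str) or raw == "":
        raise SequenceValidationError("empty sequence")
    seq = raw.strip().upper()
    if not seq:
        raise SequenceValidationError("empty sequence")
    bad = sorted(set(seq) - _STANDARD_SET)
    if bad:
        if policy == "drop_record":
            return None
        raise SequenceValidationError(
            f"sequence contains non-standard characters: {''.join(bad)}",
            offending="".join(bad),
        )
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records (sequences uppercased, not validated).

    The id is the header token before the first whitespace. Raises
    :class:`FastaParseError` with a line number if sequence data precedes
    the first header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            logger.warning("empty FASTA file: %s", path)
            return []
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("FASTA file contained no records: %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _parse_tm(value) -> float | None:
    try:
        tm = float(value)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(tm) or not (TM_RANGE[0] <= tm <= TM_RANGE[1]):
        return None
    return tm


def load_dataset(
    path: str | Path,
    *,
    min_length: int = MIN_SEQUENCE_LENGTH,
    provenance: str | None = None,
) -> Dataset:
    """Load a delimited training table into a validated, deduplicated Dataset.

    Rows failing sequence validation, carrying a non-numeric or implausible
    Tm, or shorter than ``min_length`` are excluded and counted in the log.
    Duplicate sequences are collapsed to their first occurrence.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
    return dataset_from_frame(
        frame, min_length=min_length, provenance=provenance or str(path)
    )


def dataset_from_frame(
    frame: pd.DataFrame,
    *,
    min_length: int = MIN_SEQUENCE_LENGTH,
    provenance: str = "",
) -> Dataset:
    missing = {"id", "sequence", "tm"} - set(frame.columns)
    if missing:
        raise DataError(f"table is missing required columns: {sorted(missing)}")

    records: list[ProteinRecord] = []
    seen_sequences: set[str] = set()
    n_excluded = 0
    for row in frame.itertuples(index=False):
        seq = row.sequence if isinstance(row.sequence, str) else ""
        try:
            valid = validate_sequence(seq, policy="drop_record")
        except SequenceValidationError:
            valid = None
        tm = _parse_tm(row.tm)
        if valid is None or tm is None or len(valid) < min_length:
            n_excluded += 1
            continue
        if valid in seen_sequences:  # duplicate definition: identical sequence
            n_excluded += 1
            continue
        seen_sequences.add(valid)
        species = getattr(row, "species", None)
        ogt = getattr(row, "ogt", None)
        records.append(
            ProteinRecord(
                id=str(row.id),
                sequence=valid,
                species=None if pd.isna(species) else str(species),
                ogt=None if ogt is None or pd.isna(ogt) else float(ogt),
                tm=tm,
            )
        )
    _ensure_unique_ids(records)
    logger.info(
        "loaded %d records (%d rows excluded) from %s",
        len(records), n_excluded, provenance,
    )
    return Dataset(records, provenance=[provenance] * len(records))


def _ensure_unique_ids(records: list[ProteinRecord]) -> None:
    seen: dict[str, int] = {}
    for r in records:
        if r.id in seen:
            seen[r.id] += 1
            r.id = f"{r.id}_{seen[r.id]}"
        else:
            seen[r.id] = 0


def save_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as a TSV training table."""
    ds.to_frame().to_csv(path, sep="\t", index=False)


def split_dataset(
    ds: Dataset, blind_fraction: float = 0.1, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Randomly partition a dataset into training and blind test sets.

    ``blind = round(blind_fraction * N)`` records are drawn without
    replacement; the split is reproducible for a fixed seed and the two
    parts are disjoint and exhaustive.
    """
    if not 0 < blind_fraction < 1:
        raise DataError(f"blind_fraction must be in (0, 1), got {blind_fraction}")
    n = len(ds)
    n_blind = int(round(blind_fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blind_idx = set(order[:n_blind].tolist())
    train_records, blind_records = [], []
    train_prov, blind_prov = [], []
    for i, (rec, prov) in enumerate(zip(ds.records, ds.provenance)):
        if i in blind_idx:
            blind_records.append(rec)
            blind_prov.append(prov)
        else:
            train_records.append(rec)
            train_prov.append(prov)
    logger.info(
        "split %d records into %d train / %d blind (seed=%d)",
        n, len(train_records), len(blind_records), seed,
    )
    return Dataset(train_records, train_prov), Dataset(blind_records, blind_prov)
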