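"""Reading, validating and writing coding sequences and time-course tables.

Coding sequences arrive as multi-FASTA and are held as ordered codon lists
(:class:`OrfRecord`). Coordinates are 0-based throughout: codon index ``i``
covers the half-open nucleotide interval ``[3i, 3i + 3)``, which keeps codon
bookkeeping uniform with the nucleotide-level sliding simulator. Only the
sense strand is analyzed; inputs are assumed strand-resolved. RNA-style input
(``AUG...``) is accepted — ``U`` is normalized to ``T`` on read.

Time courses (species fractions vs time, one column per chain species) travel
as TSV with a ``time_s`` column; see :func:`read_timecourse_tsv`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OrfRecord",
    "FastaReadReport",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_timecourse_tsv",
    "write_timecourse_tsv",
    "STOP_CODONS",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGT")

Policy = Literal["strict", "lenient", "skip-invalid"]


class CdsValidationError(ValueError):
    """A coding sequence violated the requested validation policy."""


@dataclass(frozen=True)
class OrfRecord:
    """One coding sequence as an ordered codon list.

    Parameters
    ----------
    id:
        Text identifier (FASTA header up to first whitespace).
    codons:
        Tuple of 3-letter uppercase DNA codons over {A, C, G, T}.
    source_offset:
        0-based nucleotide start of codon 1 within the raw record.
    """

    id: str
    codons: tuple[str, ...]
    source_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError(f"record {self.id!r}: empty codon list")
        for c in self.codons:
            if len(c) != 3 or not set(c) <= _VALID_BASES:
                raise ValueError(f"record {self.id!r}: invalid codon {c!r}")

    @property
    def sequence(self) -> str:
        """Concatenated nucleotide sequence."""
        return "".join(self.codons)

    def validate_strict(self) -> None:
        """Require an ATG start and a stop codon at the end."""
        if self.codons[0] != "ATG":
            raise CdsValidationError(
                f"record {self.id!r}: first codon {self.codons[0]} is not ATG"
            )
        if self.codons[-1] not in STOP_CODONS:
            raise CdsValidationError(
                f"record {self.id!r}: last codon {self.codons[-1]} is not a stop"
            )


@dataclass
class FastaReadReport:
    """Tally of records dropped or truncated while reading a CDS FASTA."""

    n_read: int = 0
    n_skipped: int = 0
    n_truncated: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_cds_fasta(
    path: str | Path,
    policy: Policy = "strict",
    report: FastaReadReport | None = None,
) -> list[OrfRecord]:
    """Read coding sequences from a multi-FASTA file.

    Lowercase input is uppercased and ``U`` mapped to ``T``. Handling of
    malformed records depends on ``policy``:

    ``strict``
        Length not divisible by 3, ambiguity codes, a non-ATG start or a
        non-stop final codon raise :class:`CdsValidationError` naming the
        offending record.
    ``lenient``
        Trailing incomplete codons are truncated (counted in the report, and
        a single summary warning is emitted); ambiguity codes still raise.
    ``skip-invalid``
        Records with non-multiple-of-3 length or ambiguity codes are dropped
        and counted.

    Parameters
    ----------
    path:
        FASTA file path.
    policy:
        One of ``strict``, ``lenient``, ``skip-invalid``.
    report:
        Optional tally object; filled in place so callers can inspect the
        number of skipped/truncated records.

    Returns
    -------
    list of OrfRecord
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if policy not in ("strict", "lenient", "skip-invalid"):
        raise ValueError(f"unknown policy {policy!r}")
    if report is None:
        report = FastaReadReport()

    records: list[OrfRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq))
        bad_alphabet = not set(seq) <= _VALID_BASES
        bad_length = len(seq) % 3 != 0
        if bad_alphabet:
            if policy == "skip-invalid":
                report.n_skipped += 1
                report.skipped_ids.append(rec.id)
                continue
            raise CdsValidationError(f"record {rec.id!r}: ambiguity codes in sequence")
        if bad_length:
            if policy == "strict":
                raise CdsValidationError(
                    f"record {rec.id!r}: length {len(seq)} not divisible by 3"
                )
            if policy == "skip-invalid":
                report.n_skipped += 1
                report.skipped_ids.append(rec.id)
                continue
            seq = seq[: 3 * (len(seq) // 3)]
            report.n_truncated += 1
        if not seq:
            report.n_skipped += 1
            report.skipped_ids.append(rec.id)
            continue
        orf = OrfRecord(
            id=rec.id,
            codons=tuple(seq[i : i + 3] for i in range(0, len(seq), 3)),
        )
        if policy == "strict":
            orf.validate_strict()
        records.append(orf)
        report.n_read += 1

    if report.n_truncated:
        warnings.warn(
            f"{path.name}: truncated trailing bases on {report.n_truncated} record(s)",
            stacklevel=2,
        )
    if not records and report.n_skipped == 0:
        raise CdsValidationError(f"{path}: empty FASTA, no records found")
    return records


def write_cds_fasta(
    records: Iterable[OrfRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as standard multi-FASTA, line-wrapped at ``width``.

    ``read_cds_fasta(write_cds_fasta(records))`` is the identity on codon
    content.
    """
    if width < 1:
        raise ValueError("width must be positive")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_timecourse_tsv(path: str | Path, sum_tol: float = 0.05):
    """Read a species-fraction time course from TSV.

    Expected layout: header ``time_s`` followed by one column per chain
    species in chain order (M, MK, MK2, ...). Times must be strictly
    increasing and non-negative; fractions in [0, 1]. Rows whose fractions
    sum outside ``[1 - sum_tol, 1 + sum_tol]`` are flagged (indices stored on
    the returned object) but not rejected — measured band quantifications do
    not sum exactly to one.

    Returns
    -------
    TimeCourse
        With ``flagged_rows`` listing the 0-based indices of off-sum rows.
    """
    from polyaslide.kinetics import TimeCourse

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no species columns")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(times < 0):
        raise ValueError(f"{path}: negative time values")
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times not strictly increasing")
    fractions = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError(f"{path}: fractions outside [0, 1]")
    sums = fractions.sum(axis=1)
    flagged = np.nonzero(np.abs(sums - 1.0) > sum_tol)[0].tolist()
    return TimeCourse(
        times=times,
        fractions=fractions,
        species=list(df.columns[1:]),
        flagged_rows=flagged,
    )


def write_timecourse_tsv(tc, path: str | Path) -> None:
    """Write a TimeCourse as TSV (``time_s`` + one column per species)."""
    df = pd.DataFrame(tc.fractions, columns=tc.species)
    df.insert(0, "time_s", tc.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
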