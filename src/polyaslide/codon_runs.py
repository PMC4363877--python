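"""Maximal lysine-codon-run extraction and observed/expected enrichment.

Lysine is encoded by AAA and AAG. Consecutive lysine codons produce
homopolymeric-A stretches on the mRNA, and genomes deplete the all-AAA
arrangements of such runs. This module quantifies that: it extracts
*maximal* runs of lysine codons from coding sequences (a run of n lysines is
counted once, at length n — it contributes no sub-runs), tallies the 2**n
codon arrangements of each run length, and compares the observed arrangement
fractions with those expected if each lysine codon were drawn independently
at the genome-wide single-codon AAA/AAG usage:

    expected(motif) = prod over codons c in motif of p(c),
    enrichment(motif) = fraction_observed(motif) / fraction_expected(motif).

Enrichment near 1 means the arrangement occurs as often as usage predicts;
values well below 1 (as for AAA-AAA-AAA) indicate selection against the
arrangement.

Terminal stop codons are excluded from usage counts (a stop cannot encode
lysine); usage fractions are kept as exact rationals until display.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from polyaslide.orf_io import STOP_CODONS, OrfRecord

__all__ = [
    "LYSINE_CODONS",
    "LysineRun",
    "CodonUsage",
    "MotifStats",
    "extract_lysine_runs",
    "single_codon_usage",
    "count_motifs",
    "expected_fraction",
    "table_from_counts",
    "enrichment_table",
    "motifs_of_length",
    "table_to_dataframe",
    "write_enrichment_tsv",
]

LYSINE_CODONS = ("AAA", "AAG")


@dataclass(frozen=True)
class LysineRun:
    """A maximal block of consecutive lysine codons within one ORF."""

    orf_id: str
    start_codon_index: int
    motif: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError("run must contain at least one codon")
        if any(c not in LYSINE_CODONS for c in self.motif):
            raise ValueError(f"non-lysine codon in run motif {self.motif}")

    @property
    def length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class CodonUsage:
    """Single-codon AAA/AAG usage among all lysine codons of a CDS set."""

    n_AAA: int
    n_AAG: int

    def __post_init__(self) -> None:
        if self.n_AAA < 0 or self.n_AAG < 0:
            raise ValueError("negative codon count")
        if self.n_AAA + self.n_AAG == 0:
            raise ValueError(
                "zero lysine codons in set: expected model undefined"
            )

    @property
    def n_lysine_codons(self) -> int:
        return self.n_AAA + self.n_AAG

    @property
    def p_AAA(self) -> Fraction:
        return Fraction(self.n_AAA, self.n_lysine_codons)

    @property
    def p_AAG(self) -> Fraction:
        return Fraction(self.n_AAG, self.n_lysine_codons)

    def p(self, codon: str) -> Fraction:
        if codon == "AAA":
            return self.p_AAA
        if codon == "AAG":
            return self.p_AAG
        raise ValueError(f"{codon!r} is not a lysine codon")


@dataclass(frozen=True)
class MotifStats:
    """Observed/expected statistics for one codon arrangement of a run length.

    ``enrichment`` is ``fraction_observed / fraction_expected``; ``None``
    when the expected fraction is zero (degenerate usage) or when no run of
    this length was observed.
    """

    motif: tuple[str, ...]
    occurrences: int
    fraction_observed: float
    fraction_expected: float
    enrichment: float | None


def motifs_of_length(n: int) -> list[tuple[str, ...]]:
    """All 2**n lysine-codon arrangements of length n, lexicographic order."""
    return list(product(LYSINE_CODONS, repeat=n))


def extract_lysine_runs(orf: OrfRecord) -> list[LysineRun]:
    """Extract maximal lysine-codon runs, ordered by start index.

    A run of n consecutive AAA/AAG codons yields exactly one
    :class:`LysineRun` of length n; it does not also contribute its
    sub-runs. Runs truncated by ORF boundaries still count as maximal.
    """
    runs: list[LysineRun] = []
    codons = orf.codons
    i = 0
    n = len(codons)
    while i < n:
        if codons[i] in LYSINE_CODONS:
            j = i
            while j < n and codons[j] in LYSINE_CODONS:
                j += 1
            runs.append(
                LysineRun(
                    orf_id=orf.id,
                    start_codon_index=i,
                    motif=tuple(codons[i:j]),
                )
            )
            i = j
        else:
            i += 1
    return runs


def _usage_codons(orf: OrfRecord) -> Sequence[str]:
    """In-frame codons of an ORF minus a terminal stop, for usage counting."""
    if orf.codons[-1] in STOP_CODONS:
        return orf.codons[:-1]
    return orf.codons


def single_codon_usage(orfs: Iterable[OrfRecord]) -> CodonUsage:
    """Count AAA/AAG over all in-frame codons, excluding terminal stops.

    Raises
    ------
    ValueError
        If the set contains no lysine codons (the independence null is
        undefined without a usage estimate).
    """
    n_aaa = 0
    n_aag = 0
    for orf in orfs:
        for codon in _usage_codons(orf):
            if codon == "AAA":
                n_aaa += 1
            elif codon == "AAG":
                n_aag += 1
    return CodonUsage(n_AAA=n_aaa, n_AAG=n_aag)


def count_motifs(
    runs: Iterable[LysineRun], n: int
) -> dict[tuple[str, ...], int]:
    """Occurrences of each length-n arrangement among runs of exactly length n.

    Runs of any other length are ignored (a length-3 run contributes nothing
    to dilysine counts). Every one of the 2**n motifs appears in the result,
    zero-filled.
    """
    if n < 2:
        raise ValueError("run length must be >= 2; length-1 runs feed usage only")
    counts: dict[tuple[str, ...], int] = {m: 0 for m in motifs_of_length(n)}
    for run in runs:
        if run.length == n:
            counts[run.motif] += 1
    return counts


def expected_fraction(motif: Sequence[str], usage: CodonUsage) -> Fraction:
    """Probability of a codon arrangement under independent draws at usage.

    Returns an exact rational; convert with ``float()`` for display.
    """
    p = Fraction(1)
    for codon in motif:
        p *= usage.p(codon)
    return p


def table_from_counts(
    counts: Mapping[tuple[str, ...], int], usage: CodonUsage
) -> list[MotifStats]:
    """Observed/expected/enrichment rows from per-motif occurrence counts.

    The arithmetic behind the enrichment table: within one run length,
    fraction_observed = count / total, fraction_expected = independence
    product at ``usage``, enrichment = observed / expected.
    """
    total = sum(counts.values())
    rows = []
    for motif in sorted(counts):
        occ = counts[motif]
        f_exp = expected_fraction(motif, usage)
        f_obs = Fraction(occ, total) if total > 0 else Fraction(0)
        if total > 0 and f_exp > 0:
            enr = float(f_obs / f_exp)
        else:
            enr = None
        rows.append(
            MotifStats(
                motif=motif,
                occurrences=occ,
                fraction_observed=float(f_obs),
                fraction_expected=float(f_exp),
                enrichment=enr,
            )
        )
    return rows


def enrichment_table(
    orfs: Sequence[OrfRecord],
    lengths: Iterable[int] = (2, 3, 4),
    usage: CodonUsage | None = None,
) -> dict[int, list[MotifStats]]:
    """Observed/expected/enrichment table per requested run length.

    For each length n, ``fraction_observed`` of a motif is its occurrence
    count divided by the total count of exact-length-n runs, and enrichment
    uses unrounded usage fractions. A length with zero observed runs is still
    emitted (all occurrences 0, enrichment ``None``) so callers can see the
    zero total.

    Parameters
    ----------
    orfs:
        The CDS set.
    lengths:
        Run lengths to tabulate, each >= 2.
    usage:
        Precomputed single-codon usage; computed from ``orfs`` when omitted.
    """
    if usage is None:
        usage = single_codon_usage(orfs)
    runs = [r for orf in orfs for r in extract_lysine_runs(orf)]
    return {
        n: table_from_counts(count_motifs(runs, n), usage)
        for n in sorted(set(lengths))
    }


def table_to_dataframe(table: Mapping[int, list[MotifStats]]) -> pd.DataFrame:
    """Flatten an enrichment table into a tidy DataFrame.

    Columns: ``run_length, motif, occurrences, fraction_observed,
    fraction_expected, enrichment`` with motifs printed as codons joined by
    ``-`` (e.g. ``AAA-AAG``).
    """
    records = []
    for n in sorted(table):
        for row in table[n]:
            records.append(
                {
                    "run_length": n,
                    "motif": "-".join(row.motif),
                    "occurrences": row.occurrences,
                    "fraction_observed": row.fraction_observed,
                    "fraction_expected": row.fraction_expected,
                    "enrichment": np.nan if row.enrichment is None else row.enrichment,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "run_length",
            "motif",
            "occurrences",
            "fraction_observed",
            "fraction_expected",
            "enrichment",
        ],
    )


def write_enrichment_tsv(
    table: Mapping[int, list[MotifStats]],
    usage: CodonUsage,
    n_orfs: int,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the enrichment table and a usage summary as TSV.

    Produces ``<prefix>.enrichment.tsv`` and ``<prefix>.summary.tsv``;
    byte-identical for identical inputs.
    """
    out_prefix = Path(out_prefix)
    enrich_path = out_prefix.with_suffix(".enrichment.tsv")
    summary_path = out_prefix.with_suffix(".summary.tsv")
    df = table_to_dataframe(table)
    df.to_csv(enrich_path, sep="\t", index=False, float_format="%.6g")
    summary = pd.DataFrame(
        [
            {
                "n_orfs": n_orfs,
                "n_lysine_codons": usage.n_lysine_codons,
                "p_AAA": float(usage.p_AAA),
                "p_AAG": float(usage.p_AAG),
            }
        ]
    )
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
    return enrich_path, summary_path
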