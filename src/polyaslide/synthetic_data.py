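"""Seeded generators for every input class the pipeline consumes.

Three families, all pure functions of (spec, seed):

* noisy kinetic time courses — the Bateman-chain truth plus a band-
  quantification noise model (gaussian-with-renormalization or Dirichlet),
  emulating densitometry of eTLC species bands;
* null codon corpora — i.i.d. per-codon draws at a specified lysine
  probability and AAA|lysine fraction, the independence null behind the
  observed/expected enrichment table, plus exact-count run injection;
* reporter mRNAs — messages with poly(A) or codon inserts, either bare
  (ATG-insert-stop) or with flanks that guarantee out-of-frame stop codons
  shortly downstream of the insert, the construction that turns ribosome
  sliding into a released truncated product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from polyaslide.codon_runs import LYSINE_CODONS, extract_lysine_runs
from polyaslide.kinetics import KineticRateSet, TimeCourse, simulate_timecourse
from polyaslide.orf_io import STOP_CODONS, OrfRecord
from polyaslide.sliding_sim import MrnaTemplate, find_a_runs

__all__ = [
    "NoiseSpec",
    "CorpusSpec",
    "generate_timecourse",
    "generate_null_orfs",
    "inject_run",
    "build_reporter_mrna",
    "shifted_frame_stops",
    "NON_LYSINE_SENSE_CODONS",
]

_BASES = "ACGT"
NON_LYSINE_SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
    if c not in STOP_CODONS and c not in LYSINE_CODONS
)
assert len(NON_LYSINE_SENSE_CODONS) == 59


@dataclass(frozen=True)
class NoiseSpec:
    """Band-quantification noise model for simulated time courses.

    ``gaussian_renormalized`` adds i.i.d. N(0, sigma) to each fraction,
    clips to [0, 1] and renormalizes each row; ``dirichlet`` draws each row
    from Dirichlet(concentration_scale * truth). Both keep rows valid
    fraction vectors. The true eTLC error structure is unreported; these are
    stand-ins.
    """

    kind: str = "gaussian_renormalized"
    sigma: float = 0.02
    concentration_scale: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_renormalized", "dirichlet"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.concentration_scale <= 0:
            raise ValueError("invalid noise parameters")


@dataclass(frozen=True)
class CorpusSpec:
    """Null CDS corpus: i.i.d. codon draws at specified lysine/AAA usage.

    ``length_codons`` is the number of internal codons per ORF (between the
    ATG and the stop), either a fixed int or an inclusive (lo, hi) range
    sampled uniformly.
    """

    n_orfs: int = 100
    length_codons: int | tuple[int, int] = 300
    p_lysine: float = 0.044  # roughly genomic lysine codon frequency
    p_AAA_given_lysine: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValueError("n_orfs must be >= 1")
        if not 0 <= self.p_lysine <= 1 or not 0 <= self.p_AAA_given_lysine <= 1:
            raise ValueError("probabilities must be in [0, 1]")


def _noisy_rows(truth: np.ndarray, noise: NoiseSpec, rng: np.random.Generator):
    if noise.kind == "gaussian_renormalized":
        if noise.sigma == 0:
            return truth.copy()
        rows = truth + rng.normal(0.0, noise.sigma, size=truth.shape)
        rows = np.clip(rows, 0.0, 1.0)
    else:
        alpha = noise.concentration_scale * truth + 1e-9
        rows = np.vstack([rng.dirichlet(a) for a in alpha])
    sums = rows.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return rows / sums


def generate_timecourse(
    rates: KineticRateSet | Sequence[float],
    times: Sequence[float],
    noise: NoiseSpec,
    replicates: int = 1,
) -> list[TimeCourse]:
    """Noisy replicates of the chain's time course with known ground truth.

    Replicate r draws from seed substream ``SeedSequence(seed, spawn_key=(r,))``;
    with ``sigma=0`` (gaussian kind) the output equals the noiseless truth.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    truth = simulate_timecourse(rates, times)
    out = []
    for r in range(replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=noise.seed, spawn_key=(r,))
        )
        out.append(
            TimeCourse(
                times=truth.times.copy(),
                fractions=_noisy_rows(truth.fractions, noise, rng),
                species=list(truth.species),
            )
        )
    return out


def generate_null_orfs(spec: CorpusSpec) -> list[OrfRecord]:
    """i.i.d.-codon ORFs passing strict validation (ATG start, stop end).

    Each internal position is lysine with ``p_lysine`` (then AAA with
    ``p_AAA_given_lysine``, else AAG), otherwise uniform over the 59
    non-lysine sense codons — no internal stop can be drawn. Deterministic
    per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed))
    non_lys = np.array(NON_LYSINE_SENSE_CODONS)
    stops = np.array(["TAA", "TAG", "TGA"])
    records = []
    for i in range(spec.n_orfs):
        if isinstance(spec.length_codons, tuple):
            lo, hi = spec.length_codons
            length = int(rng.integers(lo, hi + 1))
        else:
            length = int(spec.length_codons)
        body = non_lys[rng.integers(len(non_lys), size=length)]
        is_lys = rng.random(length) < spec.p_lysine
        is_aaa = rng.random(length) < spec.p_AAA_given_lysine
        body[is_lys] = np.where(is_aaa[is_lys], "AAA", "AAG")
        stop = stops[rng.integers(3)]
        records.append(
            OrfRecord(id=f"null_{i:05d}", codons=("ATG", *body.tolist(), str(stop)))
        )
    return records


def inject_run(
    records: Sequence[OrfRecord],
    motif: Sequence[str],
    copies: int,
    seed: int = 0,
) -> list[OrfRecord]:
    """Overwrite codons to plant exactly ``copies`` new maximal runs of ``motif``.

    Insertion windows are chosen (seeded, uniformly) among interior positions
    whose codons and immediate flanks contain no lysine codon, so each
    injected run is maximal with exactly the intended motif and no existing
    run is created, destroyed or extended. Raises if the corpus cannot host
    the requested number of disjoint windows.
    """
    motif = tuple(motif)
    if any(c not in LYSINE_CODONS for c in motif):
        raise ValueError("motif must consist of lysine codons")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    out = [list(r.codons) for r in records]
    if copies == 0:
        return list(records)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    m = len(motif)
    # candidate (record, start) windows: codons [start-1, start+m] all
    # non-lysine, interior to the ORF (keep ATG and the stop intact)
    candidates = []
    for ri, codons in enumerate(out):
        for start in range(2, len(codons) - m - 1):
            window = codons[start - 1 : start + m + 1]
            if all(c not in LYSINE_CODONS for c in window):
                candidates.append((ri, start))
    rng.shuffle(candidates)
    placed = 0
    used: dict[int, list[tuple[int, int]]] = {}
    for ri, start in candidates:
        if placed == copies:
            break
        span = (start - 1, start + m + 1)
        if any(a < span[1] and span[0] < b for a, b in used.get(ri, [])):
            continue
        for k, codon in enumerate(motif):
            out[ri][start + k] = codon
        used.setdefault(ri, []).append(span)
        placed += 1
    if placed < copies:
        raise ValueError(
            f"could only place {placed} of {copies} runs in the corpus"
        )
    return [
        OrfRecord(id=r.id, codons=tuple(cs), source_offset=r.source_offset)
        for r, cs in zip(records, out)
    ]


# ---------------------------------------------------------------------------
# reporter construction

# Downstream core: no frame-0 stop (CTA AGT AGA CCG), a TAA at shift +1 and a
# TAG at shift +2 — out-of-frame stops within a few codons of the insert.
_OOF_STOP_CORE = "CTAAGTAGACCG"
_UPSTREAM_FLANK = "GGTTCT"  # Gly-Ser, ends in a non-A base
_FILLER = "GGCTCTGTC"  # Gly-Ser-Val, stop-free in frame 0


def shifted_frame_stops(
    sequence: str, start: int, upto: int | None = None
) -> dict[int, list[int]]:
    """Positions of stop codons by frame offset relative to ``start``."""
    if upto is None:
        upto = len(sequence)
    found: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(start, min(upto, len(sequence) - 2)):
        if sequence[i : i + 3] in STOP_CODONS:
            found[(i - start) % 3].append(i)
    return found


def build_reporter_mrna(
    poly_a: int | None = None,
    codons: Sequence[str] | None = None,
    flank_style: str = "minimal",
) -> MrnaTemplate:
    """Construct a reporter message around a poly(A) or codon insert.

    ``minimal`` is the bare in vitro message: ATG + insert + stop (e.g. the
    MK_A2-Stop context for ``codons=("AAA", "AAA")``). ``mcherry_like`` adds
    a short upstream flank and a downstream flank carrying, by construction,
    a stop codon in each of the two shifted frames within 60 nt of the
    insert, then filler and the in-frame stop — the configuration in which
    sliding yields a released truncated product. A non-multiple-of-3 poly(A)
    insert is padded to the codon boundary with non-A bases, so the A-run
    length is exactly ``poly_a`` and the annotated stop stays in frame.
    """
    if (poly_a is None) == (codons is None):
        raise ValueError("specify exactly one of poly_a or codons (or codons=())")
    if poly_a is not None:
        if poly_a < 0:
            raise ValueError("poly_a must be >= 0")
        insert = "A" * poly_a
        pad = {0: "", 1: "CT", 2: "C"}[poly_a % 3]
        insert += pad
    else:
        for c in codons:
            if len(c) != 3 or not set(c) <= set("ACGT"):
                raise ValueError(f"bad insert codon {c!r}")
            if c in STOP_CODONS:
                raise ValueError("stop codon inside insert")
        insert = "".join(codons)

    if flank_style == "minimal":
        seq = "ATG" + insert + "TAA"
        template = MrnaTemplate(seq, start_index=0)
    elif flank_style == "mcherry_like":
        down = _OOF_STOP_CORE + _FILLER * 2
        seq = "ATG" + _UPSTREAM_FLANK + insert + down + "TAA"
        template = MrnaTemplate(seq, start_index=0)
        insert_end = 3 + len(_UPSTREAM_FLANK) + len(insert)
        stops = shifted_frame_stops(seq, template.start_index, insert_end + 60)
        shifted = {f for f in (1, 2) if any(p >= insert_end - 3 for p in stops[f])}
        if shifted != {1, 2}:  # construction guarantee, verified by scanner
            raise AssertionError("downstream flank lacks a shifted-frame stop")
    else:
        raise ValueError(f"unknown flank_style {flank_style!r}")
    return template


def reporter_a_run_length(template: MrnaTemplate) -> int:
    """Length of the longest A-run in a reporter (0 if none)."""
    runs = find_a_runs(template)
    return max((ln for _s, ln in runs), default=0)
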