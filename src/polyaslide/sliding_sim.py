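"""Stochastic simulator of ribosome pausing and sliding on A-runs.

The model is phenomenological at the nucleotide level. A ribosome is
represented by the position of its A-site codon on the mRNA (0-based
nucleotide index of the codon's first base); the reading frame is implicit,
``frame_offset = (a_site_nt - start_index) mod 3``. At each state the
ribosome chooses among competing exponential events:

ELONGATE
    Append the amino acid decoded from the current A-site codon (standard
    genetic code) and advance by 3 nt. The rate is ``k_fast`` for non-lysine
    codons and for the first lysine of a run; it drops to ``k_slow_AAA`` /
    ``k_slow_AAG`` when the previous incorporation was a lysine *and* the
    A-site codon sits in an in-reading run of at least ``min_lys_run_slow``
    consecutive lysine codons — short (di-lysine) contexts do not pause,
    longer iterated-lysine stretches do. ``k_next`` optionally overrides the
    rate for the first codon beyond the focal A-run (0 models a withheld
    downstream tRNA, as when only Lys-tRNA is supplied).
SLIDE
    Non-canonical movement on homopolymeric A: available whenever the A-site
    or P-site codon touches a maximal A-run of length >= ``min_A_run``. The
    ribosome re-pairs at a uniformly chosen alternative placement whose
    A-site codon lies wholly on A's within the run (both directions,
    |d| >= 1); no peptide bond is formed. Total rate is ``k_slide_unit``
    times the number of accessible placements, so longer runs slide more.
TERMINATE
    Release at a stop codon in the current reading, rate ``k_term``
    (0 models absent release factors).

A trajectory ends on release, on running past the template 3' end (guard;
unreachable when stops exist in all frames), or at ``t_max`` (stalled).
Ensembles are classified into full-length (released in frame at the
annotated stop), truncated/out-of-frame (released anywhere else), and
stalled products; trajectories whose lysine tally exceeds the encoded
in-frame count are additionally flagged extended (the eTLC "extra lysine"
signature).

An exact CTMC companion (:func:`exact_distribution`) enumerates the
reachable state space and integrates the forward equations, serving as an
independent check of the Gillespie kernel on small templates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csr_matrix
from Bio.Data.CodonTable import standard_dna_table

from polyaslide.orf_io import STOP_CODONS
from polyaslide.codon_runs import LYSINE_CODONS

__all__ = [
    "MrnaTemplate",
    "SlidingParams",
    "RibosomeState",
    "TrajectoryResult",
    "ProductSummary",
    "find_a_runs",
    "allowed_slide_offsets",
    "step_rates",
    "simulate_ribosome",
    "simulate_ensemble",
    "exact_distribution",
    "encoded_lysine_count",
]

ELONGATE = "ELONGATE"
SLIDE = "SLIDE"
TERMINATE = "TERMINATE"

# statuses
ELONGATING = "elongating"
RELEASED = "released"
STALLED = "stalled_at_tmax"
OUT_OF_TEMPLATE = "out_of_template"

_CODON_AA = dict(standard_dna_table.forward_table)


@dataclass(frozen=True)
class MrnaTemplate:
    """An mRNA with an annotated reading frame.

    ``sequence`` uses DNA alphabet (U is mapped to T); ``start_index`` is the
    0-based position of the initiator ATG and ``annotated_stop_index`` the
    0-based position of the in-frame stop codon.
    """

    sequence: str
    start_index: int = 0
    annotated_stop_index: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= set("ACGT"):
            raise ValueError("template contains non-ACGT characters")
        if seq[self.start_index : self.start_index + 3] != "ATG":
            raise ValueError("codon at start_index is not ATG")
        stop = self.annotated_stop_index
        if stop is None:
            stop = self._find_inframe_stop()
            object.__setattr__(self, "annotated_stop_index", stop)
        if self.sequence[stop : stop + 3] not in STOP_CODONS:
            raise ValueError("codon at annotated_stop_index is not a stop")
        if (stop - self.start_index) % 3 != 0:
            raise ValueError("annotated stop is not in frame with the start")

    def _find_inframe_stop(self) -> int:
        for i in range(self.start_index, len(self.sequence) - 2, 3):
            if self.sequence[i : i + 3] in STOP_CODONS:
                return i
        raise ValueError("no in-frame stop codon found")

    def codon_at(self, nt: int) -> str:
        return self.sequence[nt : nt + 3]


@dataclass(frozen=True)
class SlidingParams:
    """Event rates and geometry of the pause/slide/elongate model.

    Rates in s^-1. Defaults correspond to the reconstituted E. coli system:
    fast (normal) elongation at 12 s^-1, the slow iterated-lysine additions
    at 5e-4 (AAA) / 9e-3 (AAG) s^-1, a 5-nt A-run threshold for sliding, and
    a 30-min observation window. ``k_next=None`` means no override (all
    downstream substrates present); ``k_next=0`` models withheld tRNA.
    ``k_slide_unit`` is the rate per accessible alternative A-site placement;
    it has no directly measured value and defaults to 2e-3 s^-1, slow
    relative to elongation and termination.
    """

    k_fast: float = 12.0
    k_slow_AAA: float = 0.0005
    k_slow_AAG: float = 0.009
    k_slide_unit: float = 0.002
    k_term: float = 0.0
    k_next: float | None = None
    min_A_run: int = 5
    min_lys_run_slow: int = 4
    t_max: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_fast", "k_slow_AAA", "k_slow_AAG", "k_slide_unit", "k_term"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_next is not None and self.k_next < 0:
            raise ValueError("k_next must be >= 0 or None")
        if self.min_A_run < 3:
            raise ValueError("min_A_run must be >= 3")
        if self.min_lys_run_slow < 2:
            raise ValueError("min_lys_run_slow must be >= 2")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass
class RibosomeState:
    """Position, frame and peptide tally of one ribosome."""

    a_site_nt: int
    peptide: list[str]
    lysines_added: int = 0
    last_aa_lysine: bool = False
    status: str = ELONGATING
    start_index: int = 0

    @property
    def frame_offset(self) -> int:
        return (self.a_site_nt - self.start_index) % 3


@dataclass(frozen=True)
class TrajectoryResult:
    """Final state plus the event log of one Gillespie trajectory."""

    state: RibosomeState
    events: list[tuple[float, str, int, int]]  # (t, event, a_site_nt, frame)
    n_slides: int


@dataclass(frozen=True)
class ProductSummary:
    """Ensemble product classification.

    full_length + truncated_oof + stalled = 1; ``fraction_extended`` counts
    trajectories whose lysine tally exceeds the encoded in-frame lysine
    count and can overlap the other categories.
    """

    n_trajectories: int
    fraction_full_length: float
    fraction_truncated_oof: float
    fraction_stalled: float
    fraction_extended: float
    peptide_length_histogram: dict[int, int]
    mean_slide_events: float


def find_a_runs(mrna: MrnaTemplate | str) -> list[tuple[int, int]]:
    """Maximal all-A nucleotide intervals as (start_nt, length), ordered."""
    seq = mrna.sequence if isinstance(mrna, MrnaTemplate) else mrna
    return [(m.start(), m.end() - m.start()) for m in re.finditer(r"A+", seq)]


def _qualifying_runs(mrna: MrnaTemplate, min_len: int) -> list[tuple[int, int]]:
    return [(s, ln) for s, ln in find_a_runs(mrna) if ln >= min_len]


def _overlapping_runs(
    runs: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Runs sharing at least one nucleotide with [lo, hi)."""
    return [(s, ln) for s, ln in runs if s < hi and s + ln > lo]


def _focal_runs(
    mrna: MrnaTemplate, a_site_nt: int, min_len: int
) -> list[tuple[int, int]]:
    """Qualifying A-runs touched by the A-site codon or the P-site codon."""
    runs = _qualifying_runs(mrna, min_len)
    lo = max(a_site_nt - 3, 0)  # P-site codon start (if any)
    return _overlapping_runs(runs, lo, a_site_nt + 3)


def allowed_slide_offsets(
    state: RibosomeState | int, mrna: MrnaTemplate, params: SlidingParams
) -> list[int]:
    """Displacements d != 0 available to a slippage event.

    Nonempty only when the A-site codon or the P-site codon touches a
    maximal A-run of length >= ``min_A_run``; each allowed d repositions the
    A-site codon wholly on A's inside that run. Both directions are allowed.
    """
    a = state.a_site_nt if isinstance(state, RibosomeState) else int(state)
    offsets: set[int] = set()
    for run_start, run_len in _focal_runs(mrna, a, params.min_A_run):
        # placements p with [p, p+3) inside [run_start, run_start+run_len)
        for p in range(run_start, run_start + run_len - 2):
            d = p - a
            if d != 0:
                offsets.add(d)
    return sorted(offsets)


def _in_reading_lysine_run_length(mrna: MrnaTemplate, a: int) -> int:
    """Length of the maximal consecutive-lysine-codon block containing the
    A-site codon, read in the frame implied by ``a``."""
    seq = mrna.sequence
    if seq[a : a + 3] not in LYSINE_CODONS:
        return 0
    n = 1
    p = a - 3
    while p >= 0 and seq[p : p + 3] in LYSINE_CODONS:
        n += 1
        p -= 3
    p = a + 3
    while p + 3 <= len(seq) and seq[p : p + 3] in LYSINE_CODONS:
        n += 1
        p += 3
    return n


def _is_first_codon_past_run(mrna: MrnaTemplate, a: int, params: SlidingParams) -> bool:
    """True when the A-site codon is the first codon beyond a focal A-run in
    its own reading: it either straddles the run's 3' boundary or starts
    exactly at the run end."""
    for run_start, run_len in _qualifying_runs(mrna, params.min_A_run):
        end = run_start + run_len
        if a == end:
            return True
        if a < end < a + 3 and a >= run_start:
            return True
    return False


def step_rates(
    state: RibosomeState, mrna: MrnaTemplate, params: SlidingParams
) -> dict[str, float]:
    """Competing event rates for an elongating ribosome; zero rates omitted.

    An empty map means the trajectory is frozen (it will be recorded as
    stalled at t_max).
    """
    if state.status != ELONGATING:
        raise ValueError("step_rates requires an elongating state")
    a = state.a_site_nt
    codon = mrna.codon_at(a)
    rates: dict[str, float] = {}

    if len(codon) == 3:
        if codon in STOP_CODONS:
            if params.k_term > 0:
                rates[TERMINATE] = params.k_term
        else:
            if params.k_next is not None and _is_first_codon_past_run(mrna, a, params):
                k = params.k_next
            elif (
                codon in LYSINE_CODONS
                and state.last_aa_lysine
                and _in_reading_lysine_run_length(mrna, a) >= params.min_lys_run_slow
            ):
                k = params.k_slow_AAA if codon == "AAA" else params.k_slow_AAG
            else:
                k = params.k_fast
            if k > 0:
                rates[ELONGATE] = k

    offsets = allowed_slide_offsets(state, mrna, params)
    if offsets and params.k_slide_unit > 0:
        rates[SLIDE] = params.k_slide_unit * len(offsets)
    return rates


def _initial_state(mrna: MrnaTemplate) -> RibosomeState:
    return RibosomeState(
        a_site_nt=mrna.start_index + 3,
        peptide=["M"],
        lysines_added=0,
        last_aa_lysine=False,
        status=ELONGATING,
        start_index=mrna.start_index,
    )


def simulate_ribosome(
    mrna: MrnaTemplate,
    params: SlidingParams,
    rng: np.random.Generator | None = None,
) -> TrajectoryResult:
    """One Gillespie trajectory: exponential waits, categorical event choice.

    The log records (t, event, a_site_nt, frame_offset) after each event.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = _initial_state(mrna)
    t = 0.0
    events: list[tuple[float, str, int, int]] = []
    n_slides = 0
    while True:
        if state.a_site_nt + 3 > len(mrna.sequence):
            state.status = OUT_OF_TEMPLATE
            break
        rates = step_rates(state, mrna, params)
        total = sum(rates.values())
        if total <= 0.0:
            state.status = STALLED
            t = params.t_max
            break
        t += rng.exponential(1.0 / total)
        if t > params.t_max:
            state.status = STALLED
            t = params.t_max
            break
        names = list(rates)
        probs = np.array([rates[n] for n in names]) / total
        event = names[rng.choice(len(names), p=probs)]
        if event == ELONGATE:
            codon = mrna.codon_at(state.a_site_nt)
            aa = _CODON_AA[codon]
            state.peptide.append(aa)
            if aa == "K":
                state.lysines_added += 1
                state.last_aa_lysine = True
            else:
                state.last_aa_lysine = False
            state.a_site_nt += 3
        elif event == SLIDE:
            offsets = allowed_slide_offsets(state, mrna, params)
            d = offsets[rng.choice(len(offsets))]
            state.a_site_nt += d
            n_slides += 1
        else:  # TERMINATE
            state.status = RELEASED
        events.append((t, event, state.a_site_nt, state.frame_offset))
        if state.status == RELEASED:
            break
    return TrajectoryResult(state=state, events=events, n_slides=n_slides)


def encoded_lysine_count(mrna: MrnaTemplate) -> int:
    """Number of lysine codons read in frame 0 from start to annotated stop."""
    n = 0
    for i in range(mrna.start_index, mrna.annotated_stop_index, 3):
        if mrna.codon_at(i) in LYSINE_CODONS:
            n += 1
    return n


def classify(result: TrajectoryResult, mrna: MrnaTemplate) -> str:
    """full_length / truncated_oof / stalled for one trajectory."""
    st = result.state
    if st.status == RELEASED:
        if st.a_site_nt == mrna.annotated_stop_index and st.frame_offset == 0:
            return "full_length"
        return "truncated_oof"
    return "stalled"


def simulate_ensemble(
    mrna: MrnaTemplate, params: SlidingParams, n: int
) -> ProductSummary:
    """n independent trajectories with per-trajectory seed substreams.

    Trajectory i draws from a generator seeded by
    ``SeedSequence(params.seed, spawn_key=(i,))``, so results are
    reproducible regardless of execution order.
    """
    if n < 1:
        raise ValueError("need at least one trajectory")
    counts = {"full_length": 0, "truncated_oof": 0, "stalled": 0}
    n_extended = 0
    hist: dict[int, int] = {}
    slides = 0.0
    encoded_k = encoded_lysine_count(mrna)
    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        )
        res = simulate_ribosome(mrna, params, rng=rng)
        counts[classify(res, mrna)] += 1
        if res.state.lysines_added > encoded_k:
            n_extended += 1
        plen = len(res.state.peptide)
        hist[plen] = hist.get(plen, 0) + 1
        slides += res.n_slides
    return ProductSummary(
        n_trajectories=n,
        fraction_full_length=counts["full_length"] / n,
        fraction_truncated_oof=counts["truncated_oof"] / n,
        fraction_stalled=counts["stalled"] / n,
        fraction_extended=n_extended / n,
        peptide_length_histogram=dict(sorted(hist.items())),
        mean_slide_events=slides / n,
    )


# ---------------------------------------------------------------------------
# exact CTMC oracle


def _ctmc_states_and_generator(
    mrna: MrnaTemplate, params: SlidingParams, lys_cap: int, max_states: int
):
    """Enumerate reachable states and build the sparse generator.

    State = (a_site_nt, last_aa_lysine, min(lysines_added, lys_cap), status)
    with status in {elongating, released, out_of_template}. Released and
    out-of-template states are absorbing.
    """
    init = (mrna.start_index + 3, False, 0, ELONGATING)
    index: dict[tuple, int] = {init: 0}
    order: list[tuple] = [init]
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    frontier = [init]

    def idx(s: tuple) -> int:
        if s not in index:
            if len(index) >= max_states:
                raise ValueError(f"CTMC state-space cap {max_states} exceeded")
            index[s] = len(order)
            order.append(s)
            frontier.append(s)
        return index[s]

    while frontier:
        s = frontier.pop()
        a, last_lys, k, status = s
        if status != ELONGATING:
            continue
        if a + 3 > len(mrna.sequence):
            # runaway: transition instantaneously in classification terms is
            # not expressible in a CTMC; treat as an absorbing state reached
            # with the rates that led here (handled by parent transitions).
            continue
        state = RibosomeState(
            a_site_nt=a,
            peptide=[],
            lysines_added=k,
            last_aa_lysine=last_lys,
            status=ELONGATING,
            start_index=mrna.start_index,
        )
        rates = step_rates(state, mrna, params)
        si = index[s]
        out = 0.0
        for event, rate in rates.items():
            if event == ELONGATE:
                codon = mrna.codon_at(a)
                aa = _CODON_AA[codon]
                k2 = min(k + 1, lys_cap) if aa == "K" else k
                a2 = a + 3
                if a2 + 3 > len(mrna.sequence) and mrna.codon_at(a2) not in STOP_CODONS:
                    tgt = (a2, aa == "K", k2, OUT_OF_TEMPLATE)
                else:
                    tgt = (a2, aa == "K", k2, ELONGATING)
                rows.append(idx(tgt)); cols.append(si); vals.append(rate)
                out += rate
            elif event == SLIDE:
                offsets = allowed_slide_offsets(a, mrna, params)
                per = params.k_slide_unit
                for d in offsets:
                    tgt = (a + d, last_lys, k, ELONGATING)
                    rows.append(idx(tgt)); cols.append(si); vals.append(per)
                out += per * len(offsets)
            else:  # TERMINATE
                tgt = (a, last_lys, k, RELEASED)
                rows.append(idx(tgt)); cols.append(si); vals.append(rate)
                out += rate
        if out > 0:
            rows.append(si); cols.append(si); vals.append(-out)

    n = len(order)
    gen = csr_matrix((vals, (rows, cols)), shape=(n, n))
    return order, index, gen


def exact_distribution(
    mrna: MrnaTemplate,
    params: SlidingParams,
    t: float | None = None,
    lys_cap: int = 12,
    max_states: int = 10_000,
) -> dict[tuple, float]:
    """Exact state distribution of the model's CTMC at time t.

    Solves dp/dt = Q p over the reachable state space
    (position x last-aa x capped lysine tally x status). Defaults
    ``t`` to ``params.t_max``. Probabilities sum to 1 within 1e-9.

    Raises
    ------
    ValueError
        If the reachable state space exceeds ``max_states``.
    """
    if t is None:
        t = params.t_max
    if t < 0:
        raise ValueError("negative time")
    order, _index, gen = _ctmc_states_and_generator(mrna, params, lys_cap, max_states)
    p0 = np.zeros(len(order))
    p0[0] = 1.0
    if t == 0:
        return {order[0]: 1.0}
    kwargs = {}
    if gen.shape[0] <= 600:  # dense Jacobian helps the stiff solver
        dense = gen.toarray()
        kwargs["jac"] = lambda _t, _p: dense
    sol = solve_ivp(
        lambda _t, p: gen.dot(p),
        (0.0, t),
        p0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
        t_eval=[t],
        **kwargs,
    )
    if not sol.success:
        raise RuntimeError(f"CTMC integration failed: {sol.message}")
    p = sol.y[:, -1]
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return {s: float(pi) for s, pi in zip(order, p) if pi > 0}


def exact_category_probabilities(
    mrna: MrnaTemplate,
    params: SlidingParams,
    t: float | None = None,
    lys_cap: int = 12,
    max_states: int = 10_000,
) -> dict[str, float]:
    """Exact full_length / truncated_oof / stalled / extended probabilities.

    Same classification rule as :func:`simulate_ensemble` applied to the
    exact CTMC distribution at time t (default ``t_max``).
    """
    dist = exact_distribution(mrna, params, t=t, lys_cap=lys_cap, max_states=max_states)
    encoded_k = encoded_lysine_count(mrna)
    out = {"full_length": 0.0, "truncated_oof": 0.0, "stalled": 0.0, "extended": 0.0}
    for (a, _last, k, status), p in dist.items():
        if status == RELEASED:
            frame = (a - mrna.start_index) % 3
            if a == mrna.annotated_stop_index and frame == 0:
                out["full_length"] += p
            else:
                out["truncated_oof"] += p
        else:
            out["stalled"] += p
        if k > encoded_k:
            out["extended"] += p
    return out
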