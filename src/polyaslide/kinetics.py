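"""Sequential first-order kinetics of stepwise lysine incorporation.

The peptide species on an iterated-lysine message form an irreversible chain

    M --k1--> MK --k2--> MK2 --k3--> ... --kn--> MKn  (absorbing),

with unit total mass and X(0) = (1, 0, ..., 0). Species fractions follow the
classic closed form for a linear chain of first-order steps (the Bateman
solution): for species i < n,

    X_i(t) = (k1 ... ki) * sum_{j<=i} exp(-k_{j+1} t)
                               / prod_{m<=i, m != j} (k_{m+1} - k_{j+1}),

and the absorbing terminal species carries the remaining mass. The Bateman
coefficients divide by pairwise rate differences, so near-equal rate pairs
are routed to a uniformization evaluation of the same chain instead
(all-non-negative terms, no cancellation; the two routes agree to ~1e-12
away from the degenerate region).

Rate constants are observed per-step aggregates (they fold together tRNA
binding, peptidyl transfer, translocation, ...), in s^-1; times in seconds.

Fitting mirrors experimental practice on quench time courses: either
*iteratively* — k1 from the disappearance of M alone, then each subsequent
k_i from the appearance/decay of the previous species with earlier rates
frozen — or *globally*, letting all rates float against all species columns
at once. Both use unweighted least squares on fractions with rates
log-parameterized for positivity. Terminal species that co-migrate on a gel
(e.g. MK4/MK5) can be lumped into one observable with :func:`lump_tail`;
the lumped chain is itself a shorter chain, so the same fitters apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticRateSet",
    "TimeCourse",
    "FitResult",
    "species_fractions",
    "fractions_matrix",
    "simulate_timecourse",
    "lump_tail",
    "fit_iterative",
    "fit_global",
    "default_species_names",
]

# relative gap below which Bateman coefficients are considered degenerate
_DEGENERATE_RTOL = 1e-6
_LOG_K_BOUNDS = (-30.0, 12.0)  # k in [~1e-13, ~1.6e5] s^-1
_MAX_NFEV = 10_000


@dataclass(frozen=True)
class KineticRateSet:
    """Ordered step rate constants k1..kn of the incorporation chain, s^-1."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rates) < 1:
            raise ValueError("need at least one rate")
        if any(k < 0 for k in self.rates):
            raise ValueError(f"negative rate in {self.rates}")
        object.__setattr__(self, "rates", tuple(float(k) for k in self.rates))

    @property
    def n_steps(self) -> int:
        return len(self.rates)

    @property
    def n_species(self) -> int:
        return len(self.rates) + 1


def default_species_names(n_species: int) -> list[str]:
    """M, MK, MK2, ... naming for a chain with ``n_species`` members."""
    names = []
    for i in range(n_species):
        if i == 0:
            names.append("M")
        elif i == 1:
            names.append("MK")
        else:
            names.append(f"MK{i}")
    return names


@dataclass
class TimeCourse:
    """Sampled species-fraction trajectories of the chain.

    ``fractions`` has shape (n_times, n_species), species in chain order.
    ``lumped_from`` marks that columns >= that original species index were
    aggregated into the final column (co-migrating bands).
    """

    times: np.ndarray
    fractions: np.ndarray
    species: list[str] = field(default_factory=list)
    lumped_from: int | None = None
    flagged_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        if self.times.ndim != 1 or self.fractions.shape[0] != self.times.size:
            raise ValueError("times/fractions shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("negative time")
        if not self.species:
            self.species = default_species_names(self.fractions.shape[1])
        if len(self.species) != self.fractions.shape[1]:
            raise ValueError("species names do not match fraction columns")

    @property
    def n_species(self) -> int:
        return self.fractions.shape[1]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a rate-constant fit."""

    estimates: KineticRateSet
    per_species_r2: tuple[float, ...]
    method: str
    residual_ss: float
    converged: bool
    n_evaluations: int


def _is_degenerate(rates: Sequence[float]) -> bool:
    k = np.asarray(rates, dtype=float)
    kmax = k.max(initial=0.0)
    if kmax == 0.0:
        return False  # frozen chain handled exactly
    diffs = np.abs(k[:, None] - k[None, :])
    np.fill_diagonal(diffs, np.inf)
    return bool(diffs.min() < _DEGENERATE_RTOL * kmax)


def _bateman_matrix(rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Closed-form species fractions, shape (n_times, n_steps + 1)."""
    k = np.asarray(rates, dtype=float)
    n = k.size
    t = np.asarray(times, dtype=float)
    out = np.zeros((t.size, n + 1))
    exps = np.exp(-np.outer(t, k))  # (n_times, n)
    # cumulative rate products k1..ki
    prod_k = np.cumprod(k)
    out[:, 0] = exps[:, 0]
    for i in range(1, n):
        # coefficients c_j = 1 / prod_{m<=i, m!=j} (k_{m+1} - k_{j+1})
        acc = np.zeros(t.size)
        for j in range(i + 1):
            denom = 1.0
            for m in range(i + 1):
                if m != j:
                    denom *= k[m] - k[j]
            acc += exps[:, j] / denom
        out[:, i] = prod_k[i - 1] * acc
    out[:, n] = 1.0 - out[:, :n].sum(axis=1)
    np.clip(out, 0.0, 1.0, out=out)
    return out


def _uniformized_matrix(rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Degenerate-safe chain evaluation by uniformization.

    Writes the chain as a uniformized DTMC, p(t) = sum_m Pois(m; L t) p0 P^m
    with L = max rate and P = I + Q/L. All terms are non-negative, so there
    is no cancellation; truncation of the Poisson tail at 1e-15 bounds the
    error. Stable where the Bateman coefficients (and scipy's expm on the
    stiff non-normal generator) lose accuracy.
    """
    from scipy.stats import poisson

    k = np.asarray(rates, dtype=float)
    n = k.size
    lam = float(k.max())
    # one-step DTMC: from i<n stay with 1 - k_i/lam, advance with k_i/lam
    advance = k / lam
    stay = 1.0 - advance
    t = np.asarray(times, dtype=float)
    out = np.empty((t.size, n + 1))
    for r, ti in enumerate(t):
        lt = lam * ti
        m_max = int(lt + 12.0 * np.sqrt(lt + 1.0) + 35.0)
        weights = poisson.pmf(np.arange(m_max + 1), lt)
        v = np.zeros(n + 1)
        v[0] = 1.0
        acc = weights[0] * v
        for m in range(1, m_max + 1):
            nxt = np.empty(n + 1)
            nxt[:n] = v[:n] * stay
            nxt[1:n] += v[: n - 1] * advance[: n - 1]
            nxt[n] = v[n] + v[n - 1] * advance[n - 1]
            v = nxt
            if weights[m] > 0.0:
                acc = acc + weights[m] * v
        out[r] = acc
    np.clip(out, 0.0, 1.0, out=out)
    return out


def fractions_matrix(rates: Sequence[float], times: np.ndarray) -> np.ndarray:
    """Species fractions at each time; rows sum to 1.

    Uses the Bateman closed form, falling back to uniformization when
    any two rates are within 1e-6 relative of each other (the closed-form
    coefficients divide by rate differences).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative time")
    rs = KineticRateSet(tuple(rates))  # validates non-negativity
    if max(rs.rates) == 0.0:  # frozen chain: all mass stays in M
        out = np.zeros((times.size, rs.n_species))
        out[:, 0] = 1.0
        return out
    if _is_degenerate(rs.rates):
        return _uniformized_matrix(rs.rates, times)
    return _bateman_matrix(rs.rates, times)


def species_fractions(rates: KineticRateSet | Sequence[float], t: float) -> np.ndarray:
    """Species-fraction vector (M, MK, ..., MKn) at a single time t >= 0."""
    if isinstance(rates, KineticRateSet):
        rates = rates.rates
    return fractions_matrix(rates, np.asarray([t]))[0]


def simulate_timecourse(
    rates: KineticRateSet | Sequence[float], times: Sequence[float]
) -> TimeCourse:
    """Noise-free time course of the chain at the given times."""
    if isinstance(rates, KineticRateSet):
        rates = rates.rates
    times = np.asarray(times, dtype=float)
    return TimeCourse(times=times, fractions=fractions_matrix(rates, times))


def lump_tail(tc: TimeCourse, j: int) -> TimeCourse:
    """Aggregate species columns >= j into one terminal observable.

    Models co-migrating terminal gel bands. Row sums are preserved; the
    result records ``lumped_from = j``.
    """
    if not 1 <= j < tc.n_species:
        raise ValueError(f"lump index {j} out of range for {tc.n_species} species")
    if j == tc.n_species - 1:
        return replace(tc, lumped_from=j)
    head = tc.fractions[:, :j]
    tail = tc.fractions[:, j:].sum(axis=1, keepdims=True)
    names = tc.species[:j] + [f"{tc.species[j]}plus"]
    return TimeCourse(
        times=tc.times.copy(),
        fractions=np.hstack([head, tail]),
        species=names,
        lumped_from=j,
        flagged_rows=list(tc.flagged_rows),
    )


def _column_model(free_log_k: np.ndarray, frozen: Sequence[float], times, col):
    """Model for species column ``col`` given frozen earlier rates."""
    rates = list(frozen) + [float(np.exp(free_log_k[0]))]
    # later rates do not influence column `col`; pad with zeros
    return fractions_matrix(rates, times)[:, col]

def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ssr = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst < 1e-15:
        return 1.0 if ssr < 1e-12 else float("-inf")
    return 1.0 - ssr / sst


def _initial_guess(times: np.ndarray, column: np.ndarray, col_index: int) -> float:
    """Heuristic rate init: half-life of M, else reciprocal time-of-peak."""
    if col_index == 0:
        below = np.nonzero(column <= 0.5)[0]
        if below.size:
            t_half = max(times[below[0]], times[times > 0].min(initial=1.0))
            return float(np.log(2.0) / t_half)
        return 1.0 / float(times[-1])
    t_peak = times[int(np.argmax(column))]
    if t_peak <= 0:
        t_peak = times[-1]
    return 1.0 / float(t_peak)


def fit_iterative(tc: TimeCourse, n_steps: int | None = None) -> FitResult:
    """Fit rates one at a time along the chain.

    k1 is fit by nonlinear least squares to the M column alone
    (mono-exponential decay); each subsequent k_i is fit to the previous
    species' column with all earlier rates frozen. Positivity is enforced by
    log-parameterization. Non-convergence returns ``converged=False`` with
    the best estimate rather than raising.

    ``n_steps`` defaults to (number of species columns) - 1; a lumped time
    course is treated as the equivalent shorter chain.
    """
    if n_steps is None:
        n_steps = tc.n_species - 1
    if n_steps != tc.n_species - 1:
        raise ValueError(
            f"n_steps={n_steps} inconsistent with {tc.n_species} species columns"
        )
    if tc.times.size < 2 * n_steps:
        raise ValueError("need at least 2 time points per step")
    rates: list[float] = []
    total_nfev = 0
    converged = True
    for i in range(n_steps):
        col = tc.fractions[:, i]
        k0 = _initial_guess(tc.times, col, i)
        best = None
        for scale in (1.0, 0.1, 10.0):
            x0 = np.clip(np.log(k0 * scale), _LOG_K_BOUNDS[0] + 1e-9, _LOG_K_BOUNDS[1] - 1e-9)
            res = least_squares(
                lambda p: _column_model(p, rates, tc.times, i) - col,
                x0=[x0],
                bounds=([_LOG_K_BOUNDS[0]], [_LOG_K_BOUNDS[1]]),
                max_nfev=_MAX_NFEV,
            )
            total_nfev += res.nfev
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < 1e-18:
                break
        converged = converged and bool(best.success)
        rates.append(float(np.exp(best.x[0])))
    estimates = KineticRateSet(tuple(rates))
    model = fractions_matrix(estimates.rates, tc.times)
    r2 = tuple(_r2(tc.fractions[:, i], model[:, i]) for i in range(tc.n_species))
    ss = float(np.sum((tc.fractions - model) ** 2))
    return FitResult(
        estimates=estimates,
        per_species_r2=r2,
        method="iterative",
        residual_ss=ss,
        converged=converged,
        n_evaluations=total_nfev,
    )


def fit_global(
    tc: TimeCourse,
    n_steps: int | None = None,
    init: KineticRateSet | None = None,
) -> FitResult:
    """Fit all rates simultaneously to all species columns.

    Minimizes the total sum of squared residuals over every column at once,
    log-parameterized; the starting point defaults to the iterative fit.
    """
    if n_steps is None:
        n_steps = tc.n_species - 1
    if n_steps != tc.n_species - 1:
        raise ValueError(
            f"n_steps={n_steps} inconsistent with {tc.n_species} species columns"
        )
    nfev0 = 0
    if init is None:
        seed_fit = fit_iterative(tc, n_steps)
        init = seed_fit.estimates
        nfev0 = seed_fit.n_evaluations
    x0 = np.log(np.clip(init.rates, np.exp(_LOG_K_BOUNDS[0]), np.exp(_LOG_K_BOUNDS[1])))

    def residuals(log_k: np.ndarray) -> np.ndarray:
        model = fractions_matrix(np.exp(log_k), tc.times)
        return (model - tc.fractions).ravel()

    res = least_squares(
        residuals,
        x0=x0,
        bounds=(
            np.full(n_steps, _LOG_K_BOUNDS[0]),
            np.full(n_steps, _LOG_K_BOUNDS[1]),
        ),
        max_nfev=_MAX_NFEV,
    )
    estimates = KineticRateSet(tuple(np.exp(res.x)))
    model = fractions_matrix(estimates.rates, tc.times)
    r2 = tuple(_r2(tc.fractions[:, i], model[:, i]) for i in range(tc.n_species))
    ss = float(np.sum((tc.fractions - model) ** 2))
    return FitResult(
        estimates=estimates,
        per_species_r2=r2,
        method="global",
        residual_ss=ss,
        converged=bool(res.success),
        n_evaluations=nfev0 + res.nfev,
    )
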