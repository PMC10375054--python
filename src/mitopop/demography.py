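"""Demographic inference: neutrality tests, mismatch distributions, dating.

Tajima's D contrasts the pairwise-difference estimator of theta (k_hat)
with the segregating-sites estimator (S / a1), normalised by the usual
constants computed from the sample size; strongly negative values indicate
an excess of rare variants, as produced by recent population expansion (or
purifying selection).  Its significance is assessed by conditional
coalescent simulation (constant size, theta set to Watterson's estimate),
the same approach Arlequin takes, rather than the beta approximation.

Fu's Fs is the log-odds ln(S'/(1-S')) where S' is the probability, under
the Ewens sampling formula with theta estimated from mean pairwise
differences, of observing at least as many distinct haplotypes as sampled.
The Ewens probabilities P(K = k) = |s(n, k)| theta^k / theta^(n) (rising
factorial) are computed with unsigned Stirling numbers of the first kind
via a log-space recursion, so the statistic is stable up to large n.
Following the original convention, Fs is declared significant at the
nominal 5% level when its one-tailed simulation p-value is below 0.02.

The mismatch (pairwise difference) distribution is compared with the
sudden-expansion model: a population at equilibrium theta0 grows
instantaneously to theta1 at mutational time tau = 2ut before present.
The transient class probabilities are

    F_i(tau, theta0, theta1) = F_i(theta1)
        + exp(-tau (theta1 + 1) / theta1)
          * sum_{j<=i} [F_j(theta0) - F_j(theta1)] tau^{i-j} / (i-j)!

with the geometric equilibrium F_i(theta) = theta^i / (1 + theta)^{i+1}.
Parameters are fitted by minimising the sum of squared deviations (SSD)
between observed and expected class frequencies; goodness of fit uses a
parametric bootstrap (simulate under the fitted model, refit, compare SSD
and Harpending's raggedness).  tau converts to years via tau = 2ut with
u the per-sequence per-generation mutation rate.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .alignment import SequenceAlignment, classify_sites
from .errors import ConfigurationError, UndefinedStatisticError
from .structure import pairwise_diff_comparable
from . import simulate as sim

__all__ = [
    "tajima_constants",
    "tajimas_d",
    "tajimas_d_from_stats",
    "tajima_d_pvalue",
    "fus_fs",
    "fs_pvalue",
    "mismatch_observed",
    "mismatch_expected",
    "raggedness",
    "MismatchFit",
    "fit_sudden_expansion",
    "gof_bootstrap",
    "ExpansionTimeEstimate",
    "expansion_time",
    "parse_rate",
    "neutrality_tests",
    "FS_SIGNIFICANCE_LEVEL",
]

#: One-tailed p-value threshold at which Fu's Fs is significant at nominal 5%.
FS_SIGNIFICANCE_LEVEL = 0.02


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 normalisation constants for sample size n."""
    if n < 2:
        raise UndefinedStatisticError("constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d_from_stats(n: int, s: int, k_hat: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D requires n >= 4")
    if s == 0:
        warnings.warn("S = 0: Tajima's D undefined (no segregating sites)")
        return float("nan")
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * s + c["e2"] * s * (s - 1))
    return (k_hat - s / c["a1"]) / denom


def _subset_stats(aln: SequenceAlignment) -> tuple[int, int, float]:
    """(n, S, k_hat) for an alignment (pairwise masking for k_hat)."""
    s = classify_sites(aln).n_variable
    diffs, _ = pairwise_diff_comparable(aln.matrix())
    iu = np.triu_indices(aln.n_sequences, k=1)
    k_hat = float(diffs[iu].mean())
    return aln.n_sequences, s, k_hat


def tajimas_d(aln: SequenceAlignment) -> float:
    """Tajima's D for an alignment (use ``aln.subset(pop)`` for one population)."""
    n, s, k_hat = _subset_stats(aln)
    return tajimas_d_from_stats(n, s, k_hat)


def tajima_d_pvalue(
    d_obs: float,
    n: int,
    s_obs: int,
    n_sims: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-tailed p-value for Tajima's D by conditional coalescent simulation.

    Neutral constant-size genealogies of size n are simulated with theta set
    to Watterson's estimate S / a1; the lower tail is the fraction of
    simulated D* <= D and the reported p-value is min(2 * tail, 1), which is
    calibrated for the expansion-detection (negative) direction.
    """
    if math.isnan(d_obs):
        raise UndefinedStatisticError("D is undefined; no p-value")
    if n_sims < 100:
        warnings.warn(f"n_sims = {n_sims} is small; p-value will be coarse")
    theta_w = s_obs / tajima_constants(n)["a1"]
    rng = np.random.default_rng(seed)
    lower = 0
    usable = 0
    for _ in range(n_sims):
        gen = sim.simulate_genealogy(n, rng)
        muts = sim.mutation_counts(gen, theta_w, rng)
        s_star, k_star, _ = sim.branch_statistics(gen, muts)
        if s_star == 0:
            continue
        usable += 1
        if tajimas_d_from_stats(n, s_star, k_star) <= d_obs:
            lower += 1
    if usable == 0:
        return float("nan")
    tail = (lower + 1) / (usable + 1)
    return min(2.0 * tail, 1.0)


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """ln |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        nxt = np.full(len(row) + 1, -np.inf)
        # |s(m+1,k)| = m |s(m,k)| + |s(m,k-1)|
        with np.errstate(divide="ignore"):
            scaled = row + (math.log(m) if m > 0 else -np.inf)
        nxt[: len(row)] = scaled
        nxt[1:] = np.logaddexp(nxt[1:], row)
        row = nxt[: m + 2]
    return row


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S'/(1 - S')), S' = P(K >= k_obs) under the Ewens formula.

    Parameters
    ----------
    n
        Sample size (>= 2).
    k_obs
        Observed number of distinct haplotypes (1 <= k_obs <= n).
    theta
        Scaled mutation rate, estimated from mean pairwise differences.

    Returns +inf when k_obs = 1 (the cumulative tail is 1).
    """
    if n < 2:
        raise UndefinedStatisticError("Fu's Fs requires n >= 2")
    if not 1 <= k_obs <= n:
        raise ConfigurationError(f"k_obs must be in [1, {n}]; got {k_obs}")
    if theta <= 0:
        raise UndefinedStatisticError("Fu's Fs requires theta > 0")
    if k_obs == 1:
        return float("inf")
    log_theta = math.log(theta)
    ls = _log_stirling_row(n)
    k = np.arange(1, n + 1)
    terms = ls[1:] + k * log_theta  # unnormalised ln P(K = k)
    upper = logsumexp(terms[k_obs - 1 :])
    lower = logsumexp(terms[: k_obs - 1])
    return float(upper - lower)


def fs_pvalue(
    fs_obs: float,
    n: int,
    theta: float,
    n_sims: int = 1000,
    seed: int | None = None,
) -> float:
    """p = P(Fs* <= Fs_obs) under neutral constant-size coalescent replicates.

    Note the convention: significance at the nominal 5% level is declared
    when p < 0.02 (see ``FS_SIGNIFICANCE_LEVEL``).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        gen = sim.simulate_genealogy(n, rng)
        muts = sim.mutation_counts(gen, theta, rng)
        _, k_hat_star, k_star = sim.branch_statistics(gen, muts)
        if k_star == 1 or k_hat_star <= 0:
            fs_star = float("inf")
        else:
            fs_star = fus_fs(n, k_star, k_hat_star)
        if fs_star <= fs_obs:
            hits += 1
    return (hits + 1) / (n_sims + 1)


# ---------------------------------------------------------------------------
# Mismatch distribution
# ---------------------------------------------------------------------------


def mismatch_observed(aln: SequenceAlignment) -> np.ndarray:
    """Normalised histogram of pairwise differences over classes 0..d_max."""
    if aln.n_sequences < 2:
        raise UndefinedStatisticError("mismatch distribution requires >= 2 sequences")
    diffs, _ = pairwise_diff_comparable(aln.matrix())
    iu = np.triu_indices(aln.n_sequences, k=1)
    vals = diffs[iu]
    freq = np.bincount(vals, minlength=int(vals.max()) + 1).astype(float)
    return freq / freq.sum()


def _geometric(theta: float, d_max: int) -> np.ndarray:
    i = np.arange(d_max + 1, dtype=float)
    if theta == 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def mismatch_expected(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Sudden-expansion model class probabilities, truncated and renormalised.

    With tau = 0 and theta0 = theta1 this reduces to the geometric
    equilibrium distribution.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ConfigurationError("tau, theta0 and theta1 must be >= 0")
    f0 = _geometric(theta0, d_max)
    f1 = _geometric(theta1, d_max)
    if theta1 > 0:
        decay = math.exp(-tau * (theta1 + 1.0) / theta1)
    else:
        decay = 1.0 if tau == 0 else 0.0
    if decay > 0:
        i = np.arange(d_max + 1, dtype=float)
        if tau == 0:
            pois = np.zeros(d_max + 1)
            pois[0] = 1.0
        else:
            pois = np.exp(i * math.log(tau) - gammaln(i + 1))
        transient = np.convolve(f0 - f1, pois)[: d_max + 1]
        f = f1 + decay * transient
    else:
        f = f1.copy()
    f = np.clip(f, 0.0, None)
    total = f.sum()
    if total == 0:
        f = np.zeros(d_max + 1)
        f[0] = 1.0
        return f
    return f / total


def raggedness(freqs) -> float:
    """Harpending's raggedness: sum of squared successive class differences,
    with an implicit zero class appended past the last observed class."""
    x = np.append(np.asarray(freqs, dtype=float), 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchFit:
    """Observed/expected mismatch distributions and fitted expansion parameters."""

    observed: np.ndarray
    expected: np.ndarray
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    ssd_pvalue: float | None = None
    raggedness_pvalue: float | None = None


def _grid_search(
    obs: np.ndarray,
    tau_grid: np.ndarray,
    theta0_grid: np.ndarray,
    theta1_grid: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Vectorised SSD over the full (tau, theta0, theta1) grid."""
    d_max = len(obs) - 1
    f0 = np.stack([_geometric(t, d_max) for t in theta0_grid])  # (G0, d+1)
    f1 = np.stack([_geometric(t, d_max) for t in theta1_grid])  # (G1, d+1)
    diff = f0[:, None, :] - f1[None, :, :]  # (G0, G1, d+1)
    i = np.arange(d_max + 1, dtype=float)
    best_val = np.inf
    best_x = None
    valid = theta0_grid[:, None] <= theta1_grid[None, :]  # (G0, G1)
    for tau in tau_grid:
        if tau == 0:
            pois = np.zeros(d_max + 1)
            pois[0] = 1.0
        else:
            pois = np.exp(i * math.log(tau) - gammaln(i + 1))
        # lower-triangular Toeplitz so conv(x, pois)[:d+1] = x @ P.T
        P = np.zeros((d_max + 1, d_max + 1))
        for r in range(d_max + 1):
            P[r, : r + 1] = pois[r::-1]
        with np.errstate(divide="ignore"):
            decay = np.where(
                theta1_grid > 0,
                np.exp(-tau * (theta1_grid + 1.0) / np.maximum(theta1_grid, 1e-300)),
                1.0 if tau == 0 else 0.0,
            )
        f = f1[None, :, :] + decay[None, :, None] * (diff @ P.T)
        f = np.clip(f, 0.0, None)
        totals = f.sum(axis=2, keepdims=True)
        f = np.where(totals > 0, f / np.maximum(totals, 1e-300), 0.0)
        ssd = np.sum((f - obs[None, None, :]) ** 2, axis=2)
        ssd = np.where(valid, ssd, np.inf)
        k = np.unravel_index(np.argmin(ssd), ssd.shape)
        if ssd[k] < best_val:
            best_val = float(ssd[k])
            best_x = np.array([tau, theta0_grid[k[0]], theta1_grid[k[1]]])
    return best_x, best_val


_TAU_BOUNDS = (0.0, 25.0)
_THETA0_BOUNDS = (0.0, 50.0)
_THETA1_MAX = 5000.0


def _clip_params(x: np.ndarray) -> tuple[float, float, float]:
    tau = float(np.clip(x[0], *_TAU_BOUNDS))
    theta0 = float(np.clip(x[1], *_THETA0_BOUNDS))
    theta1 = float(np.clip(x[2], theta0, _THETA1_MAX))
    return tau, theta0, theta1


def fit_sudden_expansion(observed, n: int | None = None, seed: int | None = None) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to a mismatch distribution.

    A coarse grid over (tau, theta0, theta1) seeds a Nelder-Mead refinement;
    parameters are constrained to tau in [0, 25], theta0 in [0, 50],
    theta1 in [theta0, 5000].  The fit itself is deterministic; ``seed`` is
    accepted for interface symmetry with the bootstrap helpers.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or len(obs) < 2:
        raise ConfigurationError("observed must be a 1-D vector with >= 2 classes")
    if not math.isclose(obs.sum(), 1.0, rel_tol=0, abs_tol=1e-6):
        raise ConfigurationError("observed mismatch frequencies must sum to 1")
    d_max = len(obs) - 1

    if np.count_nonzero(obs) == 1:
        warnings.warn("degenerate mismatch distribution (single class); tau fixed at 0")
        cls = int(np.flatnonzero(obs)[0])
        theta = float(cls)
        exp = mismatch_expected(0.0, theta, theta, d_max)
        return MismatchFit(
            observed=obs,
            expected=exp,
            tau=0.0,
            theta0=theta,
            theta1=theta,
            ssd=float(np.sum((obs - exp) ** 2)),
            raggedness=raggedness(obs),
        )

    def ssd_of(x: np.ndarray) -> float:
        tau, th0, th1 = _clip_params(x)
        exp = mismatch_expected(tau, th0, th1, d_max)
        return float(np.sum((obs - exp) ** 2))

    mean_d = float(np.sum(np.arange(d_max + 1) * obs))
    tau_grid = np.unique(
        np.concatenate(
            [
                np.linspace(0.0, min(_TAU_BOUNDS[1], max(2.0 * mean_d, 5.0)), 21),
                [mean_d],
            ]
        )
    )
    theta0_grid = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0])
    theta1_grid = np.array([0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0])
    best_x, best_val = _grid_search(obs, tau_grid, theta0_grid, theta1_grid)
    res = minimize(
        ssd_of,
        best_x,
        method="Nelder-Mead",
        options=dict(xatol=1e-5, fatol=1e-12, maxiter=600, maxfev=1200),
    )
    x = res.x if res.fun <= best_val else best_x
    tau, th0, th1 = _clip_params(x)
    exp = mismatch_expected(tau, th0, th1, d_max)
    return MismatchFit(
        observed=obs,
        expected=exp,
        tau=tau,
        theta0=th0,
        theta1=th1,
        ssd=float(np.sum((obs - exp) ** 2)),
        raggedness=raggedness(obs),
    )


def gof_bootstrap(
    fit: MismatchFit,
    n: int,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Coalescent samples of size n are simulated under the fitted expansion
    model (theta = theta1 at present, a growth_factor = theta1/theta0 change
    at scaled time tau/theta1), each replicate is refitted, and
    p = P(statistic* >= statistic_obs) with the (b+1)/(m+1) estimator.
    """
    if n_boot < 50:
        warnings.warn(f"n_boot = {n_boot} is small; p-values will be coarse")
    theta1 = max(fit.theta1, 1e-6)
    tau_scaled = fit.tau / theta1
    growth = theta1 / max(fit.theta0, theta1 * 1e-9)
    rng = np.random.default_rng(seed)
    hits_ssd = 0
    hits_rag = 0
    for _ in range(n_boot):
        gen = sim.simulate_genealogy(
            n, rng, tau_event=tau_scaled, growth_factor=growth
        )
        muts = sim.mutation_counts(gen, theta1, rng)
        obs_star = sim.mismatch_from_genealogy(gen, muts)
        if len(obs_star) < 2:
            obs_star = np.append(obs_star, 0.0)
        refit = fit_sudden_expansion(obs_star)
        if refit.ssd >= fit.ssd:
            hits_ssd += 1
        if refit.raggedness >= fit.raggedness:
            hits_rag += 1
    return (hits_ssd + 1) / (n_boot + 1), (hits_rag + 1) / (n_boot + 1)


# ---------------------------------------------------------------------------
# Expansion time
# ---------------------------------------------------------------------------


_RATE_RE = re.compile(
    r"^\s*([0-9.eE+-]+)\s*%\s*(?:/|per)\s*(?:million\s*years?|myr)\s*$",
    re.IGNORECASE,
)


def parse_rate(rate: "str | float") -> float:
    """Per-site per-year substitution rate from a number or a '%/Myr' string.

    ``"3.1%/Myr"`` (or ``"3.1% per million years"``) parses to 3.1e-8.
    """
    if isinstance(rate, (int, float)):
        return float(rate)
    m = _RATE_RE.match(rate)
    if m:
        return float(m.group(1)) / 100.0 / 1e6
    try:
        return float(rate)
    except ValueError as exc:
        raise ConfigurationError(f"cannot parse mutation rate {rate!r}") from exc


@dataclass
class ExpansionTimeEstimate:
    tau: float
    rate_per_site_per_year: float
    L: int
    generation_years: float
    u: float  # per-sequence per-generation mutation rate
    t_years: float


def expansion_time(
    tau: float,
    rate: "str | float",
    L: int,
    generation_years: float = 1.0,
    rate_convention: str = "per_lineage",
) -> ExpansionTimeEstimate:
    """Convert the fitted tau to years via tau = 2ut.

    Parameters
    ----------
    rate
        Per-site per-year substitution rate, or a '%/Myr' string.
    rate_convention
        ``"per_lineage"`` treats the rate as a single-lineage substitution
        rate (u = rate * L * generation); ``"pairwise"`` treats it as a
        divergence (between-lineage) rate, halving u.
    """
    r = parse_rate(rate)
    if r < 0 or L < 0 or generation_years < 0 or tau < 0:
        raise ConfigurationError("all expansion-time inputs must be >= 0")
    if rate_convention == "per_lineage":
        u = r * L * generation_years
    elif rate_convention == "pairwise":
        u = 0.5 * r * L * generation_years
    else:
        raise ConfigurationError(f"unknown rate convention {rate_convention!r}")
    if tau == 0:
        t = 0.0
    elif u == 0:
        raise UndefinedStatisticError("u = 0 with tau > 0: expansion time undefined")
    else:
        t = tau / (2.0 * u)
    return ExpansionTimeEstimate(
        tau=tau,
        rate_per_site_per_year=r,
        L=L,
        generation_years=generation_years,
        u=u,
        t_years=t,
    )


# ---------------------------------------------------------------------------
# Per-population summary
# ---------------------------------------------------------------------------


def neutrality_tests(
    aln: SequenceAlignment,
    n_sims: int = 1000,
    seed: int | None = None,
    populations: "tuple[str, ...] | None" = None,
) -> pd.DataFrame:
    """Tajima's D and Fu's Fs (with simulation p-values) per population."""
    pops = populations if populations is not None else aln.population_labels
    rng = np.random.default_rng(seed)
    rows = []
    for pop in pops:
        sub = aln.subset(pop)
        n, s, k_hat = _subset_stats(sub)
        d = tajimas_d_from_stats(n, s, k_hat)
        d_p = (
            tajima_d_pvalue(d, n, s, n_sims=n_sims, seed=int(rng.integers(2**31 - 1)))
            if not math.isnan(d)
            else float("nan")
        )
        k_obs = len(set(sub.sequences))
        if k_hat > 0:
            fs = fus_fs(n, k_obs, k_hat)
            fs_p = fs_pvalue(
                fs, n, k_hat, n_sims=n_sims, seed=int(rng.integers(2**31 - 1))
            )
        else:
            fs, fs_p = float("nan"), float("nan")
        rows.append(
            dict(
                population=pop,
                n=n,
                S=s,
                tajimas_d=d,
                d_pvalue=d_p,
                fus_fs=fs,
                fs_pvalue=fs_p,
            )
        )
    return pd.DataFrame(rows).set_index("population")
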