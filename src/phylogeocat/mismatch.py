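"""Mismatch distributions and the sudden-expansion demographic model.

The mismatch distribution is the histogram of pairwise nucleotide
differences among sampled sequences. Under a sudden demographic expansion
from scaled size θ0 to θ1 at τ units of mutational time before present
(τ = 2·u·t, with u the per-sequence per-generation mutation rate), the
distribution of the number of differences j between a random pair is

    F_j(τ, θ0, θ1) = F̂_j(θ1)
        + exp(-τ (θ1 + 1) / θ1) · Σ_{i=0..j} τ^{j-i}/(j-i)! · [F̂_i(θ0) - F̂_i(θ1)]

where F̂_j(θ) = θ^j / (1+θ)^{j+1} is the geometric equilibrium
distribution. Parameters are estimated by least squares between the
observed relative frequencies and F_j, and tested/CI'd by parametric
bootstrap. Expansion timing follows t = τ / (2u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .seqio import MissingPolicy, SequenceAlignment
from .popgen import pairwise_differences

THETA1_CAP = 99999.0


@dataclass(frozen=True)
class MismatchHistogram:
    """Pairwise-difference census: counts[d] pairs differ at d sites."""

    counts: tuple[int, ...]

    @property
    def n_pairs(self) -> int:
        return int(sum(self.counts))

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def mean(self) -> float:
        d = np.arange(len(self.counts))
        return float(np.dot(d, self.counts) / self.n_pairs)

    @property
    def relative(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pairs


def mismatch_histogram(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> MismatchHistogram:
    """Exact pairwise-difference histogram; its mean equals θπ."""
    if aln.n < 2:
        raise ValueError("mismatch histogram requires n >= 2")
    diff = pairwise_differences(aln, missing_policy)
    vals = diff[np.triu_indices(aln.n, 1)]
    counts = np.bincount(vals)
    return MismatchHistogram(counts=tuple(int(c) for c in counts))


def _equilibrium(theta: float, d_max: int) -> np.ndarray:
    """Geometric F̂_j(θ) = θ^j/(1+θ)^{j+1}; point mass at 0 when θ=0."""
    j = np.arange(d_max + 1)
    if theta <= 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    # log-space for large θ / d
    logf = j * np.log(theta) - (j + 1) * np.log1p(theta)
    return np.exp(logf)


def expected_mismatch(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Sudden-expansion mismatch probabilities F_j for j = 0..d_max.

    The full distribution over j = 0..∞ sums to 1; the returned vector is
    the truncation to d_max (use ``1 - vec.sum()`` for the tail mass).
    """
    for name, v in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    f1 = _equilibrium(theta1, d_max)
    if tau == 0:
        # no elapsed time: the pre-expansion equilibrium is what we observe
        return _equilibrium(theta0, d_max)
    f0 = _equilibrium(theta0, d_max)
    j = np.arange(d_max + 1)
    # log(tau^m / m!) for m = 0..d_max
    from scipy.special import gammaln

    log_pois = j * np.log(tau) - gammaln(j + 1)
    pois = np.exp(log_pois)
    delta = f0 - f1
    conv = np.array(
        [np.dot(pois[: jj + 1][::-1], delta[: jj + 1]) for jj in range(d_max + 1)]
    )
    # theta1 -> 0 makes the decay rate (theta1+1)/theta1 diverge: decay = 0
    decay = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else 0.0
    out = f1 + decay * conv
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SuddenExpansionFit:
    tau: float
    theta0: float
    theta1: float
    SSD: float
    p_SSD: float | None
    raggedness: float
    p_raggedness: float | None
    ci95: dict[str, tuple[float, float]] | None
    n_boot: int
    seed: int
    boundary_fit: bool = False


def raggedness(hist: MismatchHistogram) -> float:
    """Harpending's raggedness r = Σ (x_i - x_{i-1})² over i = 1..d+1.

    Relative frequencies x padded with zero beyond both ends, so a one-bin
    histogram has r = 1² + 1² = 2.
    """
    x = np.concatenate([[0.0], hist.relative, [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def _ssd(params: np.ndarray, obs: np.ndarray) -> float:
    tau, theta0, theta1 = params
    exp = expected_mismatch(tau, theta0, theta1, len(obs) - 1)
    return float(np.sum((obs - exp) ** 2))


def _fit_point(
    obs: np.ndarray,
    tau_bounds=(0.0, 50.0),
    theta0_bounds=(0.0, 50.0),
    theta1_cap=THETA1_CAP,
) -> tuple[float, float, float, float]:
    """Deterministic grid search then Nelder-Mead refinement.

    Returns (tau, theta0, theta1, SSD). θ1 is searched log-spaced up to the
    cap; the best grid point seeds a bounded simplex refinement.
    """
    d_max = len(obs) - 1
    mean = float(np.dot(np.arange(d_max + 1), obs))
    tau_grid = np.unique(
        np.concatenate([np.linspace(0.0, min(2 * mean + 5, tau_bounds[1]), 21), [mean]])
    )
    theta0_grid = np.concatenate([[0.0], np.geomspace(0.01, theta0_bounds[1], 10)])
    theta1_grid = np.concatenate([np.geomspace(0.1, theta1_cap, 12), [theta1_cap]])

    best = (0.0, 0.0, theta1_cap, np.inf)
    for t in tau_grid:
        for q0 in theta0_grid:
            for q1 in theta1_grid:
                if q1 < q0:
                    continue
                s = _ssd(np.array([t, q0, q1]), obs)
                if s < best[3] - 1e-15:
                    best = (float(t), float(q0), float(q1), s)

    def penalized(p):
        t, q0, q1 = p
        if (
            t < tau_bounds[0]
            or t > tau_bounds[1]
            or q0 < theta0_bounds[0]
            or q0 > theta0_bounds[1]
            or q1 < q0
            or q1 > theta1_cap
        ):
            return 1e6
        return _ssd(p, obs)

    res = minimize(
        penalized,
        x0=np.array(best[:3]),
        method="Nelder-Mead",
        options=dict(xatol=1e-4, fatol=1e-9, maxiter=2000),
    )
    if res.fun < best[3]:
        t, q0, q1 = res.x
        return float(t), float(q0), float(q1), float(res.fun)
    return best


def _simulate_histogram_from_model(
    tau: float, theta0: float, theta1: float, n_pairs: int, d_max: int, rng
) -> MismatchHistogram:
    """Draw a bootstrap histogram of n_pairs pairwise differences from the
    fitted sudden-expansion distribution (multinomial over 0..d_hi)."""
    d_hi = max(d_max * 2, d_max + 20)
    probs = expected_mismatch(tau, theta0, theta1, d_hi)
    tail = max(1.0 - probs.sum(), 0.0)
    p = np.concatenate([probs, [tail]])
    p = p / p.sum()
    draws = rng.multinomial(n_pairs, p)
    # lump tail draws into the last real bin
    counts = draws[:-1].copy()
    counts[-1] += draws[-1]
    nz = np.nonzero(counts)[0]
    hi = int(nz[-1]) if nz.size else 0
    return MismatchHistogram(counts=tuple(int(c) for c in counts[: hi + 1]))


def fit_sudden_expansion(
    hist: MismatchHistogram,
    n_boot: int = 1000,
    seed: int = 0,
    theta1_cap: float = THETA1_CAP,
) -> SuddenExpansionFit:
    """Least-squares sudden-expansion fit with parametric bootstrap.

    ``p_SSD`` is the fraction of bootstrap replicates (simulated under the
    fitted model, re-fit) whose SSD is >= the observed SSD; the same
    replicates give 2.5/97.5 percentile CIs and the raggedness p-value.
    A histogram with all mass at 0 yields the flagged boundary fit τ=0.
    """
    obs = hist.relative
    if len(obs) == 1:
        return SuddenExpansionFit(
            tau=0.0, theta0=0.0, theta1=0.0, SSD=0.0, p_SSD=None,
            raggedness=raggedness(hist), p_raggedness=None, ci95=None,
            n_boot=0, seed=seed, boundary_fit=True,
        )
    tau, q0, q1, ssd = _fit_point(obs, theta1_cap=theta1_cap)
    r_obs = raggedness(hist)
    if n_boot <= 0:
        return SuddenExpansionFit(
            tau=tau, theta0=q0, theta1=q1, SSD=ssd, p_SSD=None,
            raggedness=r_obs, p_raggedness=None, ci95=None, n_boot=0, seed=seed,
            boundary_fit=bool(q1 >= theta1_cap * (1 - 1e-9)),
        )
    rng = np.random.default_rng(seed)
    taus, q0s, q1s, ssds, rags = [], [], [], [], []
    for _ in range(n_boot):
        bh = _simulate_histogram_from_model(tau, q0, q1, hist.n_pairs, hist.d_max, rng)
        bt, b0, b1, bs = _fit_point(bh.relative, theta1_cap=theta1_cap)
        taus.append(bt)
        q0s.append(b0)
        q1s.append(b1)
        ssds.append(bs)
        rags.append(raggedness(bh))
    taus, q0s, q1s = np.array(taus), np.array(q0s), np.array(q1s)
    ssds, rags = np.array(ssds), np.array(rags)
    ci = {
        "tau": tuple(np.percentile(taus, [2.5, 97.5])),
        "theta0": tuple(np.percentile(q0s, [2.5, 97.5])),
        "theta1": tuple(np.percentile(q1s, [2.5, 97.5])),
    }
    return SuddenExpansionFit(
        tau=tau, theta0=q0, theta1=q1, SSD=ssd,
        p_SSD=float(np.mean(ssds >= ssd)),
        raggedness=r_obs,
        p_raggedness=float(np.mean(rags >= r_obs)),
        ci95={k: (float(a), float(b)) for k, (a, b) in ci.items()},
        n_boot=n_boot, seed=seed,
        boundary_fit=bool(q1 >= theta1_cap * (1 - 1e-9)),
    )


# ---------------------------------------------------------------------------
# Expansion dating


@dataclass(frozen=True)
class ExpansionTime:
    """t = τ/(2µ) with µ = L · rate_per_bp_per_year · generation_time."""

    t_generations: float
    t_truncated: int
    mu: float
    L: int
    rate_per_bp_per_year: float
    generation_time: float


def expansion_time(
    tau: float,
    L: int,
    rate_per_bp_per_year: float,
    generation_time: float = 1.0,
) -> ExpansionTime:
    """Date an expansion from τ and a per-site per-year mutation rate.

    With a one-year generation time, generations equal years. The printed
    value truncates fractional generations (``t_truncated``); the exact
    value is kept alongside.
    """
    if rate_per_bp_per_year <= 0 or L <= 0 or generation_time <= 0:
        raise ValueError("L, rate and generation time must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    mu = L * rate_per_bp_per_year * generation_time
    t = tau / (2.0 * mu)
    return ExpansionTime(
        t_generations=t,
        t_truncated=int(t),
        mu=mu,
        L=L,
        rate_per_bp_per_year=rate_per_bp_per_year,
        generation_time=generation_time,
    )
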