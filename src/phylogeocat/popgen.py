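"""Within-population diversity statistics and neutrality tests.

Implements the classical mtDNA summary statistics — gene (haplotype)
diversity *h*, nucleotide diversity π, mean pairwise difference θπ and
Watterson's θs — together with Tajima's D and Fu's Fs, whose significance
is assessed against constant-size neutral coalescent simulations run with
θ set to the observed θπ (the convention of the standard analysis
packages).

Variance conventions
--------------------
* *h*: Nei's (1987) sampling variance.
* θπ: total variance of the mean pairwise difference under the neutral
  coalescent, V = b1·θ + b2·θ², evaluated at θ̂ = θπ.
* θs: S-based plug-in variance V = (a1²·S + a2·S²) / (a1²·(a1² + a2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import MissingPolicy, SequenceAlignment, collapse_haplotypes, used_columns


class InsufficientDataError(ValueError):
    """Too few sequences/haplotypes for the requested statistic."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. S = 0)."""


# ---------------------------------------------------------------------------
# Tajima's constants


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


# ---------------------------------------------------------------------------
# Diversity statistics


def gene_diversity(counts) -> tuple[float, float]:
    """Gene diversity h = n/(n-1)·(1 - Σp²) and its Nei (1987) s.d."""
    counts = np.asarray(list(counts), dtype=float)
    n = counts.sum()
    if n < 2:
        raise InsufficientDataError("gene diversity requires n >= 2")
    p = counts / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sum2)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return h, float(np.sqrt(max(var, 0.0)))


def pairwise_differences(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> np.ndarray:
    """Symmetric (n, n) matrix of per-pair nucleotide differences."""
    mask = used_columns(aln, missing_policy)
    arr = aln.to_array()[:, mask]
    n = aln.n
    codes = np.zeros(arr.shape, dtype=np.int8)
    for k, c in enumerate("ACGTN-"):
        codes[arr == c] = k
    diff = np.zeros((n, n), dtype=int)
    for i in range(n):
        d = (codes[i] != codes[i + 1 :]).sum(axis=1)
        diff[i, i + 1 :] = d
        diff[i + 1 :, i] = d
    return diff


def theta_pi(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> tuple[float, float]:
    """Mean pairwise difference θπ and its coalescent s.d. (at θ̂=θπ)."""
    n = aln.n
    if n < 2:
        raise InsufficientDataError("theta_pi requires n >= 2")
    diff = pairwise_differences(aln, missing_policy)
    tp = float(diff[np.triu_indices(n, 1)].mean())
    c = tajima_constants(n)
    var = c["b1"] * tp + c["b2"] * tp * tp
    return tp, float(np.sqrt(max(var, 0.0)))


def watterson_theta(S: int, n: int) -> tuple[float, float]:
    """Watterson's θs = S/a1 with the S-based plug-in s.d."""
    if n < 2:
        raise InsufficientDataError("watterson_theta requires n >= 2")
    if S < 0:
        raise ValueError("S must be non-negative")
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, 2)
    theta = S / a1
    var = (a1 * a1 * S + a2 * S * S) / (a1 * a1 * (a1 * a1 + a2))
    return float(theta), float(np.sqrt(var))


@dataclass(frozen=True)
class DiversitySummary:
    """Table-2-style per-population diversity block."""

    n: int
    L: int
    K: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    theta_pi: float
    theta_pi_sd: float
    theta_s: float
    theta_s_sd: float


def diversity_summary(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> DiversitySummary:
    from .seqio import site_summary

    table = collapse_haplotypes(aln, missing_policy)
    L = int(used_columns(aln, missing_policy).sum())
    h, h_sd = gene_diversity(table.counts)
    tp, tp_sd = theta_pi(aln, missing_policy)
    S = site_summary(aln, missing_policy).S
    ts, ts_sd = watterson_theta(S, aln.n)
    return DiversitySummary(
        n=aln.n,
        L=L,
        K=table.k,
        h=h,
        h_sd=h_sd,
        pi=tp / L,
        pi_sd=tp_sd / L,
        theta_pi=tp,
        theta_pi_sd=tp_sd,
        theta_s=ts,
        theta_s_sd=ts_sd,
    )


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d_from_summaries(theta_pi_val: float, S: int, n: int) -> float:
    """Tajima's (1989) D from θπ, S and n."""
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((theta_pi_val - S / c["a1"]) / np.sqrt(var))


@dataclass(frozen=True)
class NeutralityResult:
    D: float | None
    p_D: float | None
    Fs: float | None
    p_Fs: float | None
    n_sims: int
    seed: int


def _null_coalescent_stats(
    n: int, theta: float, n_sims: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the neutral constant-size null used for p-values.

    Infinite-sites coalescent with θ fixed at the supplied value; returns
    per-replicate (theta_pi, S, K) arrays. Uses msprime.
    """
    import msprime

    rng = np.random.default_rng(seed)
    tp = np.empty(n_sims)
    S = np.empty(n_sims, dtype=int)
    K = np.empty(n_sims, dtype=int)
    # Ne=1, ploidy 1: pairwise coalescence rate 1; E[pairwise diff] = theta
    # when per-generation sequence mutation rate = theta/2.
    for i in range(n_sims):
        ts = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1.0,
            sequence_length=1.0,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2.0,
            model=msprime.InfiniteSites(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        S[i] = mts.num_sites
        tp[i] = mts.diversity(span_normalise=False)
        geno = mts.genotype_matrix()
        if geno.shape[0] == 0:
            K[i] = 1
        else:
            K[i] = len({tuple(col) for col in geno.T})
    return tp, S, K


def tajimas_d(
    aln: SequenceAlignment,
    n_sims: int = 1000,
    seed: int = 0,
    missing_policy: MissingPolicy = "complete-deletion",
) -> NeutralityResult:
    """Tajima's D with a simulated one-tailed p-value.

    The null distribution is a constant-size coalescent with θ set to the
    observed θπ. For negative observed D the p-value is the fraction of
    simulated D ≤ D_obs; for positive D, the fraction ≥ D_obs.
    """
    from .seqio import site_summary

    tp, _ = theta_pi(aln, missing_policy)
    S = site_summary(aln, missing_policy).S
    d_obs = tajimas_d_from_summaries(tp, S, aln.n)
    sim_tp, sim_S, _ = _null_coalescent_stats(aln.n, tp, n_sims, seed)
    d_sim = np.full(n_sims, np.nan)
    ok = sim_S >= 1
    c = tajima_constants(aln.n)
    var = c["e1"] * sim_S[ok] + c["e2"] * sim_S[ok] * (sim_S[ok] - 1)
    d_sim[ok] = (sim_tp[ok] - sim_S[ok] / c["a1"]) / np.sqrt(var)
    valid = d_sim[~np.isnan(d_sim)]
    if d_obs <= 0:
        p = float(np.mean(valid <= d_obs)) if valid.size else 1.0
    else:
        p = float(np.mean(valid >= d_obs)) if valid.size else 1.0
    return NeutralityResult(D=d_obs, p_D=p, Fs=None, p_Fs=None, n_sims=n_sims, seed=seed)


# ---------------------------------------------------------------------------
# Fu's Fs


def log_stirling_first(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n via the log-space recurrence.

    |s(n+1,k)| = |s(n,k-1)| + n·|s(n,k)|; stays finite for n in the
    hundreds where the raw integers overflow.
    """
    log_s = np.full(n + 1, -np.inf)
    log_s[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(log_s[:-1], np.log(m - 1) + log_s[1:]) if m > 1 else log_s[:-1]
        log_s = new
    return log_s


def ewens_log_probs(n: int, theta: float) -> np.ndarray:
    """log P(K = k | θ, n) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        out = np.full(n, -np.inf)
        out[0] = 0.0
        return out
    log_s = log_stirling_first(n)[1:]  # k = 1..n
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return log_s + k * np.log(theta) - log_rising


def fu_fs_from_summaries(theta_pi_val: float, k_obs: int, n: int) -> float:
    """Fu's Fs = ln( S' / (1-S') ) with S' = P(K >= k_obs | θ=θπ).

    Both the tail S' and its complement are accumulated in log space from
    the Ewens probabilities, so the log-odds stays accurate when S' is
    within machine epsilon of 0 or 1; the exact limits return ∓∞ (flagged
    values, not exceptions).
    """
    from scipy.special import logsumexp

    logp = ewens_log_probs(n, theta_pi_val)
    log_sp = logsumexp(logp[k_obs - 1 :])  # P(K >= k_obs)
    log_comp = logsumexp(logp[: k_obs - 1]) if k_obs > 1 else -np.inf  # P(K < k_obs)
    if log_comp == -np.inf:
        return float("inf")
    if log_sp == -np.inf:
        return float("-inf")
    return float(log_sp - log_comp)


def fus_fs(
    aln: SequenceAlignment,
    n_sims: int = 1000,
    seed: int = 0,
    missing_policy: MissingPolicy = "complete-deletion",
) -> NeutralityResult:
    """Fu's Fs with a simulated p-value (P(Fs_sim <= Fs_obs))."""
    tp, _ = theta_pi(aln, missing_policy)
    k_obs = collapse_haplotypes(aln, missing_policy).k
    fs_obs = fu_fs_from_summaries(tp, k_obs, aln.n)
    sim_tp, _, sim_K = _null_coalescent_stats(aln.n, tp, n_sims, seed)
    fs_sim = np.array(
        [fu_fs_from_summaries(t, int(k), aln.n) for t, k in zip(sim_tp, sim_K)]
    )
    finite = fs_sim[np.isfinite(fs_sim)]
    if np.isfinite(fs_obs) and finite.size:
        p = float(np.mean(finite <= fs_obs))
    else:
        p = 0.0 if fs_obs == -np.inf else 1.0
    return NeutralityResult(D=None, p_D=None, Fs=fs_obs, p_Fs=p, n_sims=n_sims, seed=seed)


def neutrality_tests(
    aln: SequenceAlignment,
    n_sims: int = 1000,
    seed: int = 0,
    missing_policy: MissingPolicy = "complete-deletion",
) -> NeutralityResult:
    """Tajima's D and Fu's Fs sharing one null simulation run."""
    from .seqio import site_summary

    tp, _ = theta_pi(aln, missing_policy)
    S = site_summary(aln, missing_policy).S
    k_obs = collapse_haplotypes(aln, missing_policy).k
    d_obs = tajimas_d_from_summaries(tp, S, aln.n) if S >= 1 else None
    fs_obs = fu_fs_from_summaries(tp, k_obs, aln.n)
    sim_tp, sim_S, sim_K = _null_coalescent_stats(aln.n, tp, n_sims, seed)

    p_d = None
    if d_obs is not None:
        c = tajima_constants(aln.n)
        ok = sim_S >= 1
        var = c["e1"] * sim_S[ok] + c["e2"] * sim_S[ok] * (sim_S[ok] - 1)
        d_sim = (sim_tp[ok] - sim_S[ok] / c["a1"]) / np.sqrt(var)
        p_d = (
            float(np.mean(d_sim <= d_obs)) if d_obs <= 0 else float(np.mean(d_sim >= d_obs))
        )
    fs_sim = np.array(
        [fu_fs_from_summaries(t, int(k), aln.n) for t, k in zip(sim_tp, sim_K)]
    )
    finite = fs_sim[np.isfinite(fs_sim)]
    p_fs = float(np.mean(finite <= fs_obs)) if np.isfinite(fs_obs) and finite.size else (
        0.0 if fs_obs == -np.inf else 1.0
    )
    return NeutralityResult(D=d_obs, p_D=p_d, Fs=fs_obs, p_Fs=p_fs, n_sims=n_sims, seed=seed)
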