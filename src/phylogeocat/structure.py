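"""Population structure: AMOVA-based ΦST, great-circle distances and
Mantel isolation-by-distance.

The fixation index reported here is ΦST from a one-level analysis of
molecular variance on pairwise sequence differences (Excoffier, Smouse &
Quattro 1992). Because the count of differing sites between two sequences
is a squared Euclidean distance, the pairwise-difference matrix enters the
sums of squares directly:

    SS(total)  = Σ_{i<j} d_ij / n
    SS(within) = Σ_pops Σ_{i<j in pop} d_ij / n_pop
    σ²_within  = SS(within) / (n - P)
    σ²_among   = (MS_among - σ²_within) / n'   with the unequal-size
                 coefficient n' = (n - Σ n_p²/n) / (P - 1)
    ΦST        = σ²_among / (σ²_among + σ²_within)

Significance comes from permuting individuals among populations. The
literature this mirrors labels the same quantity F_ST; we keep the Φ
notation to make the molecular-distance basis explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np

from .seqio import MissingPolicy, SequenceAlignment
from .popgen import pairwise_differences

EARTH_RADIUS_KM = 6371.0


class GroupingError(ValueError):
    """Invalid population assignment for a structure analysis."""


class UndefinedCorrelationError(ValueError):
    """A distance matrix is constant; Pearson r is undefined."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal labelled distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n) float
    units: str = "substitutions"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        object.__setattr__(self, "values", v)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=tuple(labels), values=self.values[np.ix_(idx, idx)], units=self.units
        )


def pairwise_difference_matrix(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> DistanceMatrix:
    """Per-pair counts of differing sites under the missing policy."""
    return DistanceMatrix(
        labels=tuple(aln.ids),
        values=pairwise_differences(aln, missing_policy).astype(float),
        units="substitutions",
    )


@dataclass(frozen=True)
class GroupingScheme:
    """Named assignment of samples to populations."""

    name: str
    assignment: dict[str, str]

    def populations(self) -> list[str]:
        return sorted(set(self.assignment.values()))


@dataclass(frozen=True)
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    p: float | None
    n_perm: int
    seed: int
    negative_component: bool = False


def _amova_phi(d: np.ndarray, codes: np.ndarray) -> tuple[float, float, float]:
    """(phi_st, sigma2_among, sigma2_within) for integer population codes."""
    n = len(codes)
    pops, counts = np.unique(codes, return_counts=True)
    P = len(pops)
    iu = np.triu_indices(n, 1)
    ss_total = d[iu].sum() / n
    ss_within = 0.0
    for p_code, n_p in zip(pops, counts):
        idx = np.flatnonzero(codes == p_code)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / n_p
    ss_among = ss_total - ss_within
    df_among = P - 1
    df_within = n - P
    if df_within <= 0:
        # every sample its own population: no within component
        sigma_w = 0.0
    else:
        sigma_w = ss_within / df_within
    n_prime = (n - np.sum(counts.astype(float) ** 2) / n) / df_among
    ms_among = ss_among / df_among
    sigma_a = (ms_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else 0.0
    return float(phi), float(sigma_a), float(sigma_w)


def amova(
    dist: DistanceMatrix,
    grouping: GroupingScheme,
    n_perm: int = 10000,
    seed: int = 0,
) -> AmovaResult:
    """One-level AMOVA ΦST with a permutation test.

    The permutation p-value counts replicates with Φ_perm >= Φ_obs,
    including the observed arrangement in numerator and denominator.
    Negative variance components are retained but flagged.
    """
    labels = dist.labels
    try:
        pops = [grouping.assignment[l] for l in labels]
    except KeyError as exc:
        raise GroupingError(f"sample {exc.args[0]!r} has no population") from exc
    uniq = sorted(set(pops))
    if len(uniq) < 2:
        raise GroupingError("AMOVA requires >= 2 populations")
    counts = [pops.count(p) for p in uniq]
    if min(counts) < 1:
        raise GroupingError("every population must have >= 1 sample")
    if len(labels) == len(uniq):
        raise GroupingError("all populations are singletons; within variance undefined")
    code_of = {p: i for i, p in enumerate(uniq)}
    codes = np.array([code_of[p] for p in pops])
    d = dist.values
    phi, s_a, s_w = _amova_phi(d, codes)
    p_val = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 1  # observed included
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            phi_p, _, _ = _amova_phi(d, perm)
            if phi_p >= phi - 1e-12:
                hits += 1
        p_val = hits / (n_perm + 1)
    denom = s_a + s_w
    return AmovaResult(
        phi_st=phi,
        sigma2_among=s_a,
        sigma2_within=s_w,
        pct_among=100.0 * s_a / denom if denom != 0 else 0.0,
        p=p_val,
        n_perm=n_perm,
        seed=seed,
        negative_component=bool(s_a < 0 or s_w < 0),
    )


def pairwise_phist(
    dist: DistanceMatrix,
    grouping: GroupingScheme,
    n_perm: int = 10000,
    seed: int = 0,
):
    """Pairwise-population ΦST table (dict keyed by frozenset of the pair).

    Each pair is analysed by a direct two-population AMOVA on the relevant
    submatrix; no multiple-testing correction is applied.
    """
    pops = grouping.populations()
    results: dict[frozenset, AmovaResult] = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pa, pb = pops[i], pops[j]
            keep = [
                l for l in dist.labels if grouping.assignment[l] in (pa, pb)
            ]
            sub = dist.submatrix(keep)
            sub_grouping = GroupingScheme(
                name=f"{grouping.name}:{pa}|{pb}",
                assignment={l: grouping.assignment[l] for l in keep},
            )
            results[frozenset((pa, pb))] = amova(sub, sub_grouping, n_perm, seed)
    return results


# ---------------------------------------------------------------------------
# Geography


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    f1, f2 = np.radians(lat1), np.radians(lat2)
    df = f2 - f1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(df / 2) ** 2 + np.cos(f1) * np.cos(f2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def great_circle_matrix(coords: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Per-sample haversine distance matrix; coords are (lat, lon)."""
    labels = tuple(coords)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(*coords[labels[i]], *coords[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=labels, values=vals, units="km")


def population_distance_matrix(
    coords: dict[str, tuple[float, float] | None],
    grouping: GroupingScheme,
) -> DistanceMatrix:
    """Population-to-population distance = mean over cross-population
    sample pairs. Samples without coordinates are dropped (with a
    warning); a population losing every member is an error."""
    import warnings

    valid = {s: c for s, c in coords.items() if c is not None}
    dropped = sorted(set(coords) - set(valid))
    if dropped:
        warnings.warn(f"samples without coordinates excluded: {dropped}", stacklevel=2)
    pops = grouping.populations()
    members = {
        p: [s for s in valid if grouping.assignment.get(s) == p] for p in pops
    }
    empty = [p for p, m in members.items() if not m]
    if empty:
        raise GroupingError(f"populations with no located members: {empty}")
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ds = [
                haversine_km(*valid[a], *valid[b])
                for a in members[pops[i]]
                for b in members[pops[j]]
            ]
            vals[i, j] = vals[j, i] = float(np.mean(ds))
    return DistanceMatrix(labels=tuple(pops), values=vals, units="km")


# ---------------------------------------------------------------------------
# Mantel


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    exact: bool = False


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(m.shape[0], -1)]


def mantel(
    geo: DistanceMatrix,
    gen: DistanceMatrix,
    n_perm: int = 10000,
    seed: int = 0,
) -> MantelResult:
    """Mantel matrix correlation with a one-tailed permutation test.

    r is the Pearson correlation over lower-triangle entries (raw values;
    no log transformation). The p-value is the proportion of simultaneous
    row/column permutations of one matrix with r_perm >= r_obs (observed
    arrangement included). For <= 5 populations all permutations are
    enumerated exactly.
    """
    if geo.labels != gen.labels:
        raise ValueError("matrices must share labels and order")
    n = len(geo.labels)
    if n < 3:
        raise ValueError("Mantel test requires >= 3 populations")
    x = _lower_triangle(geo.values)
    y_m = gen.values
    if np.allclose(x, x[0]) or np.allclose(_lower_triangle(y_m), y_m[1, 0]):
        raise UndefinedCorrelationError("constant distance matrix")
    y = _lower_triangle(y_m)
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def r_of(perm) -> float:
        yp = _lower_triangle(y_m[np.ix_(perm, perm)])
        return float(np.corrcoef(x, yp)[0, 1])

    if n <= 5:
        rs = [r_of(list(p)) for p in iter_permutations(range(n))]
        p_val = float(np.mean([r >= r_obs - 1e-12 for r in rs]))
        return MantelResult(r=r_obs, p=p_val, n_perm=len(rs), seed=seed, exact=True)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        if r_of(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=hits / (n_perm + 1), n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Latitudinal bands


LATITUDINAL_BANDS = (
    ("10N-19.9N", 10.0, 20.0),
    ("20N-28.9N", 20.0, 29.0),
    ("29N-35N", 29.0, 35.0),
)


def assign_latitudinal_class(lat: float) -> str:
    """South/central/north latitude band for India.

    Bands are the half-open intervals [10,20), [20,29) and the closed
    [29,35] — gap values between the printed band edges (e.g. 19.95) close
    downward into the lower band. Latitudes outside [10,35] get the
    ``unclassified`` label with a warning.
    """
    import warnings

    if not (10.0 <= lat <= 35.0):
        warnings.warn(f"latitude {lat} outside [10, 35]; unclassified", stacklevel=2)
        return "unclassified"
    for name, lo, hi in LATITUDINAL_BANDS:
        if lo <= lat < hi or (name == "29N-35N" and lo <= lat <= 35.0):
            return name
    return "unclassified"  # pragma: no cover
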