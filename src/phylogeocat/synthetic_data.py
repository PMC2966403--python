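"""Synthetic fixtures: coalescent sequence data under the demographies the
genetic analyses assume, and climate rasters with threshold-governed
presence points.

Sequence data
-------------
Genealogies come from the single-locus coalescent (msprime, haploid
samples — mtDNA is maternally inherited and effectively haploid). The
scaled diversity parameter is θ = 2·N_e·u with u the mutation rate per
sequence per generation; simulations fix N_e = 1 so u = θ/2 and branch
lengths are in units of N_e generations. Three demographies are offered:

``constant``          one deme of constant size (θ);
``sudden_expansion``  a deme currently at θ1 that was θ0 before τ units of
                      mutational time (τ = 2·u·t, matching the mismatch
                      model's parameterisation);
``two_island``        two demes exchanging migrants at scaled rate M
                      (immigration fraction per 2N generations), merged
                      into one ancestral deme T 2N-generations back.

Mutations are finite-sites by default (HKY with a transition bias over L
discrete sites, so parallel hits and multi-state sites occur, as in real
data) with an infinite-sites mode for oracle tests.

Climate data
------------
Rasters are deterministic row/column gradients plus seeded Gaussian noise;
presences are drawn uniformly from cells satisfying a hard predicate on
the variables (emulating an occupancy limit such as a summer-temperature
ceiling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import msprime
import numpy as np

from .niche import ClimateStack, Grid, PresenceRecords, SamplingError
from .seqio import SequenceAlignment

BASES = "ACGT"


@dataclass(frozen=True)
class DemographyModel:
    """Coalescent demography for sequence simulation.

    * constant: ``theta``; sample size n.
    * sudden_expansion: ``theta0 -> theta1`` at ``tau`` mutational units.
    * two_island: per-deme ``theta``, scaled migration ``M``, split ``T``
      (in 2N generations), per-deme sample sizes.
    """

    kind: Literal["constant", "sudden_expansion", "two_island"]
    theta: float = 5.0
    theta0: float = 1.0
    theta1: float = 100.0
    tau: float = 4.0
    M: float = 1.0
    T: float = 5.0
    samples: tuple[int, ...] = (20,)

    def __post_init__(self) -> None:
        if min(self.samples) < 1:
            raise ValueError("need at least one sample per deme")
        if self.kind == "sudden_expansion" and self.theta1 < self.theta0:
            raise ValueError("theta1 must be >= theta0")
        for v in (self.theta, self.theta0, self.theta1, self.tau, self.M, self.T):
            if v < 0:
                raise ValueError("rates and times must be >= 0")


@dataclass(frozen=True)
class SimulatedAlignment:
    """Alignment plus the provenance needed to reproduce it."""

    alignment: SequenceAlignment
    model: DemographyModel
    L: int
    ti_tv: float
    seed: int
    populations: dict[str, str] = field(default_factory=dict)
    tree_newick: str = ""


def _demography_and_samples(model: DemographyModel, u: float):
    """Translate θ-scale parameters to msprime sizes/times (N_e units,
    reference N = 1 so one coalescent time unit = 1 generation here)."""
    def size(theta: float) -> float:
        # theta = 0 still needs a positive genealogy size; with the matching
        # near-zero mutation rate the sequences stay identical
        return theta / (2 * u) if theta > 0 else 1.0

    demog = msprime.Demography()
    if model.kind == "constant":
        demog.add_population(name="pop0", initial_size=size(model.theta))
        samples = {"pop0": model.samples[0]}
    elif model.kind == "sudden_expansion":
        n1 = size(model.theta1)
        n0 = size(model.theta0) if model.theta0 > 0 else 1e-3 * n1
        t_split = model.tau / (2 * u)
        demog.add_population(name="pop0", initial_size=n1)
        demog.add_population_parameters_change(
            time=t_split, population="pop0", initial_size=n0
        )
        samples = {"pop0": model.samples[0]}
    else:  # two_island
        if len(model.samples) != 2:
            raise ValueError("two_island needs two sample sizes")
        n = size(model.theta)
        demog.add_population(name="pop0", initial_size=n)
        demog.add_population(name="pop1", initial_size=n)
        demog.add_population(name="anc", initial_size=n)
        # scaled migration M migrants per deme per 2N generations
        rate = model.M / (2 * n)
        demog.set_migration_rate("pop0", "pop1", rate)
        demog.set_migration_rate("pop1", "pop0", rate)
        demog.add_population_split(time=model.T * 2 * n, derived=["pop0", "pop1"], ancestral="anc")
        samples = {"pop0": model.samples[0], "pop1": model.samples[1]}
    return demog, samples


def simulate_alignment(
    model: DemographyModel,
    L: int = 601,
    ti_tv: float = 4.0,
    seed: int = 1,
    infinite_sites: bool = False,
) -> SimulatedAlignment:
    """Simulate a haploid alignment under the demography.

    Finite-sites mutations use the HKY model with transition/transversion
    bias ``ti_tv`` (kappa) over L discrete sites and a random ancestral
    state per site; ``infinite_sites=True`` switches to Jukes-Cantor on a
    continuous genome for oracle tests (each mutation hits a fresh site,
    then mapped onto columns). θ values are per-sequence, so the per-site
    rate is θ/(2·N·L) at the chosen reference size.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if sum(model.samples) < 1:
        raise ValueError("no samples requested")
    rng = np.random.default_rng(seed)
    # choose reference u so that sizes are comfortable: u = theta_ref / 2 at N=1
    theta_ref = {
        "constant": model.theta,
        "sudden_expansion": model.theta1,
        "two_island": model.theta,
    }[model.kind]
    u = max(theta_ref, 1e-8) / 2.0  # per-sequence rate at N = 1
    demog, samples = _demography_and_samples(model, u)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demog,
        ploidy=1,
        sequence_length=L,
        random_seed=anc_seed,
    )
    if infinite_sites:
        mts = msprime.sim_mutations(
            ts,
            rate=u / L,
            model=msprime.InfiniteSites(),
            discrete_genome=False,
            random_seed=mut_seed,
        )
    else:
        mts = msprime.sim_mutations(
            ts,
            rate=u / L,
            model=msprime.HKY(kappa=ti_tv),
            discrete_genome=True,
            random_seed=mut_seed,
        )

    pop_names = {p.id: p.metadata.get("name", str(p.id)) for p in mts.populations()}
    records = []
    populations: dict[str, str] = {}
    sample_nodes = list(mts.samples())
    # random ancestral background, then apply variant columns on top
    background = rng.choice(list(BASES), size=L)
    mat = np.tile(background, (len(sample_nodes), 1))
    if infinite_sites:
        # map mutations onto distinct columns deterministically
        if mts.num_sites > L:
            raise ValueError("more infinite-sites mutations than columns; increase L")
        for idx, var in enumerate(mts.variants()):
            col = idx % L
            derived = BASES[(BASES.index(mat[0, col]) + 1) % 4]
            geno = var.genotypes
            mat[geno > 0, col] = derived
    else:
        for var in mts.variants():
            col = int(var.site.position)
            alleles = var.alleles
            geno = var.genotypes
            for g in np.unique(geno):
                allele = alleles[g]
                if allele is None:
                    continue
                mat[geno == g, col] = allele
    for row, node in enumerate(sample_nodes):
        pop = pop_names[mts.node(node).population]
        sid = f"{pop}_{row:03d}"
        records.append((sid, "".join(mat[row])))
        populations[sid] = pop
    aln = SequenceAlignment(tuple(records))
    newick = ts.first().as_newick() if ts.num_trees >= 1 else ""
    return SimulatedAlignment(
        alignment=aln,
        model=model,
        L=L,
        ti_tv=ti_tv,
        seed=seed,
        populations=populations,
        tree_newick=newick,
    )


# ---------------------------------------------------------------------------
# Climate


@dataclass(frozen=True)
class GradientSpec:
    """Layer = base + row_slope·row + col_slope·col + N(0, noise_sd)."""

    name: str
    base: float = 0.0
    row_slope: float = 0.0
    col_slope: float = 0.0
    noise_sd: float = 0.0


def simulate_climate_stack(
    shape: tuple[int, int],
    variables: list[GradientSpec],
    seed: int = 1,
    xll: float = 60.0,
    yll: float = 0.0,
    cellsize: float = 0.25,
    nodata_border: int = 0,
) -> ClimateStack:
    """Deterministic gradient layers plus seeded Gaussian noise.

    ``nodata_border`` masks that many cells around the edge in every
    layer (same mask everywhere, as a co-registered stack requires).
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    layers: dict[str, Grid] = {}
    for spec in variables:
        vals = spec.base + spec.row_slope * rows + spec.col_slope * cols
        vals = vals.astype(float)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=(nrows, ncols))
        if nodata_border > 0:
            b = nodata_border
            vals[:b, :] = np.nan
            vals[-b:, :] = np.nan
            vals[:, :b] = np.nan
            vals[:, -b:] = np.nan
        layers[spec.name] = Grid(values=vals, xll=xll, yll=yll, cellsize=cellsize)
    return ClimateStack(layers=layers)


def sample_presences(
    stack: ClimateStack,
    rule: Callable[[dict[str, float]], bool],
    n: int,
    seed: int = 1,
    jitter: bool = True,
) -> PresenceRecords:
    """Uniform sample (without replacement) of cells satisfying the rule.

    ``rule`` receives {variable: value} for one cell. Points are placed at
    cell centers, optionally jittered within the cell. Raises
    :class:`SamplingError` when fewer than n cells satisfy the rule.
    """
    ref = stack.reference
    ok_cells = []
    for r in range(ref.nrows):
        for c in range(ref.ncols):
            if np.isnan(ref.values[r, c]):
                continue
            cellvals = {name: float(g.values[r, c]) for name, g in stack.layers.items()}
            if rule(cellvals):
                ok_cells.append((r, c))
    if len(ok_cells) < n:
        raise SamplingError(
            f"rule satisfied by {len(ok_cells)} cells; {n} requested"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ok_cells), size=n, replace=False)
    pts = []
    for i in pick:
        r, c = ok_cells[int(i)]
        lat, lon = ref.center_of(r, c)
        if jitter:
            lat += float(rng.uniform(-0.49, 0.49)) * ref.cellsize
            lon += float(rng.uniform(-0.49, 0.49)) * ref.cellsize
        pts.append((lat, lon))
    return PresenceRecords(points=tuple(pts), sources=("synthetic",) * n)
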