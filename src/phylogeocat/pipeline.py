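"""Configuration-driven pipeline tying the analysis stages together.

``run_phylogeography`` produces, per species: a diversity table, AMOVA
tables under each grouping scheme with pairwise ΦST, a mismatch /
sudden-expansion table with expansion dating, a median-joining network
(GraphML + DOT), an NJ tree with bootstrap supports (Newick) and Mantel
isolation-by-distance results. ``run_niche`` produces the
correlation-filter report, envelope model JSON, suitability grid, the
replicate AUC table and a threshold report. Every stage is seeded from
the config; reruns with identical config are byte-identical.

The console entry point is ``phylogeocat`` (see ``--help``); a synthetic
two-species input bundle for smoke-testing is produced by
``phylogeocat simulate`` / :func:`generate_fixture`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import mismatch as mm
from . import network as nw
from . import niche as nc
from . import phylo as ph
from . import popgen as pg
from . import seqio
from . import structure as st
from . import synthetic_data as sd

log = logging.getLogger("phylogeocat")


@dataclass
class SpeciesConfig:
    name: str
    fasta: list[str]  # one aligned FASTA per gene fragment, concatenated in order
    metadata: str
    schemes: list[str] = field(default_factory=lambda: ["biogeographic"])
    outgroup: str | None = None
    mutation_rate_per_bp_per_year: float = 1.3e-8
    generation_time: float = 1.0


@dataclass
class NicheConfig:
    rasters: str
    presences: str
    r_max: float = 0.7
    tail: float = 0.025
    n_reps: int = 10
    train_frac: float = 0.75
    threshold_variable: str = "bio5"
    threshold_value: float = 38.0
    priority: list[str] = field(default_factory=list)  # keep-first order for the filter


@dataclass
class AnalysisConfig:
    species: list[SpeciesConfig]
    niche: NicheConfig | None = None
    n_sims: int = 1000
    n_perm: int = 1000
    n_boot: int = 200
    n_bootstrap_tree: int = 200
    seed: int = 1
    missing_policy: str = "complete-deletion"

    @staticmethod
    def from_yaml(path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesConfig(**s) for s in raw.get("species", [])]
        niche = NicheConfig(**raw["niche"]) if raw.get("niche") else None
        keys = {k: v for k, v in raw.items() if k not in ("species", "niche")}
        return AnalysisConfig(species=species, niche=niche, **keys)


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# Phylogeography


@_stage("load")
def _load_species(spc: SpeciesConfig, missing_policy: str):
    fragments = [seqio.read_fasta(f) for f in spc.fasta]
    aln = fragments[0]
    for frag in fragments[1:]:
        aln = seqio.concatenate(aln, frag)
    meta = seqio.read_metadata(spc.metadata)
    meta = meta.set_index("sample_id")
    missing = sorted(set(aln.ids) - set(meta.index))
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    return aln, meta


@_stage("diversity")
def _diversity(aln, missing_policy) -> dict:
    ds = pg.diversity_summary(aln, missing_policy)
    ss = seqio.site_summary(aln, missing_policy)
    return {
        "n": ds.n, "L": ds.L, "haplotypes": ds.K,
        "gene_diversity": round(ds.h, 3), "gene_diversity_sd": round(ds.h_sd, 3),
        "pi": round(ds.pi, 5), "theta_pi": round(ds.theta_pi, 3),
        "theta_pi_sd": round(ds.theta_pi_sd, 3),
        "theta_s": round(ds.theta_s, 3), "theta_s_sd": round(ds.theta_s_sd, 3),
        "S": ss.S, "transitions": ss.transitions, "transversions": ss.transversions,
    }


@_stage("neutrality")
def _neutrality(aln, n_sims, seed, missing_policy) -> dict:
    res = pg.neutrality_tests(aln, n_sims=n_sims, seed=seed, missing_policy=missing_policy)
    return {
        "tajimas_D": None if res.D is None else round(res.D, 3),
        "p_D": res.p_D,
        "fus_Fs": None if res.Fs is None else round(res.Fs, 3),
        "p_Fs": res.p_Fs,
        "n_sims": res.n_sims,
    }


@_stage("mismatch")
def _mismatch(aln, spc: SpeciesConfig, n_boot, seed, missing_policy) -> dict:
    hist = mm.mismatch_histogram(aln, missing_policy)
    fit = mm.fit_sudden_expansion(hist, n_boot=n_boot, seed=seed)
    L = int(seqio.used_columns(aln, missing_policy).sum())
    dating = {}
    if fit.ci95:
        lo, hi = fit.ci95["tau"]
        for tag, tau in (("point", fit.tau), ("lower", lo), ("upper", hi)):
            et = mm.expansion_time(
                tau, L, spc.mutation_rate_per_bp_per_year, spc.generation_time
            )
            dating[tag] = {"tau": round(tau, 3), "t_years": et.t_truncated}
    return {
        "mismatch_mean": round(hist.mean, 3),
        "tau": round(fit.tau, 3), "theta0": round(fit.theta0, 3),
        "theta1": round(fit.theta1, 3),
        "SSD": round(fit.SSD, 5), "p_SSD": fit.p_SSD,
        "raggedness": round(fit.raggedness, 3), "p_raggedness": fit.p_raggedness,
        "ci95": fit.ci95, "boundary_fit": fit.boundary_fit,
        "dating": dating,
        "histogram": list(hist.counts),
    }


@_stage("structure")
def _structure(aln, meta, schemes, n_perm, seed, missing_policy) -> dict:
    dm = st.pairwise_difference_matrix(aln, missing_policy)
    out = {}
    for scheme in schemes:
        if scheme not in meta.columns:
            raise KeyError(f"grouping scheme column {scheme!r} missing from metadata")
        assignment = {s: str(meta.loc[s, scheme]) for s in aln.ids}
        grouping = st.GroupingScheme(scheme, assignment)
        if len(grouping.populations()) < 2:
            out[scheme] = {"error": "fewer than 2 populations"}
            continue
        overall = st.amova(dm, grouping, n_perm=n_perm, seed=seed)
        pairs = st.pairwise_phist(dm, grouping, n_perm=n_perm, seed=seed)
        out[scheme] = {
            "phi_st": round(overall.phi_st, 4),
            "p": overall.p,
            "pct_among": round(overall.pct_among, 2),
            "negative_component": overall.negative_component,
            "pairwise": {
                "|".join(sorted(k)): {"phi_st": round(v.phi_st, 4), "p": v.p}
                for k, v in pairs.items()
            },
        }
    return out


@_stage("ibd")
def _ibd(aln, meta, scheme, n_perm, seed, missing_policy) -> dict | None:
    if scheme not in meta.columns or "latitude" not in meta.columns:
        return None
    coords = {}
    for s in aln.ids:
        lat, lon = meta.loc[s, "latitude"], meta.loc[s, "longitude"]
        coords[s] = None if pd.isna(lat) or pd.isna(lon) else (float(lat), float(lon))
    assignment = {s: str(meta.loc[s, scheme]) for s in aln.ids}
    grouping = st.GroupingScheme(scheme, assignment)
    pops = grouping.populations()
    if len(pops) < 3:
        return {"error": "Mantel needs >= 3 populations"}
    geo = st.population_distance_matrix(coords, grouping)
    dm = st.pairwise_difference_matrix(aln, missing_policy)
    pairs = st.pairwise_phist(dm, grouping, n_perm=0, seed=seed)
    vals = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            phi = max(pairs[frozenset((a, pops[j]))].phi_st, 0.0)
            vals[i, j] = vals[j, i] = phi
    gen = st.DistanceMatrix(tuple(pops), vals, units="phi_st")
    res = st.mantel(geo, gen, n_perm=n_perm, seed=seed)
    return {"r": round(res.r, 3), "p": res.p, "n_groups": len(pops), "exact": res.exact}


@_stage("network")
def _network(aln, meta, outdir: Path, species: str, missing_policy) -> dict:
    table = seqio.collapse_haplotypes(aln, missing_policy)
    net = nw.median_joining(table)
    assignment = (
        {s: str(meta.loc[s, "population"]) for s in aln.ids}
        if "population" in meta.columns
        else None
    )
    nw.to_graphml(net, outdir / f"{species}_network.graphml", assignment)
    nw.to_dot(net, outdir / f"{species}_network.dot")
    return {
        "observed_nodes": len(net.observed_nodes),
        "median_vectors": len(net.median_nodes),
        "total_edge_weight": net.total_edge_weight(),
    }


@_stage("tree")
def _tree(aln, spc: SpeciesConfig, n_reps, seed, outdir: Path, missing_policy) -> dict:
    # collapse to haplotypes first: NJ on 30-50 identical sequences is noise
    table = seqio.collapse_haplotypes(aln, missing_policy)
    reps = [mem[0] for mem in table.members]
    sub = aln.subset(reps)
    if sub.n < 3:
        return {"error": "fewer than 3 distinct haplotypes"}
    tree, skipped = ph.bootstrap_support(sub, n_reps=n_reps, seed=seed,
                                         missing_policy=missing_policy)
    (outdir / f"{spc.name}_nj.nwk").write_text(tree.newick + "\n")
    return {
        "n_leaves": sub.n,
        "skipped_bootstrap_replicates": skipped,
        "clamped_branches": tree.clamped_branches,
        "newick": tree.newick,
    }


def run_phylogeography(config: AnalysisConfig, outdir: str | Path) -> dict:
    """Run the per-species genetic pipeline; returns (and writes) the
    report bundle as JSON plus per-table CSV/graph files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for h in list(log.handlers):
        log.removeHandler(h)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.propagate = False
    import phylogeocat

    bundle: dict = {
        "version": getattr(phylogeocat, "__version__", "0"),
        "seed": config.seed,
        "settings": {
            "n_sims": config.n_sims, "n_perm": config.n_perm,
            "n_boot": config.n_boot, "missing_policy": config.missing_policy,
        },
        "species": {},
    }
    log.info("version=%s seed=%s settings=%s", bundle["version"], config.seed,
             bundle["settings"])
    mp = config.missing_policy
    for i, spc in enumerate(config.species):
        seed = config.seed + 1000 * i
        aln, meta = _load_species(spc, mp)
        rep = {"diversity": _diversity(aln, mp)}
        rep["neutrality"] = _neutrality(aln, config.n_sims, seed, mp)
        rep["mismatch"] = _mismatch(aln, spc, config.n_boot, seed, mp)
        rep["structure"] = _structure(aln, meta, spc.schemes, config.n_perm, seed, mp)
        rep["ibd"] = _ibd(aln, meta, spc.schemes[0], config.n_perm, seed, mp)
        rep["network"] = _network(aln, meta, outdir, spc.name, mp)
        rep["tree"] = _tree(aln, spc, config.n_bootstrap_tree, seed, outdir, mp)
        bundle["species"][spc.name] = rep
        pd.DataFrame([rep["diversity"]]).to_csv(
            outdir / f"{spc.name}_diversity.csv", index=False
        )
    (outdir / "phylogeography.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle


# ---------------------------------------------------------------------------
# Niche


def run_niche(config: AnalysisConfig, outdir: str | Path) -> dict:
    """Run the BIOCLIM niche pipeline; writes model JSON, suitability
    grid, AUC table and threshold report."""
    if config.niche is None:
        raise StageError("stage 'niche' failed: no niche block in config")
    ncfg = config.niche
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    full_stack = nc.ClimateStack.from_directory(ncfg.rasters)
    presences = nc.PresenceRecords.from_csv(ncfg.presences)
    table = nc.extract_values(full_stack, presences)
    kept = nc.correlation_filter(table, r_max=ncfg.r_max,
                                 priority=ncfg.priority or None)
    stack = nc.ClimateStack(layers={v: full_stack.layers[v] for v in kept})
    model = nc.fit_envelope(table[kept], tail=ncfg.tail)
    model.to_json(outdir / "envelope_model.json")
    suit, member = nc.suitability(model, stack)
    nc.write_ascii_grid(suit, outdir / "suitability.asc")
    nc.write_ascii_grid(member, outdir / "envelope_membership.asc")
    reps = nc.replicate_protocol(
        presences, stack, n_reps=ncfg.n_reps, train_frac=ncfg.train_frac,
        tail=ncfg.tail, seed=config.seed,
    )
    auc_df = pd.DataFrame(
        [
            {"replicate": r.replicate, "auc": r.auc,
             "n_presence_test": r.n_presence_test, "n_absence": r.n_absence}
            for r in reps
        ]
    )
    auc_df.to_csv(outdir / "auc_replicates.csv", index=False)
    summary = nc.auc_summary(reps)
    # threshold mapping reads the raw variable, filtered or not
    thr = (
        nc.threshold_map(full_stack, ncfg.threshold_variable, presences,
                         ncfg.threshold_value)
        if ncfg.threshold_variable in full_stack.layers
        else None
    )
    bundle = {
        "variables_kept": kept,
        "envelopes": {k: list(v) for k, v in model.envelopes.items()},
        "auc": summary,
        "threshold": None if thr is None else {
            "variable": thr.variable, "mean": round(thr.mean, 3),
            "ci95": [round(x, 3) for x in thr.ci95], "max": round(thr.max, 3),
            "threshold": thr.threshold, "n_exceeding": thr.n_exceeding, "n": thr.n,
        },
    }
    (outdir / "niche.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle


# ---------------------------------------------------------------------------
# Synthetic input bundle


def generate_fixture(outdir: str | Path, seed: int = 1,
                     n_per_species: tuple[int, int] = (30, 24)) -> Path:
    """Write a complete synthetic two-species input bundle + config.yaml.

    Species A is simulated under a sudden expansion (one panmictic
    population sampled across regions); species B under a two-island
    split with no migration, mirroring an expanding generalist versus a
    deeply structured species. Rasters carry a north-south temperature
    gradient; presences obey a hard bio5 ceiling.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # species A: expansion
    mA = sd.DemographyModel(kind="sudden_expansion", theta0=1.0, theta1=100.0,
                            tau=4.0, samples=(n_per_species[0],))
    simA = sd.simulate_alignment(mA, L=601, seed=int(rng.integers(1, 2**31 - 1)))
    # species B: two islands, deep split
    nb = n_per_species[1] // 2
    mB = sd.DemographyModel(kind="two_island", theta=3.0, M=0.0, T=5.0,
                            samples=(nb, n_per_species[1] - nb))
    simB = sd.simulate_alignment(mB, L=564, seed=int(rng.integers(1, 2**31 - 1)))

    regionsA = ["north", "center", "south"]
    for sim, name, L_split in ((simA, "speciesA", 460), (simB, "speciesB", 362)):
        aln = sim.alignment
        # split concatenated sequence into two "gene" FASTAs
        fa1 = seqio.SequenceAlignment(
            tuple((sid, s[:L_split]) for sid, s in aln.records))
        fa2 = seqio.SequenceAlignment(
            tuple((sid, s[L_split:]) for sid, s in aln.records))
        seqio.write_fasta(fa1, outdir / f"{name}_gene1.fasta")
        seqio.write_fasta(fa2, outdir / f"{name}_gene2.fasta")
        rows = []
        for i, sid in enumerate(aln.ids):
            if name == "speciesA":
                pop = regionsA[i % 3]
                lat = {"north": 30.0, "center": 24.0, "south": 14.0}[pop]
            else:
                pop = sim.populations[sid]
                lat = 32.0 if pop == "pop0" else 11.0
            lat = float(np.clip(lat + rng.uniform(-1.5, 1.5), 10.2, 34.8))
            lon = float(rng.uniform(72, 88))
            rows.append({
                "sample_id": sid, "population": pop, "biogeographic": pop,
                "taxonomic": pop, "latitudinal": st.assign_latitudinal_class(lat),
                "latitude": round(lat, 4), "longitude": round(lon, 4),
            })
        pd.DataFrame(rows).to_csv(outdir / f"{name}_metadata.csv", index=False)

    # climate + presences
    rasters = outdir / "rasters"
    rasters.mkdir(exist_ok=True)
    specs = [
        sd.GradientSpec("bio5", base=18.0, row_slope=0.5, noise_sd=0.5),
        sd.GradientSpec("bio7", base=10.0, col_slope=0.3, noise_sd=0.5),
        sd.GradientSpec("bio13", base=300.0, row_slope=-2.0, noise_sd=5.0),
    ]
    stack = sd.simulate_climate_stack((40, 40), specs, seed=seed + 7)
    for var, grid in stack.layers.items():
        nc.write_ascii_grid(grid, rasters / f"{var}.asc")
    pres = sd.sample_presences(
        stack, lambda v: v["bio5"] < 32.0, n=140, seed=seed + 8)
    pres.to_csv(outdir / "presences.csv")

    config = {
        "seed": seed,
        "n_sims": 200, "n_perm": 200, "n_boot": 50, "n_bootstrap_tree": 100,
        "species": [
            {"name": "speciesA",
             "fasta": [str(outdir / "speciesA_gene1.fasta"),
                       str(outdir / "speciesA_gene2.fasta")],
             "metadata": str(outdir / "speciesA_metadata.csv"),
             "schemes": ["biogeographic", "latitudinal"]},
            {"name": "speciesB",
             "fasta": [str(outdir / "speciesB_gene1.fasta"),
                       str(outdir / "speciesB_gene2.fasta")],
             "metadata": str(outdir / "speciesB_metadata.csv"),
             "schemes": ["biogeographic"]},
        ],
        "niche": {"rasters": str(rasters), "presences": str(outdir / "presences.csv"),
                  "threshold_variable": "bio5", "threshold_value": 32.0,
                  "priority": ["bio5", "bio7", "bio13"]},
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """Comparative mtDNA phylogeography and BIOCLIM niche modelling."""


def _common(fn):
    fn = click.option("--config", "config_path", required=True,
                      type=click.Path(exists=True))(fn)
    fn = click.option("--out", "outdir", required=True, type=click.Path())(fn)
    fn = click.option("--seed", type=int, default=None,
                      help="override the config seed")(fn)
    return fn


def _load_config(config_path, seed):
    cfg = AnalysisConfig.from_yaml(config_path)
    if seed is not None:
        cfg.seed = seed
    return cfg


@cli.command()
@_common
def all(config_path, outdir, seed):  # noqa: A001 - CLI verb
    """Run the genetic pipeline and the niche model."""
    cfg = _load_config(config_path, seed)
    run_phylogeography(cfg, outdir)
    if cfg.niche is not None:
        run_niche(cfg, outdir)
    click.echo(f"reports written to {outdir}")


@cli.command()
@_common
def phylogeography(config_path, outdir, seed):
    """Diversity, neutrality, mismatch, AMOVA, network, tree, Mantel."""
    cfg = _load_config(config_path, seed)
    run_phylogeography(cfg, outdir)
    click.echo(f"reports written to {outdir}")


@cli.command()
@_common
def niche(config_path, outdir, seed):
    """BIOCLIM envelope model, AUC replicates and threshold report."""
    cfg = _load_config(config_path, seed)
    run_niche(cfg, outdir)
    click.echo(f"reports written to {outdir}")


@cli.command()
@click.option("--out", "outdir", required=True, type=click.Path())
@click.option("--seed", type=int, default=1)
def simulate(outdir, seed):
    """Write a synthetic two-species input bundle plus config.yaml."""
    cfg = generate_fixture(outdir, seed=seed)
    click.echo(f"fixture config at {cfg}")
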