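"""BIOCLIM percentile-envelope niche modelling.

The model is presence-only: for each climate variable an envelope
[quantile(q), quantile(1-q)] of the training presence values is computed
(default tail q = 0.025, i.e. the central 95%). A grid cell's suitability
for one variable is the tent function of its training percentile P,

    s = 1 - 2·|P - 0.5|   (0 outside the envelope),

so cells at the training median score 1 and scores fall off linearly
toward the envelope edges; the cell's overall suitability is the minimum
across variables. Models are evaluated against random pseudo-absences with
the rank-based (Mann-Whitney) AUC over replicate 75/25 presence splits.

Rasters are ESRI ASCII grids (north-up, origin at the lower-left corner
per the format's ``xllcorner/yllcorner``, cell-center registration for
point extraction), read and written directly with numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0


class PointError(ValueError):
    """Points fall outside the raster extent or on nodata cells."""


class SamplingError(ValueError):
    """Requested more samples than available valid cells."""


# ---------------------------------------------------------------------------
# Rasters


@dataclass(frozen=True)
class Grid:
    """One raster layer: values[row, col], row 0 = northernmost."""

    values: np.ndarray  # float, np.nan marks nodata
    xll: float
    yll: float
    cellsize: float

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest cell (row, col) for a point; raises PointError outside."""
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise PointError(f"point ({lat}, {lon}) outside raster extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - row + 0.5) * self.cellsize
        return lat, lon


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (.asc); nodata becomes NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    vals = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    vals[vals == nodata] = np.nan
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data block does not match header dimensions")
    return Grid(
        values=vals,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )


def write_ascii_grid(grid: Grid, path: str | Path, nodata: float = DEFAULT_NODATA) -> None:
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {grid.cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


@dataclass(frozen=True)
class ClimateStack:
    """Named co-registered climate layers sharing shape/extent/mask."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty climate stack")
        grids = list(self.layers.values())
        g0 = grids[0]
        for g in grids[1:]:
            if (
                g.values.shape != g0.values.shape
                or g.xll != g0.xll
                or g.yll != g0.yll
                or g.cellsize != g0.cellsize
            ):
                raise ValueError("all layers must share shape, extent and cell size")
            if not np.array_equal(np.isnan(g.values), np.isnan(g0.values)):
                raise ValueError("all layers must share the nodata mask")

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    @property
    def reference(self) -> Grid:
        return next(iter(self.layers.values()))

    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.reference.values)

    @staticmethod
    def from_directory(path: str | Path) -> "ClimateStack":
        path = Path(path)
        layers = {
            p.stem: read_ascii_grid(p) for p in sorted(path.glob("*.asc"))
        }
        return ClimateStack(layers=layers)


@dataclass(frozen=True)
class PresenceRecords:
    """Deduplicated (lat, lon) occurrence points with provenance tags."""

    points: tuple[tuple[float, float], ...]
    sources: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.points)) != len(self.points):
            raise ValueError("presence points must be unique")
        if self.sources and len(self.sources) != len(self.points):
            raise ValueError("sources must match points")

    @property
    def n(self) -> int:
        return len(self.points)

    @staticmethod
    def from_csv(path: str | Path) -> "PresenceRecords":
        import pandas as pd

        df = pd.read_csv(path)
        pts = tuple(zip(df["latitude"].astype(float), df["longitude"].astype(float)))
        src = tuple(df["source"].astype(str)) if "source" in df.columns else ()
        return PresenceRecords(points=pts, sources=src)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("latitude,longitude,source\n")
            srcs = self.sources or ("",) * self.n
            for (lat, lon), s in zip(self.points, srcs):
                fh.write(f"{lat},{lon},{s}\n")


# ---------------------------------------------------------------------------
# Extraction and variable filtering


def extract_values(stack: ClimateStack, points: PresenceRecords):
    """Nearest-cell values per point, as a pandas DataFrame (row order
    preserved). Points outside the extent or on nodata cells raise
    :class:`PointError` listing the offenders."""
    import pandas as pd

    ref = stack.reference
    bad: list[tuple[float, float]] = []
    cells: list[tuple[int, int]] = []
    for lat, lon in points.points:
        try:
            r, c = ref.cell_of(lat, lon)
        except PointError:
            bad.append((lat, lon))
            continue
        if np.isnan(ref.values[r, c]):
            bad.append((lat, lon))
            continue
        cells.append((r, c))
    if bad:
        raise PointError(f"points outside extent or on nodata cells: {bad}")
    data = {
        name: [g.values[r, c] for r, c in cells] for name, g in stack.layers.items()
    }
    return pd.DataFrame(data)


def correlation_filter(values, r_max: float = 0.7, priority: list[str] | None = None):
    """Greedy Pearson-correlation variable filter.

    Repeatedly finds the most-correlated remaining pair with |r| > r_max
    and drops the lower-priority member (priority = caller-supplied order,
    default column order). Constant columns are excluded with a warning.
    Returns the kept variable names in priority order.
    """
    import warnings

    cols = list(values.columns)
    if len(cols) < 2 or len(values) < 3:
        raise ValueError("correlation filter needs >= 2 variables and >= 3 rows")
    keep = []
    for c in cols:
        if values[c].std(ddof=0) == 0:
            warnings.warn(f"constant column {c!r} excluded", stacklevel=2)
        else:
            keep.append(c)
    order = priority or cols
    rank = {c: order.index(c) if c in order else len(order) for c in keep}
    corr = values[keep].corr().abs()
    while True:
        worst = None
        for i, a in enumerate(keep):
            for b in keep[i + 1 :]:
                r = corr.loc[a, b]
                if r > r_max and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        drop = b if rank[a] <= rank[b] else a
        keep.remove(drop)
    return sorted(keep, key=lambda c: rank[c])


# ---------------------------------------------------------------------------
# Envelope model


@dataclass(frozen=True)
class EnvelopeModel:
    """Per-variable percentile envelopes plus the sorted training values
    retained for percentile (tent) scoring."""

    envelopes: dict[str, tuple[float, float]]
    training: dict[str, np.ndarray]  # sorted
    tail: float

    @property
    def variables(self) -> list[str]:
        return list(self.envelopes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tail": self.tail,
            "envelopes": {k: list(v) for k, v in self.envelopes.items()},
            "training": {k: list(map(float, v)) for k, v in self.training.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "EnvelopeModel":
        payload = json.loads(Path(path).read_text())
        return EnvelopeModel(
            envelopes={k: tuple(v) for k, v in payload["envelopes"].items()},
            training={k: np.array(v) for k, v in payload["training"].items()},
            tail=payload["tail"],
        )


def fit_envelope(values, tail: float = 0.025) -> EnvelopeModel:
    """Fit per-variable envelopes at the given two-sided tail fraction.

    Quantiles use linear interpolation between order statistics. Requires
    >= 5 presence rows with valid values.
    """
    if not (0 <= tail < 0.5):
        raise ValueError("tail must be in [0, 0.5)")
    if len(values) < 5:
        raise ValueError("envelope fitting requires >= 5 presences")
    envelopes: dict[str, tuple[float, float]] = {}
    training: dict[str, np.ndarray] = {}
    for col in values.columns:
        v = np.sort(np.asarray(values[col], dtype=float))
        if np.isnan(v).any():
            raise ValueError(f"variable {col!r} has missing values")
        lo, hi = np.quantile(v, [tail, 1.0 - tail], method="linear")
        envelopes[col] = (float(lo), float(hi))
        training[col] = v
    return EnvelopeModel(envelopes=envelopes, training=training, tail=tail)


def _tent_score(x: np.ndarray, train: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """1 - 2|P - 0.5| with P the training percentile; 0 outside [lo, hi].

    P uses the midpoint rank convention (ties average left/right ranks) so
    every value inside the training support gets 0 < P < 1 and hence a
    strictly positive tent score.
    """
    left = np.searchsorted(train, x, side="left")
    right = np.searchsorted(train, x, side="right")
    p = (left + right) / (2.0 * len(train))
    s = 1.0 - 2.0 * np.abs(p - 0.5)
    s[(x < lo) | (x > hi)] = 0.0
    return s


def suitability(
    model: EnvelopeModel, stack: ClimateStack
) -> tuple[Grid, Grid]:
    """Suitability grid (min over per-variable tent scores) plus the
    Boolean all-envelopes-membership grid; nodata propagates as NaN."""
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks model variables: {missing}")
    ref = stack.reference
    score = np.full(ref.values.shape, np.inf)
    inside = np.ones(ref.values.shape, dtype=float)
    for var in model.variables:
        vals = stack.layers[var].values
        lo, hi = model.envelopes[var]
        s = _tent_score(vals.ravel(), model.training[var], lo, hi).reshape(vals.shape)
        score = np.minimum(score, s)
        inside = inside * ((vals >= lo) & (vals <= hi))
    mask = ~stack.valid_mask()
    score[mask] = np.nan
    inside[mask] = np.nan
    g = lambda a: Grid(values=a, xll=ref.xll, yll=ref.yll, cellsize=ref.cellsize)
    return g(score), g(inside)


def score_points(model: EnvelopeModel, stack: ClimateStack, points: PresenceRecords) -> np.ndarray:
    """Suitability of individual points (same tent-min rule)."""
    table = extract_values(stack, points)
    scores = np.full(len(table), np.inf)
    for var in model.variables:
        lo, hi = model.envelopes[var]
        s = _tent_score(np.asarray(table[var], float), model.training[var], lo, hi)
        scores = np.minimum(scores, s)
    return scores


# ---------------------------------------------------------------------------
# Pseudo-absences and evaluation


def pseudo_absences(stack: ClimateStack, n: int, seed: int = 0) -> PresenceRecords:
    """Uniform sample of n distinct valid (non-nodata) cell centers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ref = stack.reference
    valid = np.argwhere(stack.valid_mask())
    if n > len(valid):
        raise SamplingError(f"requested {n} points but only {len(valid)} valid cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(valid), size=n, replace=False)
    pts = tuple(ref.center_of(int(r), int(c)) for r, c in valid[pick])
    return PresenceRecords(points=pts, sources=("pseudo-absence",) * n)


@dataclass(frozen=True)
class AucResult:
    auc: float
    n_presence_test: int
    n_absence: int
    replicate: int
    seed: int
    degenerate: bool = False


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic / (n·m); ties count half."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    from scipy.stats import rankdata

    allv = np.concatenate([pos, neg])
    ranks = rankdata(allv)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def evaluate_auc(
    model: EnvelopeModel,
    presence_test: PresenceRecords,
    absences: PresenceRecords,
    stack: ClimateStack,
    replicate: int = 0,
    seed: int = 0,
) -> AucResult:
    if presence_test.n == 0 or absences.n == 0:
        raise ValueError("both point sets must be non-empty")
    pos = score_points(model, stack, presence_test)
    neg = score_points(model, stack, absences)
    degenerate = bool(np.all(np.concatenate([pos, neg]) == pos[0]))
    auc = 0.5 if degenerate else auc_mann_whitney(pos, neg)
    return AucResult(
        auc=auc,
        n_presence_test=presence_test.n,
        n_absence=absences.n,
        replicate=replicate,
        seed=seed,
        degenerate=degenerate,
    )


def replicate_protocol(
    presences: PresenceRecords,
    stack: ClimateStack,
    n_reps: int = 10,
    train_frac: float = 0.75,
    tail: float = 0.025,
    seed: int = 0,
) -> list[AucResult]:
    """Replicate 75/25 split-and-evaluate protocol.

    Per replicate: random train/test split of the presences, envelope fit
    on the training part, AUC of the test part against freshly drawn
    pseudo-absences of size equal to the full presence count.
    """
    if presences.n < 8:
        raise ValueError("replicate protocol requires >= 8 presences")
    rng = np.random.default_rng(seed)
    results: list[AucResult] = []
    for rep in range(n_reps):
        idx = rng.permutation(presences.n)
        n_train = int(round(train_frac * presences.n))
        tr = PresenceRecords(points=tuple(presences.points[i] for i in idx[:n_train]))
        te = PresenceRecords(points=tuple(presences.points[i] for i in idx[n_train:]))
        model = fit_envelope(extract_values(stack, tr), tail=tail)
        rep_seed = int(rng.integers(1, 2**31 - 1))
        absences = pseudo_absences(stack, presences.n, seed=rep_seed)
        results.append(
            evaluate_auc(model, te, absences, stack, replicate=rep, seed=rep_seed)
        )
    return results


def auc_summary(results: list[AucResult]) -> dict[str, float]:
    aucs = np.array([r.auc for r in results])
    return {
        "mean": float(aucs.mean()),
        "min": float(aucs.min()),
        "max": float(aucs.max()),
        "n_reps": len(results),
    }


# ---------------------------------------------------------------------------
# Threshold mapping


@dataclass(frozen=True)
class ThresholdReport:
    variable: str
    mean: float
    ci95: tuple[float, float]
    max: float
    threshold: float
    n_exceeding: int
    n: int


def threshold_map(
    stack: ClimateStack,
    variable: str,
    presences: PresenceRecords,
    threshold: float,
) -> ThresholdReport:
    """Summarise one variable at the presence points against a hard limit.

    Reports the mean with its 95% t-interval, the maximum, and how many
    presences exceed the supplied threshold.
    """
    if variable not in stack.layers:
        raise KeyError(f"variable {variable!r} not in stack")
    sub = ClimateStack(layers={variable: stack.layers[variable]})
    vals = np.asarray(extract_values(sub, presences)[variable], float)
    n = len(vals)
    mean = float(vals.mean())
    if n > 1 and vals.std(ddof=1) > 0:
        from scipy.stats import t as t_dist

        half = float(t_dist.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n))
    else:
        half = 0.0
    return ThresholdReport(
        variable=variable,
        mean=mean,
        ci95=(mean - half, mean + half),
        max=float(vals.max()),
        threshold=threshold,
        n_exceeding=int(np.sum(vals > threshold)),
        n=n,
    )
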