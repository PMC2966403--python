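"""Aligned mtDNA sequence handling: FASTA I/O, fragment concatenation,
haplotype collapsing and polymorphic-site summaries.

All downstream genetics (diversity statistics, mismatch distributions,
AMOVA, networks, trees) operates on :class:`SequenceAlignment`, an ordered,
equal-length collection of sequences over the alphabet ``{A,C,G,T,N,-}``.
Missing data (``N``) and alignment gaps (``-``) are handled by a single
*missing policy*:

``complete-deletion``
    columns containing ``N`` or ``-`` in *any* record are dropped before an
    analysis (the convention of the standard population-genetics packages,
    and the default here);
``strict``
    sequences are compared character-by-character as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

MissingPolicy = Literal["strict", "complete-deletion"]


class AlignmentError(ValueError):
    """Sequences violate the equal-length/unique-id alignment contract."""


class FormatError(ValueError):
    """Malformed or empty input file."""


class DegenerateDataError(ValueError):
    """An operation removed every usable column."""


@dataclass(frozen=True)
class SequenceAlignment:
    """An ordered multiple sequence alignment of mtDNA fragments.

    Records are ``(sample_id, sequence)`` pairs; sequences are stored
    upper-case over ``{A,C,G,T,N,-}`` and must share one length.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1 or 0 in lengths:
            raise AlignmentError(
                f"records have unequal lengths {sorted(lengths)}; an alignment "
                "requires one common length >= 1"
            )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        for sid, seq in self.records:
            bad = set(seq) - ALPHABET
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"illegal symbol {seq[pos]!r} in record {sid!r} at position {pos}"
                )

    # -- basic views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, ids: Iterable[str]) -> "SequenceAlignment":
        wanted = list(ids)
        missing = sorted(set(wanted) - set(self.ids))
        if missing:
            raise KeyError(f"sample ids not in alignment: {missing}")
        keep = set(wanted)
        return SequenceAlignment(
            tuple((sid, seq) for sid, seq in self.records if sid in keep)
        )

    @staticmethod
    def from_records(records: Iterable[tuple[str, str]]) -> "SequenceAlignment":
        return SequenceAlignment(tuple((sid, normalize(seq)) for sid, seq in records))


def normalize(seq: str) -> str:
    """Upper-case a sequence and map RNA ``U`` to ``T`` (with a warning)."""
    up = seq.upper()
    if "U" in up:
        warnings.warn("sequence contains 'U'; mapping to 'T'", stacklevel=2)
        up = up.replace("U", "T")
    return up


def used_columns(aln: SequenceAlignment, missing_policy: MissingPolicy) -> np.ndarray:
    """Boolean mask of columns retained under the missing policy."""
    arr = aln.to_array()
    if missing_policy == "strict":
        return np.ones(arr.shape[1], dtype=bool)
    return ~((arr == "N") | (arr == "-")).any(axis=0)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file into a :class:`SequenceAlignment`.

    Record order is preserved; lower-case input is normalized. Unequal
    record lengths raise :class:`AlignmentError`; an empty file raises
    :class:`FormatError`.
    """
    path = Path(path)
    records = [(rec.id, normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return SequenceAlignment(tuple(records))


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metadata

METADATA_COLUMNS = [
    "sample_id",
    "population",
    "biogeographic",
    "taxonomic",
    "latitudinal",
    "latitude",
    "longitude",
]


def read_metadata(path: str | Path):
    """Read the sample metadata CSV (see :data:`METADATA_COLUMNS`).

    Latitude/longitude may be blank; when present they must be valid
    decimal degrees.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in ("sample_id", "population") if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError("metadata has duplicate sample_id values")
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
            if len(bad):
                raise FormatError(f"{col} out of range [{lo},{hi}]: {bad.tolist()}")
            df[col] = vals
    return df


# ---------------------------------------------------------------------------
# Concatenation


def concatenate(aln_a: SequenceAlignment, aln_b: SequenceAlignment) -> SequenceAlignment:
    """Concatenate two gene fragments sample-by-sample (A then B).

    The id sets must match exactly; record order follows ``aln_a``.
    """
    ids_a, ids_b = set(aln_a.ids), set(aln_b.ids)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise KeyError(f"sample id sets differ; symmetric difference: {diff}")
    b_map = dict(aln_b.records)
    return SequenceAlignment(tuple((sid, seq + b_map[sid]) for sid, seq in aln_a.records))


# ---------------------------------------------------------------------------
# Haplotypes


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with their multiplicities and memberships.

    Ordered by decreasing count, ties broken by first occurrence in the
    source alignment, so output is deterministic.
    """

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]
    columns_used: tuple[int, ...] = field(default=())

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return sum(self.counts)

    def per_population_counts(self, assignment: dict[str, str]) -> "np.ndarray":
        """Haplotype x population count matrix (populations sorted by name)."""
        pops = sorted(set(assignment.values()))
        mat = np.zeros((self.k, len(pops)), dtype=int)
        pop_idx = {p: j for j, p in enumerate(pops)}
        for i, mem in enumerate(self.members):
            for sid in mem:
                mat[i, pop_idx[assignment[sid]]] += 1
        return mat


def collapse_haplotypes(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Under ``complete-deletion`` every column containing ``N`` or ``-`` in any
    record is removed before comparison; under ``strict`` raw sequences are
    compared. Raises :class:`DegenerateDataError` if no column survives.
    """
    mask = used_columns(aln, missing_policy)
    if not mask.any():
        raise DegenerateDataError("complete-deletion removed every column")
    cols = np.flatnonzero(mask)
    arr = aln.to_array()[:, mask]
    keyed = ["".join(row) for row in arr]

    order: dict[str, int] = {}
    groups: dict[str, list[str]] = {}
    for sid, key in zip(aln.ids, keyed):
        if key not in order:
            order[key] = len(order)
            groups[key] = []
        groups[key].append(sid)

    haps = sorted(order, key=lambda h: (-len(groups[h]), order[h]))
    return HaplotypeTable(
        haplotypes=tuple(haps),
        counts=tuple(len(groups[h]) for h in haps),
        members=tuple(tuple(groups[h]) for h in haps),
        columns_used=tuple(int(c) for c in cols),
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write the haplotype table as TSV: index, sequence, count, member ids."""
    with open(path, "w") as fh:
        fh.write("haplotype\tsequence\tcount\tmembers\n")
        for i, (hap, cnt, mem) in enumerate(
            zip(table.haplotypes, table.counts, table.members), start=1
        ):
            fh.write(f"H{i}\t{hap}\t{cnt}\t{','.join(mem)}\n")


# ---------------------------------------------------------------------------
# Polymorphic sites


@dataclass(frozen=True)
class SiteSummary:
    """Counts of segregating sites and their transition/transversion status."""

    S: int
    transitions: int
    transversions: int
    positions: tuple[int, ...]


def site_summary(
    aln: SequenceAlignment, missing_policy: MissingPolicy = "complete-deletion"
) -> SiteSummary:
    """Census polymorphic sites.

    A site is segregating when >= 2 distinct symbols among ``{A,C,G,T}``
    occur in the retained columns. Each segregating site contributes a
    transition for every observed purine-purine / pyrimidine-pyrimidine
    state pair and a transversion for every mixed pair, so a site with more
    than two states may count toward both.
    """
    if aln.n < 2:
        raise AlignmentError("site summary requires >= 2 records")
    mask = used_columns(aln, missing_policy)
    arr = aln.to_array()
    positions: list[int] = []
    ti = tv = 0
    for j in np.flatnonzero(mask):
        states = set(arr[:, j]) & set("ACGT")
        if len(states) < 2:
            continue
        positions.append(int(j))
        site_ti = site_tv = 0
        ordered = sorted(states)
        for a_i in range(len(ordered)):
            for b_i in range(a_i + 1, len(ordered)):
                a, b = ordered[a_i], ordered[b_i]
                if (a in PURINES) == (b in PURINES):
                    site_ti += 1
                else:
                    site_tv += 1
        ti += site_ti
        tv += site_tv
    return SiteSummary(
        S=len(positions), transitions=ti, transversions=tv, positions=tuple(positions)
    )
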