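"""Domain types, coordinate conventions and file IO for OK-seq analysis.

Conventions fixed package-wide
------------------------------
* All intervals are 0-based, half-open (BED convention).
* ``Watson`` is the reference plus strand (BED ``+``); ``Crick`` the minus
  strand (``-``).  Watson-mapping Okazaki fragments derive from
  leftward-moving replication forks, Crick-mapping fragments from
  rightward-moving forks.
* The 5' end of a Watson fragment is its ``start``; the 5' end of a Crick
  fragment is ``end - 1`` (the last covered base).  3' ends are the opposite
  extremities.

File formats handled here: BED6 (fragments, tRNA/stall loci), BED3 (dyads,
exclusion regions), 2-column chromosome-sizes TSV, a house origin TSV
(columns ``chromosome  midpoint  name  [t_rep]  [fkh_class]
[true_competence]``), and bedGraph for binned tracks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

WATSON = "+"
CRICK = "-"

FKH_CLASSES = ("activated", "repressed", "independent", "unknown")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp) of the genome fragments map to."""

    sizes: dict[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise ValidationError("genome has no chromosomes")
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has length {length} <= 0")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a 2-column ``name<TAB>length`` table into a :class:`GenomeLayout`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 tab-separated columns", path, lineno)
            name = fields[0]
            if name in sizes:
                raise ParseError(f"duplicate chromosome {name!r}", path, lineno)
            try:
                sizes[name] = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer length {fields[1]!r}", path, lineno) from None
    return GenomeLayout(sizes)


def write_chrom_sizes(genome: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Okazaki fragments
# ---------------------------------------------------------------------------

class OkFragmentSet:
    """A pooled collection of stranded Okazaki-fragment intervals.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``chrom, start, end, name, score, strand``; the strand column holds the
    BED symbols (``+`` = Watson, ``-`` = Crick).
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeLayout | None = None,
                 validate: bool = True):
        df = df.reset_index(drop=True)
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = "." if col == "name" else 0
        self.df = df[FRAGMENT_COLUMNS].copy()
        self.df["start"] = self.df["start"].astype(np.int64)
        self.df["end"] = self.df["end"].astype(np.int64)
        self.genome = genome
        if validate:
            self._validate()

    @classmethod
    def from_arrays(cls, chrom, start, end, strand, genome=None, name=None,
                    validate: bool = True) -> "OkFragmentSet":
        df = pd.DataFrame({
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "name": "." if name is None else name,
            "score": 0,
            "strand": strand,
        })
        return cls(df, genome=genome, validate=validate)

    @classmethod
    def empty(cls, genome=None) -> "OkFragmentSet":
        return cls(pd.DataFrame(columns=FRAGMENT_COLUMNS), genome=genome)

    def _validate(self):
        df = self.df
        if len(df) == 0:
            return
        bad = ~df["strand"].isin([WATSON, CRICK])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"record {i}: strand must be '+' or '-', got "
                                  f"{df['strand'].iloc[i]!r}")
        bad = (df["start"].to_numpy() < 0) | (df["start"].to_numpy() >= df["end"].to_numpy())
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"record {i}: invalid interval [{df['start'].iloc[i]}, {df['end'].iloc[i]})")
        if self.genome is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.genome:
                    raise ValidationError(f"unknown chromosome {chrom!r}")
                if (sub["end"].to_numpy() > self.genome.length(chrom)).any():
                    raise ValidationError(
                        f"fragment extends past end of chromosome {chrom!r}")

    def __len__(self) -> int:
        return len(self.df)

    def canonical(self) -> pd.DataFrame:
        """Deterministic record order: (chrom, start, end, strand)."""
        return (self.df.sort_values(["chrom", "start", "end", "strand"],
                                    kind="mergesort")
                .reset_index(drop=True))

    def __eq__(self, other) -> bool:
        if not isinstance(other, OkFragmentSet):
            return NotImplemented
        a = self.canonical()[["chrom", "start", "end", "strand"]]
        b = other.canonical()[["chrom", "start", "end", "strand"]]
        return a.equals(b)

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2

    def lengths(self) -> np.ndarray:
        return self.df["end"].to_numpy() - self.df["start"].to_numpy()

    def subset_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


def read_fragments(path, genome: GenomeLayout) -> OkFragmentSet:
    """Read a stranded BED6 file of Okazaki fragments, validating every record."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=FRAGMENT_COLUMNS, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return OkFragmentSet.empty(genome)

    if df["strand"].isna().any() or df["start"].isna().any() or df["end"].isna().any():
        lineno = int(df.index[df.isna().any(axis=1)][0]) + 1
        raise ParseError("expected 6 tab-separated BED columns", path, lineno)
    for col in ("start", "end"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            raise ParseError(f"non-integer {col}", path, int(df.index[bad][0]) + 1) from None
    try:
        return OkFragmentSet(df, genome=genome)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_fragments(frags: OkFragmentSet, path) -> None:
    """Write fragments as BED6 in canonical (chrom, start, end, strand) order."""
    frags.canonical().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Origins
# ---------------------------------------------------------------------------

ORIGIN_COLUMNS = ["chromosome", "midpoint", "name", "t_rep", "fkh_class",
                  "true_competence"]


class OriginTable:
    """Replication origins with midpoint, timing (T_rep, minutes), Forkhead
    class, and — for simulations — true firing competence in [0, 1]."""

    def __init__(self, df: pd.DataFrame, genome: GenomeLayout | None = None):
        df = df.copy()
        for col, default in (("t_rep", np.nan), ("fkh_class", "unknown"),
                             ("true_competence", np.nan)):
            if col not in df.columns:
                df[col] = default
        df["fkh_class"] = df["fkh_class"].fillna("unknown")
        df["midpoint"] = df["midpoint"].astype(np.int64)
        df["t_rep"] = df["t_rep"].astype(float)
        df["true_competence"] = df["true_competence"].astype(float)
        df = df[ORIGIN_COLUMNS].sort_values(["chromosome", "midpoint"],
                                            kind="mergesort").reset_index(drop=True)
        if df["name"].duplicated().any():
            dup = df["name"][df["name"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate origin name {dup!r}")
        bad = ~df["fkh_class"].isin(FKH_CLASSES)
        if bad.any():
            raise ValidationError(
                f"unknown fkh_class {df['fkh_class'][bad].iloc[0]!r}")
        comp = df["true_competence"].to_numpy()
        if np.any((comp < 0) | (comp > 1)):
            raise ValidationError("true_competence outside [0, 1]")
        if genome is not None:
            for chrom, sub in df.groupby("chromosome", sort=False):
                if chrom not in genome:
                    raise ValidationError(f"origin on unknown chromosome {chrom!r}")
                m = sub["midpoint"].to_numpy()
                if np.any((m < 0) | (m >= genome.length(chrom))):
                    raise ValidationError(f"origin midpoint outside chromosome {chrom!r}")
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "OriginTable":
        return OriginTable(self.df[mask], genome=self.genome)

    def names(self) -> list[str]:
        return list(self.df["name"])


def read_origins(path, genome: GenomeLayout | None = None) -> OriginTable:
    """Read the house origin TSV (header row; required columns ``chromosome``,
    ``midpoint``, ``name``; optional ``t_rep``, ``fkh_class``,
    ``true_competence``)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "name": str})
    for col in ("chromosome", "midpoint", "name"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    mid = pd.to_numeric(df["midpoint"], errors="coerce")
    if mid.isna().any() or (mid != mid.round()).any():
        lineno = int(df.index[mid.isna() | (mid != mid.round())][0]) + 2
        raise ParseError("midpoint is not an integer", path, lineno)
    df["midpoint"] = mid.astype(np.int64)
    try:
        return OriginTable(df, genome=genome)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_origins(origins: OriginTable, path) -> None:
    origins.df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Point lists (nucleosome dyads) and interval lists (exclusions, loci)
# ---------------------------------------------------------------------------

def read_dyads(path, genome: GenomeLayout | None = None) -> dict[str, np.ndarray]:
    """Read nucleosome dyad positions from BED3; a record's dyad is the
    midpoint of its interval. Returns sorted position arrays per chromosome."""
    iv = read_intervals(path, genome)
    out: dict[str, np.ndarray] = {}
    for chrom, sub in iv.groupby("chrom", sort=False):
        pos = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        out[chrom] = np.sort(pos.astype(np.int64))
    return out


def read_intervals(path, genome: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a BED3 interval list (exclusion regions etc.)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        i = int(df.index[df["start"] >= df["end"]][0]) + 1
        raise ParseError("interval start >= end", path, i)
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValidationError(f"{path}: unknown chromosome {chrom!r}")
            if (sub["end"].to_numpy() > genome.length(chrom)).any():
                raise ValidationError(f"{path}: interval past end of {chrom!r}")
    return df.reset_index(drop=True)


def write_intervals(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_loci(path, genome: GenomeLayout | None = None) -> pd.DataFrame:
    """Read oriented loci (tRNA genes / stall sites) from BED6.

    Returns a DataFrame ``chrom, start, end, name, strand`` where strand is
    the transcription direction.
    """
    frags = read_fragments(path, genome) if genome is not None else None
    if frags is None:
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             names=FRAGMENT_COLUMNS, dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    else:
        df = frags.df
    return df[["chrom", "start", "end", "name", "strand"]].reset_index(drop=True)


def write_loci(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Binned tracks (bedGraph)
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """A fixed-bin numeric track over a genome; NaN marks masked bins.

    ``state`` records the processing stage of copy-number tracks
    (raw | normalized | smoothed); plain count tracks stay "raw".
    """

    genome: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    state: str = "raw"

    @classmethod
    def zeros(cls, genome: GenomeLayout, bin_size: int, state: str = "raw"):
        vals = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chromosomes}
        return cls(genome, bin_size, vals, state)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, self.bin_size,
                           {c: v.copy() for c, v in self.values.items()}, self.state)

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def flat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.chromosomes])


def read_bedgraph(path, genome: GenomeLayout, bin_size: int,
                  missing: float = np.nan) -> BinnedTrack:
    """Read a bedGraph whose intervals align to the ``bin_size`` grid.

    Bins absent from the file get ``missing`` (NaN by default, i.e. masked).
    """
    track = BinnedTrack.zeros(genome, bin_size)
    for v in track.values.values():
        v.fill(missing)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"], dtype={0: str})
    except pd.errors.EmptyDataError:
        return track
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValidationError(f"{path}: unknown chromosome {chrom!r}")
        start = sub["start"].to_numpy(dtype=np.int64)
        end = sub["end"].to_numpy(dtype=np.int64)
        if np.any(start % bin_size) or np.any((end - start) != bin_size):
            # tolerate a short final bin
            nb = genome.n_bins(chrom, bin_size)
            last_ok = (end == genome.length(chrom)) & (start == (nb - 1) * bin_size)
            if np.any((np.asarray(start % bin_size, bool) | ((end - start) != bin_size)) & ~last_ok):
                raise ParseError(f"intervals not aligned to {bin_size} bp grid on {chrom}", path)
        track.values[chrom][start // bin_size] = sub["value"].to_numpy(dtype=float)
    return track


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a binned track as bedGraph; masked (NaN) bins are omitted."""
    with open(path, "w") as fh:
        for chrom in track.genome.chromosomes:
            vals = track.values[chrom]
            length = track.genome.length(chrom)
            for i in np.flatnonzero(~np.isnan(vals)):
                start = int(i) * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[i]:.10g}\n")
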