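"""Origin Efficiency Metric (OEM), meta-origin profiles and class comparisons.

The OEM of an origin with midpoint m is the difference in Watson-strand
fraction between the 10 kb flank to its left and to its right:

    OEM = W_L / (W_L + C_L)  -  W_R / (W_R + C_R)

with left flank [m - window, m) and right flank [m, m + window).  Watson
fragments derive from leftward-moving forks, so an origin that fires in a
fraction f of cells diverts forks outward and shows OEM ~ f: the metric is a
proxy for the fraction of cells in which the origin fires actively.  OEM
lies in [-1, 1]; a flank with fewer than ``min_count`` fragments renders the
record undefined (NaN) rather than noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genome_io import OriginTable
from .strand_coverage import StrandedCoverage

OEM_TABLE_COLUMNS = ["name", "oem", "w_l", "c_l", "w_r", "c_r"]


@dataclass
class OEMRecord:
    name: str
    oem: float  # NaN when undefined
    w_l: float
    c_l: float
    w_r: float
    c_r: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.oem)


@dataclass
class MetaProfile:
    """Mean per-origin profile on offset bins relative to origin midpoints."""

    offsets: np.ndarray        # bin-center offsets, bp
    values: np.ndarray         # mean value per bin (NaN where no origin defined)
    n_origins: np.ndarray      # origins contributing per bin
    normalized: bool = False

    def normalize_max(self) -> "MetaProfile":
        peak = np.nanmax(self.values)
        if not np.isfinite(peak) or peak == 0:
            raise ValidationError("profile has no positive maximum")
        return MetaProfile(self.offsets, self.values / peak, self.n_origins, True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values,
                             "n_origins": self.n_origins})


def oem(cov: StrandedCoverage, chrom: str, midpoint: int, name: str = "",
        window: int = 10000, min_count: int = 50) -> OEMRecord:
    """OEM for a single origin from binned stranded counts.

    Flanks that run off the chromosome end are truncated to the available
    range (partial-window policy).
    """
    if window < cov.bin_size:
        raise ValidationError("window must be >= coverage bin size")
    length = cov.genome.length(chrom)
    if not 0 <= midpoint < length:
        raise ValidationError(f"origin midpoint {midpoint} outside {chrom!r}")
    left_lo = max(midpoint - window, 0)
    right_hi = min(midpoint + window, length)
    w_l, c_l = cov.counts_in(chrom, left_lo, midpoint) if midpoint > left_lo else (0.0, 0.0)
    w_r, c_r = cov.counts_in(chrom, midpoint, right_hi) if right_hi > midpoint else (0.0, 0.0)
    if (w_l + c_l) < min_count or (w_r + c_r) < min_count:
        value = float("nan")
    else:
        value = w_l / (w_l + c_l) - w_r / (w_r + c_r)
    return OEMRecord(name, value, w_l, c_l, w_r, c_r)


def oem_table(cov: StrandedCoverage, origins: OriginTable, window: int = 10000,
              min_count: int = 50) -> pd.DataFrame:
    """OEM for every origin, preserving origin order.

    Returns a DataFrame with columns ``name, oem, w_l, c_l, w_r, c_r``;
    undefined records carry NaN OEM.
    """
    if len(origins) == 0:
        raise ValidationError("empty origin table")
    records = []
    for row in origins.df.itertuples(index=False):
        rec = oem(cov, row.chromosome, int(row.midpoint), name=row.name,
                  window=window, min_count=min_count)
        records.append((rec.name, rec.oem, rec.w_l, rec.c_l, rec.w_r, rec.c_r))
    return pd.DataFrame(records, columns=OEM_TABLE_COLUMNS)


def oem_summary(table: pd.DataFrame) -> dict:
    """Median/quartile/whisker summary over defined OEM records."""
    vals = table["oem"].to_numpy(dtype=float)
    defined = vals[~np.isnan(vals)]
    if len(defined) == 0:
        raise ValidationError("no defined OEM records")
    q1, med, q3 = np.percentile(defined, [25, 50, 75])
    return {"n_defined": int(len(defined)),
            "n_undefined": int(len(vals) - len(defined)),
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(defined.min()), "max": float(defined.max())}


def meta_origin_profile(cov: StrandedCoverage, origins: OriginTable,
                        window: int = 10000, bin_size: int = 500,
                        normalize_max: bool = False) -> MetaProfile:
    """Mean Watson fraction per offset bin around origin midpoints.

    Origins are averaged with equal weight; an origin with zero counts in an
    offset bin is omitted from that bin's mean.  With ``normalize_max`` the
    profile is divided by its maximum (as in meta-origin plots "normalized
    to the maximum").
    """
    if len(origins) == 0:
        raise ValidationError("no origins")
    if window % bin_size:
        raise ValidationError("bin_size must divide window")
    n_off = 2 * (window // bin_size)
    edges = np.arange(-window, window + bin_size, bin_size)
    sums = np.zeros(n_off)
    counts = np.zeros(n_off, dtype=int)
    for row in origins.df.itertuples(index=False):
        chrom = row.chromosome
        m = int(row.midpoint)
        length = cov.genome.length(chrom)
        for k in range(n_off):
            lo, hi = m + edges[k], m + edges[k + 1]
            if lo < 0 or hi > length:
                continue
            w, c = cov.counts_in(chrom, int(lo), int(hi))
            if w + c == 0:
                continue
            sums[k] += w / (w + c)
            counts[k] += 1
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    profile = MetaProfile(offsets=(edges[:-1] + edges[1:]) // 2, values=values,
                          n_origins=counts)
    return profile.normalize_max() if normalize_max else profile


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    groups: dict[str, np.ndarray]   # group name -> defined OEM values
    pair: tuple[str, str]
    t: float
    df: float
    p: float
    n_excluded: int                 # origins lacking annotation or OEM


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, welch: bool):
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def split_and_compare(table: pd.DataFrame, origins: OriginTable, scheme: str,
                      theta: float = 18.0,
                      pair: tuple[str, str] | None = None,
                      welch: bool = True) -> ComparisonResult:
    """Partition origins, collect their OEMs and run an unpaired t-test.

    Schemes
    -------
    ``timing_median``
        early (T_rep below the median) vs late; pair defaults to
        ("early", "late").
    ``fkh``
        Forkhead classes activated / repressed / independent; ``pair`` picks
        the two classes to test (default activated vs repressed).
    ``earliest_k``
        earliest origins with T_rep < ``theta`` vs the remainder (an
        earliest-subset split in the style of earliest-22-of-283 analyses
        uses theta = 18 min).

    Welch's unequal-variance t-test is the default; ``welch=False`` gives the
    pooled-variance test.
    """
    merged = origins.df.merge(table[["name", "oem"]], on="name", how="left")
    n_excluded = 0

    if scheme == "timing_median":
        t_rep = merged["t_rep"]
        annotated = merged[~t_rep.isna()]
        n_excluded += int(t_rep.isna().sum())
        med = annotated["t_rep"].median()
        groups_df = {"early": annotated[annotated["t_rep"] < med],
                     "late": annotated[annotated["t_rep"] >= med]}
        pair = pair or ("early", "late")
    elif scheme == "fkh":
        annotated = merged[merged["fkh_class"] != "unknown"]
        n_excluded += int((merged["fkh_class"] == "unknown").sum())
        groups_df = {cls: annotated[annotated["fkh_class"] == cls]
                     for cls in ("activated", "repressed", "independent")}
        pair = pair or ("activated", "repressed")
    elif scheme == "earliest_k":
        t_rep = merged["t_rep"]
        annotated = merged[~t_rep.isna()]
        n_excluded += int(t_rep.isna().sum())
        groups_df = {"earliest": annotated[annotated["t_rep"] < theta],
                     "rest": annotated[annotated["t_rep"] >= theta]}
        pair = pair or ("earliest", "rest")
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")

    groups: dict[str, np.ndarray] = {}
    for gname, gdf in groups_df.items():
        vals = gdf["oem"].to_numpy(dtype=float)
        n_excluded += int(np.isnan(vals).sum())
        groups[gname] = vals[~np.isnan(vals)]
    for gname in pair:
        if gname not in groups:
            raise ValidationError(f"scheme {scheme!r} has no group {gname!r}")
        if len(groups[gname]) < 2:
            raise ValidationError(f"group {gname!r} has < 2 defined OEMs")
    t, df, p = _welch_or_pooled(groups[pair[0]], groups[pair[1]], welch)
    return ComparisonResult(groups, pair, t, df, p, n_excluded)


def replicate_correlation(table_a: pd.DataFrame,
                          table_b: pd.DataFrame) -> tuple[float, pd.DataFrame, int]:
    """Pearson correlation of OEMs between two replicate tables.

    Only origins with a defined OEM in both tables contribute.  Returns
    ``(r, paired scatter DataFrame, n_dropped)``.
    """
    merged = table_a[["name", "oem"]].merge(table_b[["name", "oem"]],
                                            on="name", suffixes=("_a", "_b"))
    if len(merged) != len(table_a) or len(merged) != len(table_b):
        raise ValidationError("replicate tables cover different origin sets")
    joint = merged.dropna()
    n_dropped = len(merged) - len(joint)
    if len(joint) < 3:
        raise ValidationError("fewer than 3 jointly defined origins")
    r = float(stats.pearsonr(joint["oem_a"], joint["oem_b"]).statistic)
    return r, joint.reset_index(drop=True), n_dropped


def average_oem_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average replicate OEM tables per origin (OEM averaging, the default
    replicate-combination mode; pooled-fragment mode is obtained by pooling
    fragments upstream instead)."""
    if not tables:
        raise ValidationError("no tables")
    out = tables[0].copy()
    oems = np.stack([t["oem"].to_numpy(dtype=float) for t in tables])
    counts = {c: np.stack([t[c].to_numpy(dtype=float) for t in tables]).sum(0)
              for c in ("w_l", "c_l", "w_r", "c_r")}
    with np.errstate(invalid="ignore"):
        out["oem"] = np.nanmean(oems, axis=0)
    for c, v in counts.items():
        out[c] = v
    return out
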