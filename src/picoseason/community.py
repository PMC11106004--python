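"""Filtering, normalization, aggregation and persistence categorization of
ASV count tables.

Tables are long-format pandas DataFrames:

* count table — columns ``sample_id, asv_id, count`` (nonnegative ints);
* taxonomy — one row per ASV: ``asv_id, marker, category, group, genus,
  species`` where ``category`` is one of ``plastid``, ``cyanobacteria``,
  ``heterotroph``, ``other`` (or ``eukaryote`` for an 18S table) and the
  ``group`` of every prasinophyte lineage starts with ``"prasinophyte"``
  (the prasinodermophytes, "Class VI", are counted among them);
* sample metadata — ``sample_id, profile_id, depth_m, timestamp`` plus the
  hydrography-derived ``period`` and ``zone`` columns.

Samples are retained when their rarefaction curve has saturated: the
endpoint slope of the analytical rarefaction curve equals the singleton
fraction f1/N, and saturation means slope below 0.1.  Relative abundances
can be taken over the whole library, over plastid amplicons only, or over
prasinophyte amplicons only.  ASVs are categorized from ephemeral (one
stability period) to persistent (all four) after excluding singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CommunityParams",
    "PersistenceRecord",
    "PRASINOPHYTE_GROUP_PREFIX",
    "is_prasinophyte",
    "rarefaction_slope",
    "filter_samples",
    "normalize",
    "summarize",
    "quadrant_assign",
    "classify_persistence",
    "apply_detection_limit",
]

PRASINOPHYTE_GROUP_PREFIX = "prasinophyte"

PERIODS = ("DM", "ST", "SS", "AT")


@dataclass(frozen=True)
class CommunityParams:
    """Filtering and categorization thresholds.

    slope_threshold — rarefaction endpoint slope below which a sample
    counts as saturated; min_plastid_reads — plastid amplicons needed for
    plastid-denominator analyses (samples under it are flagged, not
    dropped); quantile — percentile used for the chlorophyll/prasinophyte
    quadrant thresholds; max_depth_m — persistence and quadrant analyses
    use samples at or above this depth; analysis_years — calendar years
    entering the persistence categorization; detection limits zero out
    nutrient values below the instrument floor (µmol kg^-1).
    """

    slope_threshold: float = 0.1
    min_plastid_reads: int = 50
    quantile: float = 0.75
    max_depth_m: float = 140.0
    surface_max_depth_m: float = 5.0
    analysis_years: tuple[int, ...] = (2017, 2018, 2019)
    lod_nitrate: float = 0.05
    lod_phosphate: float = 0.03
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        for name in ("slope_threshold", "min_plastid_reads", "max_depth_m",
                     "surface_max_depth_m", "lod_nitrate", "lod_phosphate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PersistenceRecord:
    """Per-ASV stability-period occupancy and category.

    ephemeral = detected in exactly one period; persistent = in all four;
    intermediate = two or three.  Singletons are excluded upstream.
    """

    asv_id: str
    periods: frozenset
    n_years: int
    years: frozenset = field(default_factory=frozenset)

    @property
    def n_periods_detected(self) -> int:
        return len(self.periods)

    @property
    def category(self) -> str:
        if self.n_periods_detected == 1:
            return "ephemeral"
        if self.n_periods_detected == 4:
            return "persistent"
        return "intermediate"


def is_prasinophyte(group) -> bool:
    return isinstance(group, str) and group.startswith(PRASINOPHYTE_GROUP_PREFIX)


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample_id", "asv_id", "count"} - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    return table


def rarefaction_slope(counts: Iterable[int]) -> float:
    """Endpoint slope of the analytical rarefaction curve for one sample.

    The expected richness after drawing n of the N reads without
    replacement is E[S(n)] = sum_i [1 - C(N - N_i, n) / C(N, n)]; the
    endpoint slope E[S(N)] - E[S(N-1)] collapses to f1 / N, the singleton
    fraction, because only ASVs with a single read can vanish when one read
    is removed.  Values near zero mean the curve has saturated.
    """
    c = np.asarray(list(counts), dtype=float)
    c = c[c > 0]
    n_total = c.sum()
    if n_total < 2:
        raise ValueError("need at least 2 reads to define a rarefaction slope")
    f1 = int((c == 1).sum())
    return f1 / float(n_total)


def filter_samples(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    params: CommunityParams = CommunityParams(),
) -> pd.DataFrame:
    """Saturation filter plus low-plastid flagging.

    Returns one row per sample: ``sample_id, total_reads, slope,
    plastid_reads, kept, low_plastid, reason``.  A sample is kept when its
    all-ASV rarefaction slope is below ``slope_threshold``.  Samples with
    fewer than ``min_plastid_reads`` plastid amplicons are flagged (not
    dropped) so plastid-denominator analyses can exclude them while the
    samples still contribute to whole-library views.
    """
    _validate_counts(table)
    if table.empty:
        return pd.DataFrame(
            columns=["sample_id", "total_reads", "slope", "plastid_reads",
                     "kept", "low_plastid", "reason"]
        )
    tax = taxonomy.set_index("asv_id") if "asv_id" in taxonomy.columns else taxonomy
    plastid_ids = set(tax.index[tax["category"] == "plastid"])
    rows = []
    for sample_id, grp in table.groupby("sample_id", sort=True):
        counts = grp["count"].to_numpy()
        total = int(counts.sum())
        slope = rarefaction_slope(counts) if total >= 2 else 1.0
        plastid = int(grp.loc[grp["asv_id"].isin(plastid_ids), "count"].sum())
        kept = slope < params.slope_threshold
        low = plastid < params.min_plastid_reads
        reason = "" if kept else f"rarefaction slope {slope:.4g} >= {params.slope_threshold}"
        rows.append(
            {"sample_id": sample_id, "total_reads": total, "slope": slope,
             "plastid_reads": plastid, "kept": kept, "low_plastid": low,
             "reason": reason}
        )
    return pd.DataFrame(rows)


def _denominator_mask(tax: pd.DataFrame, denominator: str) -> pd.Index:
    if denominator == "total":
        return tax.index
    if denominator == "plastid":
        return tax.index[tax["category"] == "plastid"]
    if denominator == "prasinophyte":
        return tax.index[tax["group"].map(is_prasinophyte)]
    raise ValueError(f"unknown denominator {denominator!r}")


def normalize(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    denominator: str = "total",
    unit: str = "asv",
) -> pd.DataFrame:
    """Per-sample relative abundances over a chosen denominator.

    ``denominator`` is ``total`` (whole library), ``plastid`` (plastid
    amplicons only) or ``prasinophyte`` (prasinophyte amplicons, Class VI
    included).  ``unit`` is ``asv`` or ``group``.  Output columns:
    ``sample_id, unit, value``.  Samples whose denominator reads are zero
    are omitted entirely (their fractions are absent, not zero).
    """
    _validate_counts(table)
    tax = taxonomy.set_index("asv_id") if "asv_id" in taxonomy.columns else taxonomy
    if unit not in ("asv", "group"):
        raise ValueError(f"unknown unit {unit!r}")
    denom_ids = set(_denominator_mask(tax, denominator))
    sub = table[table["asv_id"].isin(denom_ids)].copy()
    if sub.empty:
        return pd.DataFrame(columns=["sample_id", "unit", "value"])
    denom = sub.groupby("sample_id")["count"].sum()
    denom = denom[denom > 0]
    sub = sub[sub["sample_id"].isin(denom.index)]
    if unit == "group":
        sub["unit"] = sub["asv_id"].map(tax["group"])
    else:
        sub["unit"] = sub["asv_id"]
    agg = sub.groupby(["sample_id", "unit"], as_index=False)["count"].sum()
    agg["value"] = agg["count"] / agg["sample_id"].map(denom)
    return agg[["sample_id", "unit", "value"]]


def summarize(
    relabund: pd.DataFrame,
    meta: pd.DataFrame,
    units: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Mean +/- sample standard deviation of fractions per (period, zone).

    ``meta`` must carry ``sample_id, period, zone``.  Samples present in
    the metadata but missing a given unit contribute a fraction of 0 (the
    unit was not observed although the denominator was); samples absent
    from ``relabund`` altogether (zero denominator) do not contribute.
    Groups with no samples are omitted; sd is absent for n = 1.
    """
    for col in ("sample_id", "period", "zone"):
        if col not in meta.columns:
            raise ValueError(f"meta missing column {col!r}")
    samples_with_denom = relabund["sample_id"].unique()
    m = meta[meta["sample_id"].isin(samples_with_denom)]
    if units is None:
        units = sorted(relabund["unit"].unique())
    rows = []
    wide = relabund.pivot_table(index="sample_id", columns="unit",
                                values="value", fill_value=0.0)
    for (period, zone), grp in m.groupby(["period", "zone"], sort=True):
        ids = [s for s in grp["sample_id"] if s in wide.index]
        if not ids:
            continue
        block = wide.reindex(ids).fillna(0.0)
        for u in units:
            vals = block[u].to_numpy() if u in block.columns else np.zeros(len(ids))
            rows.append({
                "period": period, "zone": zone, "unit": u,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": len(vals),
            })
    return pd.DataFrame(rows)


def quadrant_assign(
    chla: pd.Series,
    pras_fraction: pd.Series,
    depth_m: pd.Series,
    params: CommunityParams = CommunityParams(),
) -> tuple[pd.DataFrame, float, float]:
    """Quadrant analysis of chlorophyll a against prasinophyte fraction.

    All three inputs are indexed by sample id.  The eligible set is
    restricted to depth <= ``max_depth_m`` with both measurements present.
    Thresholds are the 75th percentiles (linear interpolation between order
    statistics) of each variable over the eligible set.  Quadrants:
    Q1 both <= threshold; Q2 Chl a above only; Q3 prasinophyte fraction
    above only; Q4 both strictly above.  Ties fall in the "<=" half.

    Returns (per-sample frame with columns chla, pras_fraction, depth_m,
    quadrant; chla threshold; prasinophyte threshold).
    """
    df = pd.DataFrame({
        "chla": chla, "pras_fraction": pras_fraction, "depth_m": depth_m,
    })
    eligible = df[(df["depth_m"] <= params.max_depth_m)
                  & df["chla"].notna() & df["pras_fraction"].notna()].copy()
    if len(eligible) < 4:
        raise ValueError("need at least 4 eligible samples for quadrant analysis")
    q = params.quantile
    chla_thr = float(np.quantile(eligible["chla"].to_numpy(), q, method="linear"))
    pras_thr = float(np.quantile(eligible["pras_fraction"].to_numpy(), q, method="linear"))
    hi_c = eligible["chla"] > chla_thr
    hi_p = eligible["pras_fraction"] > pras_thr
    eligible["quadrant"] = np.select(
        [hi_c & hi_p, hi_c & ~hi_p, ~hi_c & hi_p], ["Q4", "Q2", "Q3"], default="Q1"
    )
    return eligible, chla_thr, pras_thr


def classify_persistence(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    params: CommunityParams = CommunityParams(),
    asv_ids: Optional[Iterable[str]] = None,
) -> tuple[list[PersistenceRecord], dict]:
    """Categorize ASVs from ephemeral to persistent.

    Detection is any positive count (an optional relative-abundance floor
    ``params.detection_floor`` of the sample library is available, default
    0).  The data is restricted to samples at or above ``max_depth_m``
    whose timestamp falls in ``analysis_years``.  ASVs whose total read
    count across the restricted data is exactly 1 (singletons) are
    excluded before categorization.

    Returns the records plus a summary dict with per-period ASV sets
    (``period_sets``), per-year sets of ASVs detected only in the
    stratified summer (``ss_only_by_year``) and all per-year sets
    (``year_sets``), the inputs for Venn/UpSet style overlap counts.
    """
    _validate_counts(table)
    m = meta.copy()
    m["timestamp"] = pd.to_datetime(m["timestamp"])
    m["year"] = m["timestamp"].dt.year
    m = m[(m["depth_m"] <= params.max_depth_m)
          & m["year"].isin(params.analysis_years)]
    sub = table.merge(m[["sample_id", "period", "year"]], on="sample_id")
    sub = sub[sub["count"] > 0]
    if asv_ids is not None:
        sub = sub[sub["asv_id"].isin(set(asv_ids))]
    if params.detection_floor > 0:
        totals = table.groupby("sample_id")["count"].sum()
        frac = sub["count"] / sub["sample_id"].map(totals)
        sub = sub[frac >= params.detection_floor]
    if sub.empty:
        return [], {"period_sets": {p: set() for p in PERIODS},
                    "ss_only_by_year": {}, "year_sets": {}}

    totals = sub.groupby("asv_id")["count"].sum()
    singletons = set(totals.index[totals == 1])
    sub = sub[~sub["asv_id"].isin(singletons)]

    records = []
    for asv_id, grp in sub.groupby("asv_id", sort=True):
        periods = frozenset(grp["period"].unique())
        years = frozenset(int(y) for y in grp["year"].unique())
        records.append(PersistenceRecord(
            asv_id=asv_id, periods=periods, n_years=len(years), years=years,
        ))
    period_sets = {
        p: set(sub.loc[sub["period"] == p, "asv_id"].unique()) for p in PERIODS
    }
    year_sets = {
        int(y): set(sub.loc[sub["year"] == y, "asv_id"].unique())
        for y in sorted(sub["year"].unique())
    }
    ss_only = {r.asv_id for r in records if r.periods == frozenset({"SS"})}
    ss_only_by_year = {y: s & ss_only for y, s in year_sets.items()}
    return records, {"period_sets": period_sets,
                     "ss_only_by_year": ss_only_by_year,
                     "year_sets": year_sets}


def apply_detection_limit(values, lod: float) -> np.ndarray:
    """Zero out measurements below the instrument detection limit.

    Values below ``lod`` are reported as 0; values at or above it pass
    through.  Negative concentrations are a data error.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if np.any(finite < 0):
        raise ValueError("negative concentrations are invalid")
    out = v.copy()
    out[np.isfinite(out) & (out < lod)] = 0.0
    return out
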