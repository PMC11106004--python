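"""Glue between the hydrography stage and the community stage.

The community summaries need every sample labelled with a stability period
(from the timeline of its profile) and a vertical zone (from its depth and
the profile's features).  This module rebuilds per-profile features from
the hydrography output tables, annotates the sample metadata, and bundles
the full community analysis into one call used by the CLI and by
reproduction scripts.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from picoseason.community import (
    CommunityParams,
    apply_detection_limit,
    classify_persistence,
    filter_samples,
    normalize,
    quadrant_assign,
    summarize,
    is_prasinophyte,
)
from picoseason.hydro import DCMRegion, ProfileFeatures, assign_zone

__all__ = ["features_from_frame", "annotate_meta", "run_community_analysis"]


def features_from_frame(features_df: pd.DataFrame) -> dict[str, ProfileFeatures]:
    """Rebuild ProfileFeatures objects from a features table (the
    hydrography stage's output or the generator's truth table)."""
    out = {}
    for _, r in features_df.iterrows():
        dcm = None
        upper = r.get("dcm_upper_m")
        if upper is not None and np.isfinite(upper):
            dcm = DCMRegion(
                upper_m=float(upper),
                max_m=float(r.get("dcm_max_m", r.get("dcm_center_m", upper))),
                lower_m=float(r["dcm_lower_m"]),
                max_fluor=float(r.get("dcm_max_fluor", 1.0) or 1.0),
                is_dcm=bool(r.get("dcm_is_dcm", True)),
            )
        def _f(key):
            v = r.get(key)
            return float(v) if v is not None and np.isfinite(v) else None

        out[r["profile_id"]] = ProfileFeatures(
            profile_id=r["profile_id"],
            timestamp=np.datetime64(pd.Timestamp(r["timestamp"])),
            mld_m=float(r["mld_m"]),
            mld_bottom_limited=bool(r.get("mld_bottom_limited", False)),
            euphotic_depth_m=_f("euphotic_depth_m"),
            light1pct_depth_m=_f("light1pct_depth_m"),
            dcm=dcm,
        )
    return out


def annotate_meta(
    meta: pd.DataFrame,
    features_df: pd.DataFrame,
    timeline_df: pd.DataFrame,
    params: CommunityParams = CommunityParams(),
) -> pd.DataFrame:
    """Attach period, zone and year to every sample.

    ``timeline_df`` needs profile_id and label; ``features_df`` the
    per-profile feature columns.  Samples from profiles without a label or
    features are dropped with a warning column rather than an error.
    """
    feats = features_from_frame(features_df)
    label_of = dict(zip(timeline_df["profile_id"], timeline_df["label"]))
    m = meta.copy()
    m["timestamp"] = pd.to_datetime(m["timestamp"])
    m["year"] = m["timestamp"].dt.year
    periods, zones = [], []
    for _, r in m.iterrows():
        pid = r["profile_id"]
        label = label_of.get(pid)
        f = feats.get(pid)
        if label is None or f is None:
            periods.append(None)
            zones.append(None)
            continue
        periods.append(label)
        zones.append(assign_zone(r["depth_m"], f, label,
                                 surface_max_depth_m=params.surface_max_depth_m))
    m["period"] = periods
    m["zone"] = zones
    return m[m["period"].notna()].reset_index(drop=True)


def run_community_analysis(
    table16: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    bottle: Optional[pd.DataFrame] = None,
    params: CommunityParams = CommunityParams(),
) -> dict:
    """Full community stage on annotated metadata.

    Returns a dict with the filter report, group-level relative abundances
    over the plastid denominator, the prasinophyte-of-plastid per-sample
    series, period-by-zone summaries, the quadrant table and thresholds
    (when bottle chlorophyll is available), the persistence records, and
    period/year set summaries.
    """
    report = filter_samples(table16, taxonomy, params)
    kept = set(report.loc[report["kept"], "sample_id"])
    ok_plastid = set(report.loc[report["kept"] & ~report["low_plastid"], "sample_id"])
    t = table16[table16["sample_id"].isin(kept)]
    meta = meta[meta["sample_id"].isin(kept)].reset_index(drop=True)

    rel_group = normalize(t[t["sample_id"].isin(ok_plastid)], taxonomy,
                          denominator="plastid", unit="group")
    tax = taxonomy.set_index("asv_id")
    pras = (
        rel_group[rel_group["unit"].map(is_prasinophyte)]
        .groupby("sample_id")["value"].sum()
    )
    # samples with plastid reads but zero prasinophytes still count as 0
    pras = pras.reindex(sorted(rel_group["sample_id"].unique()), fill_value=0.0)

    summary = summarize(rel_group, meta)

    quadrant = None
    thresholds = None
    if bottle is not None and "chla_ug_kg" in bottle.columns:
        b = bottle.set_index("sample_id")
        common = [s for s in pras.index if s in b.index]
        depth = meta.set_index("sample_id")["depth_m"]
        common = [s for s in common if s in depth.index]
        if len(common) >= 4:
            q, chla_thr, pras_thr = quadrant_assign(
                b.loc[common, "chla_ug_kg"], pras.loc[common],
                depth.loc[common], params,
            )
            quadrant, thresholds = q, (chla_thr, pras_thr)

    pras_ids = tax.index[tax["group"].map(is_prasinophyte)
                         & (tax["marker"] == "plastid16S")]
    records, sets = classify_persistence(
        t[t["asv_id"].isin(set(pras_ids))], meta, params
    )
    persistence = pd.DataFrame([
        {"asv_id": r.asv_id, "n_periods_detected": r.n_periods_detected,
         "periods": ",".join(sorted(r.periods)), "n_years": r.n_years,
         "category": r.category}
        for r in records
    ])
    nutrients = None
    if bottle is not None and "nitrate_nitrite_umol_kg" in bottle.columns:
        nutrients = bottle.copy()
        nutrients["nitrate_nitrite_umol_kg"] = apply_detection_limit(
            nutrients["nitrate_nitrite_umol_kg"], params.lod_nitrate)
        nutrients["phosphate_umol_kg"] = apply_detection_limit(
            nutrients["phosphate_umol_kg"], params.lod_phosphate)
    return {
        "filter_report": report,
        "rel_group_plastid": rel_group,
        "pras_fraction": pras,
        "summary": summary,
        "quadrant": quadrant,
        "quadrant_thresholds": thresholds,
        "persistence": persistence,
        "persistence_records": records,
        "sets": sets,
        "nutrients": nutrients,
        "meta": meta,
    }
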