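"""Readers and writers for the pipeline's plain-text formats.

CTD casts arrive as a long CSV (one row per profile-depth); ASV counts,
taxonomy and sample metadata as long-format TSVs; bottle chemistry as CSV.
All parsing goes through pandas.
"""

from __future__ import annotations

from dataclasses import fields
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from picoseason.community import CommunityParams
from picoseason.crossmarker import LinkParams
from picoseason.hydro import CTDProfile, HydroParams, ProfileFeatures, StabilityTimeline

CTD_COLUMNS = ["profile_id", "timestamp", "depth_m", "temp_C", "salinity",
               "sigma_t", "fluor_rfu", "par"]


def read_ctd_csv(path) -> list[CTDProfile]:
    """Parse a long-format CTD CSV into per-cast profiles, sorted by time.

    ``par`` and ``fluor_rfu`` columns may be missing or hold NaNs; the
    corresponding arrays are then omitted from the profile.
    """
    df = pd.read_csv(path)
    missing = {"profile_id", "timestamp", "depth_m", "sigma_t"} - set(df.columns)
    if missing:
        raise ValueError(f"CTD CSV missing columns {sorted(missing)}")
    profiles = []
    for pid, grp in df.groupby("profile_id", sort=False):
        grp = grp.sort_values("depth_m")
        ts = pd.Timestamp(grp["timestamp"].iloc[0])

        def col(name):
            if name not in grp.columns:
                return None
            arr = grp[name].to_numpy(dtype=float)
            return None if np.isnan(arr).all() else arr

        profiles.append(CTDProfile(
            profile_id=str(pid),
            timestamp=np.datetime64(ts),
            depth_m=grp["depth_m"].to_numpy(dtype=float),
            temp_C=col("temp_C"),
            salinity=col("salinity"),
            sigma_t=grp["sigma_t"].to_numpy(dtype=float),
            fluor_rfu=col("fluor_rfu"),
            par=col("par"),
        ))
    profiles.sort(key=lambda p: p.timestamp)
    return profiles


def features_frame(features: list[ProfileFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append({
            "profile_id": f.profile_id,
            "timestamp": pd.Timestamp(f.timestamp).isoformat(),
            "mld_m": f.mld_m,
            "mld_bottom_limited": f.mld_bottom_limited,
            "euphotic_depth_m": f.euphotic_depth_m,
            "light1pct_depth_m": f.light1pct_depth_m,
            "dcm_upper_m": f.dcm.upper_m if f.dcm else None,
            "dcm_max_m": f.dcm.max_m if f.dcm else None,
            "dcm_lower_m": f.dcm.lower_m if f.dcm else None,
            "dcm_max_fluor": f.dcm.max_fluor if f.dcm else None,
            "dcm_is_dcm": f.dcm.is_dcm if f.dcm else False,
        })
    return pd.DataFrame(rows)


def timeline_frame(features: list[ProfileFeatures], timeline: StabilityTimeline) -> pd.DataFrame:
    rows = []
    for f, (ts, label, trigger) in zip(features, timeline.entries):
        rows.append({
            "profile_id": f.profile_id,
            "timestamp": pd.Timestamp(ts).isoformat(),
            "label": label,
            "trigger": trigger,
        })
    return pd.DataFrame(rows)


def read_asv_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "asv_id", "count"}
    if need - set(df.columns):
        raise ValueError(f"ASV TSV missing columns {sorted(need - set(df.columns))}")
    df["count"] = df["count"].astype(int)
    return df


def read_taxonomy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").fillna("")
    need = {"asv_id", "marker", "category", "group", "genus", "species"}
    if need - set(df.columns):
        raise ValueError(f"taxonomy TSV missing columns {sorted(need - set(df.columns))}")
    return df


def read_meta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "profile_id", "depth_m", "timestamp"}
    if need - set(df.columns):
        raise ValueError(f"metadata TSV missing columns {sorted(need - set(df.columns))}")
    return df


def read_bottle_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pairs_tsv(path) -> list[tuple[str, str, tuple]]:
    """Pairs file: asv16_id, species18_label, comma-separated 18S asv ids."""
    df = pd.read_csv(path, sep="\t")
    need = {"asv16_id", "species18_label", "asv18_ids"}
    if need - set(df.columns):
        raise ValueError(f"pairs TSV missing columns {sorted(need - set(df.columns))}")
    return [
        (r["asv16_id"], r["species18_label"],
         tuple(s.strip() for s in str(r["asv18_ids"]).split(",") if s.strip()))
        for _, r in df.iterrows()
    ]


def _params_from_yaml(cls, path):
    if path is None:
        return cls()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key, val in list(raw.items()):
        if isinstance(val, list):
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return cls(**raw)


def load_hydro_params(path: Optional[str] = None) -> HydroParams:
    return _params_from_yaml(HydroParams, path)


def load_community_params(path: Optional[str] = None) -> CommunityParams:
    return _params_from_yaml(CommunityParams, path)


def load_link_params(path: Optional[str] = None) -> LinkParams:
    return _params_from_yaml(LinkParams, path)
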