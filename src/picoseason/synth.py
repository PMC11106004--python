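"""Synthetic annual subtropical time series with planted ground truth.

The generator emulates a Bermuda-like open-ocean site: winter deep
convective mixing with the mixed layer exceeding the euphotic zone depth,
spring shoaling, a stratified summer with a deep chlorophyll maximum near
80-120 m, and an autumn transition as the deepening mixed layer entrains
the DCM.  On top of the physics it plants a paired 16S/18S amplicon
community with known composition templates per (stability period, vertical
zone), persistent and summer-ephemeral ASVs, and cross-marker species pairs
sharing a latent abundance, so every downstream stage can be scored against
ground truth.

Physics is generated directly on sigma-t (the analysis never needs an
equation of state): profiles are mixed-layer-uniform above the planted MLD
with a linear pycnocline below, built so the density-offset criterion
crosses exactly at the planted depth.  PAR decays exponentially;
fluorescence is a Gaussian DCM when stratified and an elevated mixed-layer
signal during deep mixing.  Community counts are Dirichlet-multinomial
around (period, zone) templates with lognormal library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from picoseason.hydro import (
    CTDProfile,
    HydroParams,
    ProfileFeatures,
    assign_zone,
    classify_stability_periods,
    compute_profile_features,
)

__all__ = [
    "PhysicsConfig",
    "CommunityConfig",
    "GroundTruth",
    "simulate_physics",
    "simulate_community",
    "simulate_zone_samples",
    "simulate_linked_pair",
    "DEFAULT_PAIRS",
    "build_taxonomy",
]


@dataclass(frozen=True)
class PhysicsConfig:
    """Forcing and noise for the physical annual cycle.

    ``mld_month_anchors`` are planted mixed layer depths (m) at the first
    day of each month; the daily MLD curve interpolates them with a
    monotone cubic.  Winter anchors exceed the euphotic depth implied by
    ``k_par`` (deep mixing); summer anchors sit above the DCM region.
    Noise terms: additive sigma-t noise (kg m^-3), multiplicative
    fluorescence and PAR noise (lognormal sigma), and a per-profile MLD
    jitter (m) around the seasonal curve.
    """

    start_date: str = "2017-01-01"
    end_date: str = "2017-12-31"
    profiles_per_month: int = 1
    # optional dense "process cruise": extra sampling days keyed by month
    process_cruise: tuple = ()  # e.g. ((3, (8, 12, 20, 24)),)
    mld_month_anchors: tuple = (250, 280, 230, 95, 60, 35, 22, 20, 30, 90, 115, 170)
    surface_sigma_winter: float = 26.2
    surface_sigma_summer: float = 24.8
    pycnocline_grad: float = 0.0125  # kg m^-3 per m
    sst_winter_C: float = 19.8
    sst_summer_C: float = 27.3
    dcm_center_m: float = 100.0
    dcm_width_m: float = 20.0
    dcm_center_jitter_m: float = 3.0
    fluor_background: float = 0.15
    fluor_dcm_peak: float = 0.95
    fluor_dm_ml: float = 0.65
    surface_par: float = 1500.0
    k_par: float = 0.046  # m^-1
    ctd_dz_m: float = 2.0
    min_depth_m: float = 1.0
    max_depth_m: float = 300.0
    bottle_depths_m: tuple = (1, 20, 60, 80, 100, 120, 200, 300)
    sigma_noise: float = 0.002
    fluor_noise: float = 0.05
    par_noise: float = 0.02
    mld_jitter_m: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        zeu = self.min_depth_m + np.log(1.0 / 0.001) / self.k_par
        if max(self.mld_month_anchors) <= zeu:
            raise ValueError(
                "winter MLD anchors must exceed the euphotic depth for a DM period"
            )
        if not self.min_depth_m < self.dcm_center_m < self.max_depth_m:
            raise ValueError("dcm_center_m must lie inside the depth grid")
        if len(self.mld_month_anchors) != 12:
            raise ValueError("mld_month_anchors needs 12 monthly values")


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage.

    daily_labels — per-calendar-day stability-period label from the
    forcing; profiles — planted per-profile MLD/DCM/euphotic features and
    label; samples — per-bottle-sample (period, zone); asv_truth — planted
    persistence category per scored ASV; link_truth — planted cross-marker
    pair status.
    """

    daily_labels: pd.DataFrame
    profiles: pd.DataFrame
    samples: Optional[pd.DataFrame] = None
    asv_truth: Optional[pd.DataFrame] = None
    link_truth: Optional[pd.DataFrame] = None

    def to_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.daily_labels.to_csv(p / "daily_labels.csv", index=False)
        self.profiles.to_csv(p / "profiles.csv", index=False)
        for name in ("samples", "asv_truth", "link_truth"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(p / f"{name}.csv", index=False)


def _season_weight(day_of_year: int) -> float:
    """0 at midwinter (mid-Feb), 1 at midsummer (mid-Aug)."""
    return 0.5 - 0.5 * np.cos(2 * np.pi * (day_of_year - 46) / 365.25)


def _mld_curve(cfg: PhysicsConfig):
    start = pd.Timestamp(cfg.start_date) - pd.DateOffset(months=2)
    end = pd.Timestamp(cfg.end_date) + pd.DateOffset(months=2)
    knots = pd.date_range(start.normalize().replace(day=1), end, freq="MS")
    x = knots.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
    y = np.array([cfg.mld_month_anchors[k.month - 1] for k in knots], dtype=float)
    interp = PchipInterpolator(x, y)

    def curve(ts: pd.Timestamp) -> float:
        return float(interp(pd.Timestamp(ts).toordinal()))

    return curve


def _grid(cfg: PhysicsConfig) -> np.ndarray:
    return np.arange(cfg.min_depth_m, cfg.max_depth_m + 1e-9, cfg.ctd_dz_m)


def _sst(cfg: PhysicsConfig, ts: pd.Timestamp) -> float:
    w = _season_weight(ts.dayofyear)
    return cfg.sst_winter_C + (cfg.sst_summer_C - cfg.sst_winter_C) * w


def _fluor_clean(
    cfg: PhysicsConfig, z: np.ndarray, mld: float, center: float, stratified: bool
) -> np.ndarray:
    zeu = cfg.min_depth_m + np.log(1.0 / 0.001) / cfg.k_par
    background = cfg.fluor_background * np.exp(-np.maximum(0.0, z - zeu) / 40.0)
    if stratified:
        return background + cfg.fluor_dcm_peak * np.exp(
            -((z - center) ** 2) / (2.0 * cfg.dcm_width_m**2)
        )
    decay = np.exp(-np.maximum(0.0, z - mld) / 30.0)
    return background + cfg.fluor_dm_ml * decay


def _clean_profile(
    cfg: PhysicsConfig, profile_id: str, ts: pd.Timestamp, mld: float, center: float
) -> CTDProfile:
    z = _grid(cfg)
    w = _season_weight(ts.dayofyear)
    s0 = cfg.surface_sigma_winter + (cfg.surface_sigma_summer - cfg.surface_sigma_winter) * w
    # pycnocline placed so the +0.125 kg m^-3 crossing lands exactly at mld
    onset = mld - 0.125 / cfg.pycnocline_grad
    sigma = s0 + cfg.pycnocline_grad * np.maximum(0.0, z - onset)
    zeu = cfg.min_depth_m + np.log(1.0 / 0.001) / cfg.k_par
    stratified = mld < zeu
    fluor = _fluor_clean(cfg, z, mld, center, stratified)
    par = cfg.surface_par * np.exp(-cfg.k_par * z)
    sst = _sst(cfg, ts)
    temp = np.where(z <= mld, sst, sst - (sst - 18.0) * np.minimum(1.0, (z - mld) / 150.0))
    sal = np.full_like(z, 36.6)
    return CTDProfile(
        profile_id=profile_id,
        timestamp=np.datetime64(ts),
        depth_m=z,
        temp_C=temp,
        salinity=sal,
        sigma_t=sigma,
        fluor_rfu=fluor,
        par=par,
    )


def _add_noise(profile: CTDProfile, cfg: PhysicsConfig, rng: np.random.Generator) -> CTDProfile:
    n = len(profile.depth_m)
    sigma = profile.sigma_t + rng.normal(0.0, cfg.sigma_noise, n)
    fluor = profile.fluor_rfu * np.exp(rng.normal(0.0, cfg.fluor_noise, n))
    par = profile.par * np.exp(rng.normal(0.0, cfg.par_noise, n))
    return CTDProfile(
        profile_id=profile.profile_id,
        timestamp=profile.timestamp,
        depth_m=profile.depth_m.copy(),
        temp_C=profile.temp_C,
        salinity=profile.salinity,
        sigma_t=sigma,
        fluor_rfu=fluor,
        par=par,
    )


def _sample_days(cfg: PhysicsConfig) -> list[pd.Timestamp]:
    months = pd.date_range(
        pd.Timestamp(cfg.start_date).normalize().replace(day=1),
        cfg.end_date,
        freq="MS",
    )
    cruise = dict(cfg.process_cruise)
    days: list[pd.Timestamp] = []
    for m in months:
        step = max(1, 28 // cfg.profiles_per_month)
        offsets = [1 + j * step for j in range(cfg.profiles_per_month)]
        offsets += list(cruise.get(m.month, ()))
        for d in sorted(set(offsets)):
            ts = m.replace(day=d)
            if pd.Timestamp(cfg.start_date) <= ts <= pd.Timestamp(cfg.end_date):
                days.append(ts)
    return days


@lru_cache(maxsize=8)
def _daily_truth(cfg: PhysicsConfig, hydro_params: HydroParams) -> pd.DataFrame:
    """Noise-free daily stability labels from the forcing curve.

    Deterministic given the configs (noise never enters the truth), so the
    result is cached across seeds.
    """
    curve = _mld_curve(cfg)
    days = pd.date_range(cfg.start_date, cfg.end_date, freq="D")
    daily_feats = []
    for ts in days:
        prof = _clean_profile(cfg, f"day{ts:%Y%m%d}", ts, curve(ts), cfg.dcm_center_m)
        daily_feats.append(compute_profile_features(prof, hydro_params))
    daily_tl = classify_stability_periods(daily_feats, hydro_params)
    return pd.DataFrame({"date": days, "label": daily_tl.labels})


def simulate_physics(
    cfg: PhysicsConfig = PhysicsConfig(),
    seed: Optional[int] = None,
    hydro_params: HydroParams = HydroParams(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a CTD table (long format, one row per profile-depth) and the
    planted ground truth.

    Daily truth labels come from running the stability state machine on
    noise-free daily profiles built from the forcing curve, so truth and
    analysis share one set of rules by construction.  Emitted profiles are
    sampled at the configured cadence with MLD jitter and sensor noise.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    curve = _mld_curve(cfg)
    daily_labels = _daily_truth(cfg, hydro_params).copy()
    label_of = dict(zip(daily_labels["date"], daily_labels["label"]))

    rows = []
    truth_rows = []
    for ts in _sample_days(cfg):
        pid = f"P{ts:%Y%m%d}"
        mld_p = float(np.clip(
            curve(ts) + rng.normal(0.0, cfg.mld_jitter_m),
            cfg.min_depth_m + 5.0, cfg.max_depth_m - 5.0,
        ))
        center_p = cfg.dcm_center_m + rng.normal(0.0, cfg.dcm_center_jitter_m)
        clean = _clean_profile(cfg, pid, ts, mld_p, center_p)
        feats = compute_profile_features(clean, hydro_params)
        noisy = _add_noise(clean, cfg, rng)
        for i in range(len(noisy.depth_m)):
            rows.append({
                "profile_id": pid,
                "timestamp": ts.isoformat(),
                "depth_m": noisy.depth_m[i],
                "temp_C": noisy.temp_C[i],
                "salinity": noisy.salinity[i],
                "sigma_t": noisy.sigma_t[i],
                "fluor_rfu": noisy.fluor_rfu[i],
                "par": noisy.par[i],
            })
        dcm = feats.dcm
        truth_rows.append({
            "profile_id": pid,
            "timestamp": ts,
            "label": label_of[ts],
            "mld_m": mld_p,
            "euphotic_depth_m": feats.euphotic_depth_m,
            "light1pct_depth_m": feats.light1pct_depth_m,
            "dcm_center_m": center_p,
            "dcm_upper_m": dcm.upper_m if dcm is not None and dcm.is_dcm else np.nan,
            "dcm_lower_m": dcm.lower_m if dcm is not None and dcm.is_dcm else np.nan,
            "dcm_is_dcm": bool(dcm.is_dcm) if dcm is not None else False,
        })
    truth = GroundTruth(
        daily_labels=daily_labels, profiles=pd.DataFrame(truth_rows)
    )
    return pd.DataFrame(rows), truth


# --------------------------------------------------------------------------
# Community generator
# --------------------------------------------------------------------------

# Micromonas species latent template (shared latent feeding both markers).
MICRO_SPECIES = ("m_commoda", "m_cand1", "m_cand2", "m_nullsp")
MICRO_SPECIES_TEMPLATE = (0.40, 0.30, 0.20, 0.10)
MICRO_ASV16 = {
    "m_commoda": "asv16_mcomA",
    "m_cand1": "asv16_81",
    "m_cand2": "asv16_1156",
    "m_nullsp": "asv16_mnull",
}
MICRO_ASV18 = {
    "m_commoda": (("asv18_mcomA_1", 0.6), ("asv18_mcomA_2", 0.4)),
    "m_cand1": (("asv18_c1_1", 0.7), ("asv18_c1_2", 0.3)),
    "m_cand2": (("asv18_c2_1", 1.0),),
    "m_nullsp": (("asv18_null_1", 1.0),),
}

# Default pairs for cross-marker linking; m_nullsp is planted unlinked
# (its 18S abundance follows an independent latent).
DEFAULT_PAIRS = tuple(
    (MICRO_ASV16[s], s, tuple(a for a, _ in MICRO_ASV18[s])) for s in MICRO_SPECIES
)
LINKED_TRUTH = {s: (s != "m_nullsp") for s in MICRO_SPECIES}


@dataclass(frozen=True)
class CommunityConfig:
    """Planted community structure and sequencing model.

    Library sizes are lognormal with the given mean/sd (reads per sample).
    ``pras_of_plastid`` maps (period, zone) to the planted prasinophyte
    fraction of plastid amplicons; unlisted combinations fall back to
    ``pras_default``.  ``dirichlet_conc_group`` controls between-sample
    compositional dispersion at the group level (small = paper-like large
    spreads); ``dirichlet_conc_asv`` the within-group ASV dispersion.
    Cross-marker species share a per-sample latent, scaled in the 18S
    marker by per-species copy-number multipliers with lognormal noise.
    """

    library_mean: float = 60279.0
    library_sd: float = 26939.0
    library18_mean: float = 30000.0
    library18_sd: float = 12000.0
    dirichlet_conc_group: float = 28.0
    dirichlet_conc_asv: float = 50.0
    dirichlet_conc_species: float = 2.0
    plastid_frac_euphotic: float = 0.12
    plastid_frac_deep: float = 0.04
    cyano_frac: float = 0.33
    pras_default: float = 0.15
    pras_of_plastid: tuple = (
        (("DM", "ml"), 0.463),
        (("DM", "surface"), 0.336),
        (("DM", "light1pct"), 0.463),
        (("ST", "surface"), 0.088),
        (("SS", "surface"), 0.036),
        (("AT", "surface"), 0.066),
        (("DM", "dcm"), 0.29),
        (("ST", "dcm"), 0.29),
        (("SS", "dcm"), 0.29),
        (("AT", "dcm"), 0.29),
        (("DM", "below_euphotic"), 0.08),
        (("ST", "below_euphotic"), 0.08),
        (("SS", "below_euphotic"), 0.08),
        (("AT", "below_euphotic"), 0.08),
    )
    # prasinophyte class split (of prasinophyte reads); the stratified
    # summer surface flips from Class II dominance to Class I / Class IX
    pras_class_split: tuple = (
        ("prasinophyte-CII", 0.55),
        ("prasinophyte-CI", 0.15),
        ("prasinophyte-CVI", 0.08),
        ("prasinophyte-CIX", 0.22),
    )
    pras_class_split_ss_surface: tuple = (
        ("prasinophyte-CII", 0.15),
        ("prasinophyte-CI", 0.40),
        ("prasinophyte-CVI", 0.05),
        ("prasinophyte-CIX", 0.40),
    )
    # non-prasinophyte plastid split (of non-prasinophyte plastid reads)
    nonpras_split: tuple = (
        ("prymnesiophyte", 0.346),
        ("stramenopile", 0.595),
        ("other-plastid", 0.059),
    )
    micromonas_of_cii: float = 0.35
    copy_multipliers: tuple = (1.0, 3.0, 0.6, 5.0)  # per MICRO_SPECIES
    noise18_sd: float = 0.2
    micro18_enrichment: float = 8.0
    chla_per_rfu: float = 0.2  # µg kg^-1 per RFU
    chla_noise: float = 0.15
    seed: int = 0

    def pras_target(self, period: str, zone: str) -> float:
        return dict(self.pras_of_plastid).get((period, zone), self.pras_default)


# 16S ASV roster: (asv_id, group, genus, species, role).  Within-group
# weights are defined in _within_weights; summer ephemerals carry weight
# only during SS.
ROSTER16 = (
    ("asv16_ostreoOII", "prasinophyte-CII", "Ostreococcus", "O_cladeOII", "persistent"),
    ("asv16_bathy", "prasinophyte-CII", "Bathycoccus", "B_calidus", "persistent"),
    ("asv16_cii_x", "prasinophyte-CII", "", "", "filler"),
    ("asv16_mcomA", "prasinophyte-CII", "Micromonas", "m_commoda", "species"),
    ("asv16_81", "prasinophyte-CII", "Micromonas", "m_cand1", "species"),
    ("asv16_1156", "prasinophyte-CII", "Micromonas", "m_cand2", "species"),
    ("asv16_mnull", "prasinophyte-CII", "Micromonas", "m_nullsp", "species"),
    ("asv16_ci_1", "prasinophyte-CI", "Pyramimonadales", "", "persistent"),
    ("asv16_ci_2", "prasinophyte-CI", "Pyramimonadales", "", "filler"),
    ("asv16_cvi_1", "prasinophyte-CVI", "Prasinoderma", "", "filler"),
    ("asv16_cix_1", "prasinophyte-CIX", "", "", "filler"),
    ("asv16_cix_2", "prasinophyte-CIX", "", "", "filler"),
    ("asv16_eph1", "prasinophyte-CIX", "", "", "ephemeral"),
    ("asv16_eph2", "prasinophyte-CIX", "", "", "ephemeral"),
    ("asv16_eph3", "prasinophyte-CI", "", "", "ephemeral"),
    ("asv16_eph4", "prasinophyte-CI", "", "", "ephemeral"),
    ("asv16_prym_1", "prymnesiophyte", "", "", "filler"),
    ("asv16_prym_2", "prymnesiophyte", "", "", "filler"),
    ("asv16_prym_3", "prymnesiophyte", "", "", "filler"),
    ("asv16_stram_1", "stramenopile", "", "", "filler"),
    ("asv16_stram_2", "stramenopile", "", "", "filler"),
    ("asv16_stram_3", "stramenopile", "", "", "filler"),
    ("asv16_other_1", "other-plastid", "", "", "filler"),
    ("asv16_other_2", "other-plastid", "", "", "filler"),
    ("asv16_cyano_1", "cyanobacteria-Prochlorococcus", "Prochlorococcus", "", "filler"),
    ("asv16_cyano_2", "cyanobacteria-Synechococcus", "Synechococcus", "", "filler"),
    ("asv16_cyano_3", "cyanobacteria-Prochlorococcus", "Prochlorococcus", "", "filler"),
    ("asv16_het_1", "heterotroph-bacteria", "", "", "filler"),
    ("asv16_het_2", "heterotroph-bacteria", "", "", "filler"),
    ("asv16_het_3", "heterotroph-bacteria", "", "", "filler"),
    ("asv16_het_4", "heterotroph-bacteria", "", "", "filler"),
    ("asv16_het_5", "heterotroph-bacteria", "", "", "filler"),
)

PERSISTENT_ASVS = tuple(a for a, *_rest in ROSTER16 if _rest[-1] == "persistent")
EPHEMERAL_ASVS = tuple(a for a, *_rest in ROSTER16 if _rest[-1] == "ephemeral")

_PLASTID_GROUPS = (
    "prasinophyte-CII", "prasinophyte-CI", "prasinophyte-CVI", "prasinophyte-CIX",
    "prymnesiophyte", "stramenopile", "other-plastid",
)


def build_taxonomy() -> pd.DataFrame:
    """Taxonomy covering both markers of the planted community."""
    rows = []
    for asv_id, group, genus, species, _role in ROSTER16:
        if group.startswith("cyanobacteria"):
            cat = "cyanobacteria"
        elif group.startswith("heterotroph"):
            cat = "heterotroph"
        else:
            cat = "plastid"
        rows.append({"asv_id": asv_id, "marker": "plastid16S", "category": cat,
                     "group": group, "genus": genus, "species": species})
    for sp in MICRO_SPECIES:
        for asv18, _w in MICRO_ASV18[sp]:
            rows.append({"asv_id": asv18, "marker": "18SV4", "category": "eukaryote",
                         "group": "prasinophyte-CII", "genus": "Micromonas",
                         "species": sp})
    for i in range(1, 4):
        rows.append({"asv_id": f"asv18_other_{i}", "marker": "18SV4",
                     "category": "eukaryote", "group": "other-eukaryote",
                     "genus": "", "species": ""})
    return pd.DataFrame(rows)


def _within_weights(group: str, period: str) -> dict[str, float]:
    """Base ASV weights within one group (summing to 1); summer ephemerals
    only carry weight during SS."""
    if group == "prasinophyte-CII":
        # Micromonas mass (0.35) is distributed over its species latent later
        return {"asv16_ostreoOII": 0.30, "asv16_bathy": 0.15, "asv16_cii_x": 0.20,
                "__micromonas__": 0.35}
    if group == "prasinophyte-CI":
        if period == "SS":
            return {"asv16_ci_1": 0.45, "asv16_ci_2": 0.25,
                    "asv16_eph3": 0.15, "asv16_eph4": 0.15}
        return {"asv16_ci_1": 0.6, "asv16_ci_2": 0.4}
    if group == "prasinophyte-CVI":
        return {"asv16_cvi_1": 1.0}
    if group == "prasinophyte-CIX":
        if period == "SS":
            return {"asv16_cix_1": 0.30, "asv16_cix_2": 0.20,
                    "asv16_eph1": 0.25, "asv16_eph2": 0.25}
        return {"asv16_cix_1": 0.6, "asv16_cix_2": 0.4}
    if group == "prymnesiophyte":
        return {"asv16_prym_1": 0.5, "asv16_prym_2": 0.3, "asv16_prym_3": 0.2}
    if group == "stramenopile":
        return {"asv16_stram_1": 0.5, "asv16_stram_2": 0.3, "asv16_stram_3": 0.2}
    if group == "other-plastid":
        return {"asv16_other_1": 0.6, "asv16_other_2": 0.4}
    raise KeyError(group)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _group_template(cfg: CommunityConfig, period: str, zone: str) -> dict[str, float]:
    plastid = (cfg.plastid_frac_deep if zone == "below_euphotic"
               else cfg.plastid_frac_euphotic)
    p = cfg.pras_target(period, zone)
    split = (cfg.pras_class_split_ss_surface
             if (period, zone) == ("SS", "surface") else cfg.pras_class_split)
    out: dict[str, float] = {}
    for g, w in split:
        out[g] = plastid * p * w
    for g, w in cfg.nonpras_split:
        out[g] = plastid * (1.0 - p) * w
    out["cyanobacteria-Prochlorococcus"] = cfg.cyano_frac * 0.7
    out["cyanobacteria-Synechococcus"] = cfg.cyano_frac * 0.3
    out["heterotroph-bacteria"] = 1.0 - plastid - cfg.cyano_frac
    return out


def _sample_asv_probs(
    cfg: CommunityConfig, period: str, zone: str, rng: np.random.Generator
) -> tuple[dict[str, float], np.ndarray]:
    """One sample's 16S ASV probability vector plus the Micromonas species
    latent shared with the 18S marker."""
    template = _group_template(cfg, period, zone)
    groups = list(template)
    alpha = cfg.dirichlet_conc_group * np.array([template[g] for g in groups])
    gfrac = rng.dirichlet(np.maximum(alpha, 1e-6))
    species_latent = rng.dirichlet(
        cfg.dirichlet_conc_species * np.array(MICRO_SPECIES_TEMPLATE)
    )
    probs: dict[str, float] = {}
    for g, gf in zip(groups, gfrac):
        if g == "heterotroph-bacteria":
            for i in range(1, 6):
                probs[f"asv16_het_{i}"] = gf / 5.0
            continue
        if g.startswith("cyanobacteria"):
            if g.endswith("Prochlorococcus"):
                probs["asv16_cyano_1"] = gf * 0.6
                probs["asv16_cyano_3"] = gf * 0.4
            else:
                probs["asv16_cyano_2"] = gf
            continue
        w = _within_weights(g, period)
        names = list(w)
        a = cfg.dirichlet_conc_asv * np.array([w[n] for n in names])
        frac = rng.dirichlet(np.maximum(a, 1e-6)) if len(names) > 1 else np.array([1.0])
        for n, f in zip(names, frac):
            if n == "__micromonas__":
                for sp, sl in zip(MICRO_SPECIES, species_latent):
                    probs[MICRO_ASV16[sp]] = gf * f * sl
            else:
                probs[n] = gf * f
    return probs, species_latent


def _counts18(
    cfg: CommunityConfig,
    micro_mass16: float,
    species_latent: np.ndarray,
    lib18: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """18S counts sharing the 16S species latent, with copy-number
    multipliers and lognormal noise; the planted null species follows an
    independently drawn latent instead."""
    null_latent = rng.dirichlet(
        cfg.dirichlet_conc_species * np.array(MICRO_SPECIES_TEMPLATE)
    )
    lat = species_latent.copy()
    lat[MICRO_SPECIES.index("m_nullsp")] = null_latent[MICRO_SPECIES.index("m_nullsp")]
    mult = np.array(cfg.copy_multipliers)
    noisy = lat * mult * np.exp(rng.normal(0.0, cfg.noise18_sd, len(lat)))
    if noisy.sum() <= 0:
        noisy = np.ones_like(noisy)
    noisy /= noisy.sum()
    m_frac = min(0.5, micro_mass16 * cfg.micro18_enrichment)
    probs: dict[str, float] = {}
    for sp, f in zip(MICRO_SPECIES, noisy):
        for asv18, w in MICRO_ASV18[sp]:
            probs[asv18] = m_frac * f * w
    rest = 1.0 - m_frac
    for i in range(1, 4):
        probs[f"asv18_other_{i}"] = rest / 3.0
    names = list(probs)
    draws = rng.multinomial(lib18, np.array([probs[n] for n in names]))
    return dict(zip(names, draws.tolist()))


def _counts_to_long(counts_by_sample: dict[str, dict[str, int]]) -> pd.DataFrame:
    rows = [
        {"sample_id": s, "asv_id": a, "count": int(c)}
        for s, d in counts_by_sample.items()
        for a, c in d.items()
        if c > 0
    ]
    return pd.DataFrame(rows, columns=["sample_id", "asv_id", "count"])


def simulate_zone_samples(
    period: str,
    zone: str,
    n: int,
    cfg: CommunityConfig = CommunityConfig(),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """n independent 16S samples from one (period, zone) template — a
    convenience for calibration experiments."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mu, s = _lognormal_params(cfg.library_mean, cfg.library_sd)
    out = {}
    for i in range(n):
        probs, _ = _sample_asv_probs(cfg, period, zone, rng)
        lib = max(1000, int(rng.lognormal(mu, s)))
        names = list(probs)
        draws = rng.multinomial(lib, np.array([probs[k] for k in names]))
        out[f"{period}_{zone}_{i:04d}"] = dict(zip(names, draws.tolist()))
    return _counts_to_long(out)


def _fluor_at(cfg: PhysicsConfig, row: pd.Series, depth: float) -> float:
    stratified = bool(row["dcm_is_dcm"])
    z = np.array([depth], dtype=float)
    center = row["dcm_center_m"]
    return float(_fluor_clean(cfg, z, row["mld_m"], center, stratified)[0])


def simulate_community(
    cfg: CommunityConfig,
    truth: GroundTruth,
    physics_cfg: PhysicsConfig = PhysicsConfig(),
    seed: Optional[int] = None,
) -> dict[str, pd.DataFrame]:
    """Paired 16S/18S count tables, taxonomy, sample metadata and bottle
    chemistry for every (profile, bottle depth) of a simulated physics run.

    Zones come from the planted per-profile features, so the (period, zone)
    composition templates line up with what the hydrography stage will
    recover.  Updates ``truth`` in place with per-sample (period, zone),
    the planted persistence roles, and the planted link status.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mu16, s16 = _lognormal_params(cfg.library_mean, cfg.library_sd)
    mu18, s18 = _lognormal_params(cfg.library18_mean, cfg.library18_sd)

    counts16: dict[str, dict[str, int]] = {}
    counts18: dict[str, dict[str, int]] = {}
    meta_rows, bottle_rows, sample_truth = [], [], []
    for _, prow in truth.profiles.iterrows():
        feats = ProfileFeatures(
            profile_id=prow["profile_id"],
            timestamp=np.datetime64(prow["timestamp"]),
            mld_m=prow["mld_m"],
            mld_bottom_limited=False,
            euphotic_depth_m=prow["euphotic_depth_m"],
            light1pct_depth_m=prow["light1pct_depth_m"],
            dcm=None,
        )
        if prow["dcm_is_dcm"]:
            from picoseason.hydro import DCMRegion

            feats.dcm = DCMRegion(
                upper_m=prow["dcm_upper_m"], max_m=prow["dcm_center_m"],
                lower_m=prow["dcm_lower_m"], max_fluor=1.0, is_dcm=True,
            )
        period = prow["label"]
        for depth in physics_cfg.bottle_depths_m:
            zone = assign_zone(depth, feats, period)
            sid = f"{prow['profile_id']}_d{int(depth):03d}"
            probs, latent = _sample_asv_probs(cfg, period, zone, rng)
            lib16 = max(1000, int(rng.lognormal(mu16, s16)))
            names = list(probs)
            draws = rng.multinomial(lib16, np.array([probs[k] for k in names]))
            counts16[sid] = dict(zip(names, draws.tolist()))
            micro_mass = sum(probs[MICRO_ASV16[sp]] for sp in MICRO_SPECIES)
            lib18 = max(500, int(rng.lognormal(mu18, s18)))
            counts18[sid] = _counts18(cfg, micro_mass, latent, lib18, rng)

            fluor = _fluor_at(physics_cfg, prow, depth)
            chla = cfg.chla_per_rfu * fluor * np.exp(rng.normal(0.0, cfg.chla_noise))
            nitrate = max(0.0, 0.01 + 1.6 * max(0.0, depth - 90.0) / 210.0
                          + rng.normal(0.0, 0.05))
            phosphate = max(0.0, 0.002 + 0.12 * max(0.0, depth - 90.0) / 210.0
                            + rng.normal(0.0, 0.01))
            meta_rows.append({
                "sample_id": sid, "profile_id": prow["profile_id"],
                "depth_m": float(depth),
                "timestamp": pd.Timestamp(prow["timestamp"]).isoformat(),
            })
            bottle_rows.append({
                "sample_id": sid, "chla_ug_kg": chla,
                "nitrate_nitrite_umol_kg": nitrate,
                "phosphate_umol_kg": phosphate,
                "poc": chla * 60.0 * np.exp(rng.normal(0.0, 0.2)),
            })
            sample_truth.append({"sample_id": sid, "period": period, "zone": zone})

    taxonomy = build_taxonomy()
    truth.samples = pd.DataFrame(sample_truth)
    truth.asv_truth = pd.DataFrame(
        [{"asv_id": a, "planted_role": "persistent"} for a in PERSISTENT_ASVS]
        + [{"asv_id": a, "planted_role": "ephemeral"} for a in EPHEMERAL_ASVS]
    )
    truth.link_truth = pd.DataFrame(
        [{"asv16_id": MICRO_ASV16[s], "species18_label": s,
          "linked": LINKED_TRUTH[s]} for s in MICRO_SPECIES]
    )
    return {
        "asv16": _counts_to_long(counts16),
        "asv18": _counts_to_long(counts18),
        "taxonomy": taxonomy,
        "meta": pd.DataFrame(meta_rows),
        "bottle": pd.DataFrame(bottle_rows),
    }


def simulate_linked_pair(
    n_samples: int = 30,
    linked: bool = True,
    seed: int = 0,
    genus_reads_mean: float = 300.0,
    cfg: CommunityConfig = CommunityConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Minimal paired tables for one cross-marker pair.

    Builds ``n_samples`` samples containing only the shared genus: the 16S
    ASV's within-genus fraction follows a per-sample latent; the 18S
    species follows the same latent (``linked=True``) or an independent one
    (``linked=False``), through binomial read sampling with lognormal
    18S noise.  Returns (table16, table18, taxonomy, pairs) ready for
    ``link_candidates``.
    """
    rng = np.random.default_rng(seed)
    sp = "m_cand1"
    asv16 = MICRO_ASV16[sp]
    asv18s = [a for a, _ in MICRO_ASV18[sp]]
    rows16, rows18 = [], []
    for i in range(n_samples):
        sid = f"S{i:04d}"
        f = rng.beta(0.8, 1.6)
        f18 = f if linked else rng.beta(0.8, 1.6)
        f18 = float(np.clip(f18 * np.exp(rng.normal(0.0, cfg.noise18_sd)), 0.0, 1.0))
        g16 = max(25, int(rng.poisson(genus_reads_mean)))
        g18 = max(25, int(rng.poisson(genus_reads_mean)))
        c16 = int(rng.binomial(g16, f))
        c18 = int(rng.binomial(g18, f18))
        rows16.append({"sample_id": sid, "asv_id": asv16, "count": c16})
        rows16.append({"sample_id": sid, "asv_id": "asv16_mcomA", "count": g16 - c16})
        split = rng.multinomial(c18, [w for _, w in MICRO_ASV18[sp]])
        for (a, _w), c in zip(MICRO_ASV18[sp], split.tolist()):
            rows18.append({"sample_id": sid, "asv_id": a, "count": c})
        rows18.append({"sample_id": sid, "asv_id": "asv18_mcomA_1", "count": g18 - c18})
    taxonomy = build_taxonomy()
    pairs = [(asv16, sp, tuple(asv18s))]
    return (pd.DataFrame(rows16), pd.DataFrame(rows18), taxonomy, pairs)
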