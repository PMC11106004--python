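"""Water-column physical structure and stability-period classification.

A subtropical annual cycle alternates between winter deep convective mixing
and summer thermal stratification.  This module derives, per CTD cast, the
mixed layer depth (MLD; density-offset criterion), light-fraction depths
(euphotic depth at 0.1% of surface PAR, plus a 1% comparison level), and the
deep chlorophyll maximum (DCM) region, then runs a small state machine over
the time-ordered casts to label four stability periods:

DM  deep mixing          — MLD deeper than the euphotic zone depth
ST  spring transition    — MLD has shoaled to ~100 m but not yet above the DCM
SS  stratified summer    — MLD shallower than the top of the DCM region
AT  autumn transition    — the deepening mixed layer first entrains the DCM

All depths are positive-down metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CTDProfile",
    "DCMRegion",
    "HydroParams",
    "ProfileFeatures",
    "StabilityTimeline",
    "InvalidProfileError",
    "UnclassifiedTimelineError",
    "compute_mld",
    "compute_light_depth",
    "detect_dcm",
    "compute_profile_features",
    "classify_stability_periods",
    "assign_zone",
    "ZONES",
]

ZONES = ("surface", "ml", "dcm", "light1pct", "below_euphotic", "other")


class InvalidProfileError(ValueError):
    """Raised when a CTD profile violates its invariants."""


class UnclassifiedTimelineError(ValueError):
    """Raised when no profile in a series satisfies any stability trigger."""


@dataclass(frozen=True)
class HydroParams:
    """Thresholds for the physical feature extraction.

    delta_sigma : kg m^-3
        Density offset over the shallowest sample that defines the MLD.
    dcm_fraction : dimensionless
        The DCM region is the contiguous interval where fluorescence stays
        within this fraction of the maximum, i.e. >= (1 - dcm_fraction)
        times the peak value.
    euphotic_par_fraction : dimensionless
        Surface-PAR fraction defining the euphotic zone depth (0.1%).
    comparison_par_fraction : dimensionless
        Surface-PAR fraction for the deep comparison level used during deep
        mixing, when no DCM exists (1%).
    st_mld_threshold_m : m
        MLD at which the spring transition begins.
    smoothing_window : count of profiles
        Optional running-median window applied to the MLD series before
        period classification; 1 disables smoothing.
    """

    delta_sigma: float = 0.125
    dcm_fraction: float = 0.35
    euphotic_par_fraction: float = 0.001
    comparison_par_fraction: float = 0.01
    st_mld_threshold_m: float = 100.0
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        if not (self.delta_sigma > 0 and self.st_mld_threshold_m > 0):
            raise ValueError("delta_sigma and st_mld_threshold_m must be positive")
        if not 0 < self.dcm_fraction < 1:
            raise ValueError("dcm_fraction must be in (0, 1)")
        if not 0 < self.euphotic_par_fraction < self.comparison_par_fraction < 1:
            raise ValueError(
                "require 0 < euphotic_par_fraction < comparison_par_fraction < 1"
            )
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


@dataclass
class CTDProfile:
    """One CTD cast: depth-aligned physical and bio-optical arrays.

    ``fluor_rfu`` and ``par`` may be ``None`` when the cast lacks the sensor;
    features depending on them are then absent.
    """

    profile_id: str
    timestamp: np.datetime64
    depth_m: np.ndarray
    temp_C: Optional[np.ndarray] = None
    salinity: Optional[np.ndarray] = None
    sigma_t: Optional[np.ndarray] = None
    fluor_rfu: Optional[np.ndarray] = None
    par: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.depth_m.size < 2:
            raise InvalidProfileError(
                f"profile {self.profile_id}: needs >= 2 depth samples"
            )
        if not np.all(np.diff(self.depth_m) > 0):
            raise InvalidProfileError(
                f"profile {self.profile_id}: depth_m must be strictly increasing"
            )
        for name in ("temp_C", "salinity", "sigma_t", "fluor_rfu", "par"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.depth_m.shape:
                raise InvalidProfileError(
                    f"profile {self.profile_id}: {name} length mismatch"
                )
            setattr(self, name, arr)
        if self.sigma_t is not None and not np.all(np.isfinite(self.sigma_t)):
            raise InvalidProfileError(
                f"profile {self.profile_id}: sigma_t must be finite"
            )
        if self.fluor_rfu is not None and np.any(self.fluor_rfu < 0):
            raise InvalidProfileError(
                f"profile {self.profile_id}: fluor_rfu must be >= 0"
            )
        if self.par is not None and np.any(self.par < 0):
            raise InvalidProfileError(f"profile {self.profile_id}: par must be >= 0")


@dataclass(frozen=True)
class DCMRegion:
    """Contiguous fluorescence-peak region around the profile maximum."""

    upper_m: float
    max_m: float
    lower_m: float
    max_fluor: float
    is_dcm: bool


@dataclass
class ProfileFeatures:
    """Derived per-cast features feeding period classification and zoning."""

    profile_id: str
    timestamp: np.datetime64
    mld_m: float
    mld_bottom_limited: bool
    euphotic_depth_m: Optional[float] = None
    light1pct_depth_m: Optional[float] = None
    dcm: Optional[DCMRegion] = None


@dataclass
class StabilityTimeline:
    """Dated sequence of stability-period labels with transition provenance.

    ``entries`` is an ordered list of (timestamp, label, trigger) where the
    trigger names the rule that put the timeline in that state.
    """

    entries: list = field(default_factory=list)

    @property
    def labels(self) -> list:
        return [label for _, label, _ in self.entries]

    def collapsed(self) -> list:
        """Consecutive-duplicate-free label sequence (the period cycle)."""
        out: list = []
        for label in self.labels:
            if not out or out[-1] != label:
                out.append(label)
        return out


def compute_mld(
    profile: CTDProfile, params: HydroParams = HydroParams()
) -> tuple[float, bool]:
    """Mixed layer depth: shallowest depth where sigma-t first reaches the
    surface value plus ``delta_sigma``, linearly interpolated between the
    bracketing samples.

    The shallowest sample stands in for "surface".  When no sample meets the
    criterion the cast is bottom-limited: the deepest sampled depth is
    returned with ``bottom_limited=True`` so deep-mixing detection still
    works on casts that do not reach the pycnocline.
    """
    if profile.sigma_t is None:
        raise InvalidProfileError(f"profile {profile.profile_id}: sigma_t missing")
    z = profile.depth_m
    sig = profile.sigma_t
    target = sig[0] + params.delta_sigma
    above = sig >= target
    if not above.any():
        return float(z[-1]), True
    i = int(np.argmax(above))
    if i == 0:
        return float(z[0]), False
    # Linear interpolation between the last sample below and first at/above.
    z0, z1 = z[i - 1], z[i]
    s0, s1 = sig[i - 1], sig[i]
    if s1 == s0:
        return float(z1), False
    return float(z0 + (z1 - z0) * (target - s0) / (s1 - s0)), False


def compute_light_depth(profile: CTDProfile, fraction: float) -> Optional[float]:
    """Depth where PAR first falls to ``fraction`` of its value at the
    shallowest sample, interpolated linearly in log(PAR) versus depth
    (exact for exponential attenuation).

    Returns ``None`` when PAR never falls that low within the cast.  Zero
    PAR readings are excluded from the log interpolation; if the first
    positive-PAR sample at depth already sits below the target, the segment
    down to the shallowest zero reading brackets the crossing.
    """
    if profile.par is None:
        raise InvalidProfileError(f"profile {profile.profile_id}: par missing")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    par = profile.par
    z = profile.depth_m
    if par[0] <= 0:
        raise InvalidProfileError(
            f"profile {profile.profile_id}: surface PAR must be positive"
        )
    if fraction == 1.0:
        return float(z[0])
    target = fraction * par[0]
    pos = par > 0
    zp, pp = z[pos], par[pos]
    below = pp <= target
    if not below.any():
        # A zero reading below the deepest positive one still proves the
        # light level was crossed; place it at the first zero sample.
        deeper_zero = (~pos) & (z > zp[-1])
        if deeper_zero.any():
            return float(z[deeper_zero][0])
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(zp[0])
    z0, z1 = zp[i - 1], zp[i]
    l0, l1 = np.log(pp[i - 1]), np.log(pp[i])
    lt = np.log(target)
    if l1 == l0:
        return float(z1)
    return float(z0 + (z1 - z0) * (lt - l0) / (l1 - l0))


def detect_dcm(
    profile: CTDProfile,
    mld_m: float,
    params: HydroParams = HydroParams(),
) -> Optional[DCMRegion]:
    """Locate the chlorophyll-fluorescence peak region.

    ``max_m`` is the depth of maximum fluorescence (shallowest on ties);
    ``upper_m``/``lower_m`` bound the contiguous interval containing the
    maximum where fluorescence stays >= (1 - dcm_fraction) of the peak,
    with boundaries linearly interpolated between samples.  The region
    counts as a true DCM (``is_dcm``) only when the mixed layer sits above
    it (``mld_m < upper_m``).

    Returns ``None`` when fluorescence has no positive maximum.
    """
    if profile.fluor_rfu is None:
        return None
    f = profile.fluor_rfu
    z = profile.depth_m
    fmax = float(np.nanmax(f))
    if not np.isfinite(fmax) or fmax <= 0:
        return None
    imax = int(np.nanargmax(f))
    max_m = float(z[imax])
    thresh = (1.0 - params.dcm_fraction) * fmax

    # Walk outward from the maximum while fluorescence stays at/above the
    # threshold, then interpolate the crossing on the first failing segment.
    i = imax
    while i > 0 and f[i - 1] >= thresh:
        i -= 1
    if i == 0:
        upper = float(z[0])
    else:
        upper = float(np.interp(thresh, [f[i - 1], f[i]], [z[i - 1], z[i]]))
    j = imax
    n = len(z)
    while j < n - 1 and f[j + 1] >= thresh:
        j += 1
    if j == n - 1:
        lower = float(z[-1])
    else:
        # descending limb: fluorescence decreases from f[j] to f[j+1]
        lower = float(np.interp(-thresh, [-f[j], -f[j + 1]], [z[j], z[j + 1]]))
    return DCMRegion(
        upper_m=upper,
        max_m=max_m,
        lower_m=lower,
        max_fluor=fmax,
        is_dcm=bool(mld_m < upper),
    )


def compute_profile_features(
    profile: CTDProfile, params: HydroParams = HydroParams()
) -> ProfileFeatures:
    """Bundle MLD, light depths and DCM region for one cast.

    Light depths require PAR with a positive surface value; the DCM requires
    fluorescence.  Missing sensors leave the corresponding feature absent.
    """
    mld, limited = compute_mld(profile, params)
    euphotic = light1 = None
    if profile.par is not None and profile.par[0] > 0:
        euphotic = compute_light_depth(profile, params.euphotic_par_fraction)
        light1 = compute_light_depth(profile, params.comparison_par_fraction)
    dcm = detect_dcm(profile, mld, params)
    return ProfileFeatures(
        profile_id=profile.profile_id,
        timestamp=profile.timestamp,
        mld_m=mld,
        mld_bottom_limited=limited,
        euphotic_depth_m=euphotic,
        light1pct_depth_m=light1,
        dcm=dcm,
    )


def _smooth_mld(features: Sequence[ProfileFeatures], window: int) -> list[float]:
    mlds = np.array([f.mld_m for f in features], dtype=float)
    if window <= 1 or len(mlds) < 2:
        return list(mlds)
    half = window // 2
    out = []
    for i in range(len(mlds)):
        lo, hi = max(0, i - half), min(len(mlds), i + half + 1)
        out.append(float(np.median(mlds[lo:hi])))
    return out


def classify_stability_periods(
    features: Sequence[ProfileFeatures],
    params: HydroParams = HydroParams(),
) -> StabilityTimeline:
    """Label time-ordered casts with stability periods DM/ST/SS/AT.

    State machine, evaluated at each cast with transitions cascading until
    no further rule fires (so a sparsely sampled series cannot get stuck one
    state behind the water column):

    * enter DM whenever MLD > euphotic depth — highest precedence, from any
      state, so renewed deep mixing after a mid-winter restratification
      re-enters DM;
    * DM -> ST when the MLD has shoaled to ``st_mld_threshold_m`` and the DM
      trigger no longer holds;
    * ST -> SS when a DCM exists and the MLD sits above its upper bound;
    * SS -> AT when the MLD reaches the DCM region's upper bound (first
      entrainment of the DCM into the mixed layer) without deep mixing.

    Labels persist between observations until a transition fires.  The first
    observation is seeded by whichever trigger holds, in precedence order
    DM > SS > ST.  Casts lacking the feature a rule needs simply cannot fire
    that rule.
    """
    feats = list(features)
    if not feats:
        raise UnclassifiedTimelineError("no profiles supplied")
    mlds = _smooth_mld(feats, params.smoothing_window)

    def dm_trigger(f: ProfileFeatures, mld: float) -> bool:
        return f.euphotic_depth_m is not None and mld > f.euphotic_depth_m

    def ss_trigger(f: ProfileFeatures, mld: float) -> bool:
        return f.dcm is not None and f.dcm.is_dcm and mld < f.dcm.upper_m

    def at_trigger(f: ProfileFeatures, mld: float) -> bool:
        return f.dcm is not None and mld >= f.dcm.upper_m and not dm_trigger(f, mld)

    def st_trigger(f: ProfileFeatures, mld: float) -> bool:
        return mld <= params.st_mld_threshold_m and not dm_trigger(f, mld)

    state: Optional[str] = None
    trigger = ""
    entries = []
    for f, mld in zip(feats, mlds):
        if state is None:
            if dm_trigger(f, mld):
                state, trigger = "DM", "seed: MLD > euphotic depth"
            elif ss_trigger(f, mld):
                state, trigger = "SS", "seed: MLD above DCM region"
            elif mld <= params.st_mld_threshold_m:
                state, trigger = "ST", "seed: MLD at/above ST threshold"
            else:
                entries.append((f.timestamp, None, "unclassified"))
                continue
            entries.append((f.timestamp, state, trigger))
            continue
        # Cascade transitions until the state is stable for this cast.
        fired = False
        for _ in range(4):
            if dm_trigger(f, mld) and state != "DM":
                state, trigger, fired = "DM", "MLD > euphotic depth", True
                continue
            if state == "DM" and st_trigger(f, mld):
                state, trigger, fired = "ST", "MLD shoaled to ST threshold", True
                continue
            if state == "ST" and ss_trigger(f, mld):
                state, trigger, fired = "SS", "MLD above DCM upper bound", True
                continue
            if state == "SS" and at_trigger(f, mld):
                state, trigger, fired = "AT", "MLD entrained DCM upper bound", True
                continue
            break
        entries.append((f.timestamp, state, trigger if fired else f"hold ({state})"))

    # Back-fill any leading unclassified casts with the first resolved state.
    first = next((lab for _, lab, _ in entries if lab is not None), None)
    if first is None:
        raise UnclassifiedTimelineError("no profile satisfies any stability trigger")
    resolved = []
    for ts, lab, trig in entries:
        if lab is None:
            resolved.append((ts, first, "back-filled from first classified cast"))
        else:
            resolved.append((ts, lab, trig))
    return StabilityTimeline(entries=resolved)


def assign_zone(
    sample_depth_m: float,
    features: ProfileFeatures,
    period_label: str,
    surface_max_depth_m: float = 5.0,
    light1pct_tolerance_m: float = 10.0,
) -> str:
    """Assign one vertical zone to a bottle sample.

    Rules are evaluated in order; the first match wins, so every sample
    receives exactly one zone:

    1. ``surface`` — depth <= 5 m;
    2. ``dcm`` — stratified-period cast (ST/SS/AT) with a true DCM and the
       depth inside [upper, lower];
    3. ``light1pct`` — deep-mixing cast, depth within +/-10 m of the 1%
       light level (the DM comparison point for the DCM);
    4. ``ml`` — depth at or above the mixed layer depth;
    5. ``below_euphotic`` — depth below the euphotic zone depth;
    6. ``other``.

    A rule whose feature is absent is skipped, never an error.
    """
    d = float(sample_depth_m)
    if d <= surface_max_depth_m:
        return "surface"
    if (
        period_label in ("ST", "SS", "AT")
        and features.dcm is not None
        and features.dcm.is_dcm
        and features.dcm.upper_m <= d <= features.dcm.lower_m
    ):
        return "dcm"
    if (
        period_label == "DM"
        and features.light1pct_depth_m is not None
        and abs(d - features.light1pct_depth_m) <= light1pct_tolerance_m
    ):
        return "light1pct"
    if d <= features.mld_m:
        return "ml"
    if features.euphotic_depth_m is not None and d > features.euphotic_depth_m:
        return "below_euphotic"
    return "other"
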