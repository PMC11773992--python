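"""Synthetic cohort generator.

Emulates a two-site intensive longitudinal study of high-risk adolescents:
~186 participants followed ~26 weeks, smartphone GPS available on ~75% of
days, weekly surveys answered on ~41% of weeks, a rare (~1% of
person-weeks) binary suicidal-event outcome driven by a within-person
homestay effect at a one-week lag, and a per-participant random intercept.

Generative model
----------------
* Each participant has a true home and ``n_anchor_locations`` anchor sites
  placed 0.6-5 km away (at least twice the homestay radius, so homestay
  and entropy are identifiable).
* A latent daily at-home fraction follows an AR(1) process on the logit
  scale; the 02:00-06:00 night window is spent at home on >=95% of days so
  the night-window home rule is well posed.
* Fixes are laid on a regular grid (default one per 10 minutes), assigned
  to home/anchor/travel segments, and jittered with isotropic Gaussian
  noise; whole days drop out completely at random.
* Weekly events are Bernoulli draws from a random-intercept logistic model
  on the *previous* week's standardized latent features; weekly ideation
  responses appear only on responded weeks.

The generator returns the ground truth (coefficients, random-intercept SD,
homes, latent series) alongside the data so every downstream stage can be
tested against it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import EARTH_RADIUS_KM

_SIGMOID = lambda z: 1.0 / (1.0 + np.exp(-z))

DESIGN_TERMS = (
    "homestay_within",
    "entropy_within",
    "distance_within",
    "homestay_between",
    "entropy_between",
    "distance_between",
    "weeks_since_baseline",
)

EVENT_TYPES = (
    "actual attempt",
    "aborted attempt",
    "interrupted attempt",
    "ED visit",
    "hospitalization",
)
_ATTEMPT_TYPES = EVENT_TYPES[:3]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the statistical structure the analysis assumes:
    186 participants x 26 weeks, 10-minute GPS cadence, 25% of days with
    no GPS, 41% weekly survey response, ~1% weekly event rate
    (``event_intercept`` -4.7 on the log-odds scale), a within-person
    homestay effect of ln 2 per 1 SD at lag 1, and a participant random
    intercept with SD 0.6.
    """

    n_participants: int = 186
    n_weeks: int = 26
    fixes_per_day: int = 144
    gps_day_missing_prob: float = 0.25
    esm_response_prob: float = 0.41
    home_radius_m: float = 200.0
    n_anchor_locations: int = 4
    within_homestay_logor: float = math.log(2.0)
    between_terms_logor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    random_intercept_sd: float = 0.6
    event_intercept: float = -4.7
    ideation_intercept: float = -2.75
    ideation_between_homestay_logor: float = 0.3
    weeks_logor: float = 0.0
    ar1_rho: float = 0.6
    ar1_sd: float = 0.8
    homestay_mu_mean: float = 0.5
    homestay_mu_sd: float = 0.4
    gps_jitter_m: float = 25.0
    night_home_prob: float = 0.95
    ssi_intercept_corr: float = 0.4
    study_start: str = "2022-01-05"  # a Wednesday
    enrollment_spread_days: int = 56
    seed: int = 0

    def __post_init__(self):
        for name in ("gps_day_missing_prob", "esm_response_prob", "night_home_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        if self.fixes_per_day < 24:
            raise ValueError("fixes_per_day must be >= 24")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in (-1, 1)")
        if self.n_anchor_locations < 1:
            raise ValueError("n_anchor_locations must be >= 1")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")

    @property
    def true_beta(self) -> dict[str, float]:
        b = dict.fromkeys(DESIGN_TERMS, 0.0)
        b["homestay_within"] = self.within_homestay_logor
        for name, v in zip(
            ("homestay_between", "entropy_between", "distance_between"),
            self.between_terms_logor,
        ):
            b[name] = float(v)
        b["weeks_since_baseline"] = self.weeks_logor
        return b


@dataclass
class GroundTruth:
    true_beta: dict[str, float]
    true_sigma_u: float
    event_intercept: float
    homes: dict  # participant_id -> (lat, lon)
    random_intercepts: dict
    latent_weekly: pd.DataFrame = field(repr=False)
    daily_truth: pd.DataFrame = field(repr=False)


@dataclass
class Cohort:
    gps: pd.DataFrame
    esm: pd.DataFrame
    events: pd.DataFrame
    baseline: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _participant_geography(rng: np.random.Generator, cfg: SimConfig):
    """Home plus anchors 0.6-5 km away (>= 2x home radius from home)."""
    home_lat = 40.7 + rng.normal(0.0, 0.05)
    home_lon = -74.0 + rng.normal(0.0, 0.05)
    min_r = 2.0 * cfg.home_radius_m / 1000.0
    anchors = []
    for _ in range(cfg.n_anchor_locations):
        r_km = rng.uniform(max(0.6, min_r), 5.0)
        th = rng.uniform(0.0, 2.0 * math.pi)
        dlat = (r_km / EARTH_RADIUS_KM) * math.degrees(1.0) * math.cos(th)
        dlon = (r_km / (EARTH_RADIUS_KM * math.cos(math.radians(home_lat)))) * math.degrees(
            1.0
        ) * math.sin(th)
        anchors.append((home_lat + dlat, home_lon + dlon))
    return (home_lat, home_lon), anchors


def _latent_ar1(rng: np.random.Generator, rho: float, sd: float, mu: float, n: int):
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    a = np.empty(n)
    a[0] = mu + rng.normal(0.0, sd)
    for d in range(1, n):
        a[d] = mu + rho * (a[d - 1] - mu) + rng.normal(0.0, innov_sd)
    return a


def _latent_home_fraction(rng: np.random.Generator, cfg: SimConfig, n_days: int):
    """Logit-AR(1) daily fraction of non-night time spent at home."""
    mu = rng.normal(cfg.homestay_mu_mean, cfg.homestay_mu_sd)
    return _SIGMOID(_latent_ar1(rng, cfg.ar1_rho, cfg.ar1_sd, mu, n_days))


def simulate_mobility(cfg: SimConfig, participant: int, rng: np.random.Generator):
    """One participant's GPS stream plus per-day generative truth.

    Returns ``(gps_df, daily_truth_df, home)`` where the truth frame holds
    the generative home fraction, path length, and dwell-entropy per day
    for every day (including days later dropped as missing, flagged by
    ``observed``).
    """
    home, anchors = _participant_geography(rng, cfg)
    n_days = cfg.n_weeks * 7
    h_frac = _latent_home_fraction(rng, cfg, n_days)
    # persistent "evenness" process, independent of homestay: controls how
    # away-time spreads over anchors, giving entropy variation of its own
    spread = _SIGMOID(
        _latent_ar1(rng, cfg.ar1_rho, 1.2, rng.normal(0.0, 0.8), n_days)
    )
    step_min = 1440.0 / cfg.fixes_per_day
    minutes = np.arange(cfg.fixes_per_day) * step_min
    night = (minutes >= 120.0) & (minutes < 360.0)
    n_night = int(night.sum())
    n_day = cfg.fixes_per_day - n_night
    observed = rng.random(n_days) >= cfg.gps_day_missing_prob
    night_at_home = rng.random(n_days) < cfg.night_home_prob

    sites = [home] + anchors
    all_rows = []
    truth_rows = []
    for d in range(n_days):
        # build the day's site sequence: morning home, anchor visits, evening home
        n_home_day = int(round(h_frac[d] * n_day))
        n_away = n_day - n_home_day
        counts = np.zeros(len(anchors), dtype=int)
        if n_away > 0:
            # concentration follows the persistent evenness process: low ->
            # a single errand dominates the day, high -> time spreads evenly
            alpha = 0.15 + 3.0 * spread[d]
            w = rng.dirichlet(np.full(len(anchors), alpha))
            counts = rng.multinomial(n_away, w)
        visit = [(0, n_home_day // 2 + n_home_day % 2)]
        for j, c in enumerate(counts):
            if c > 0:
                visit.append((j + 1, int(c)))
        visit.append((0, n_home_day // 2))
        site_idx = np.concatenate(
            [np.full(c, s, dtype=int) for s, c in visit if c > 0]
        ) if any(c > 0 for _, c in visit) else np.zeros(0, dtype=int)
        # non-night slots get the schedule; night slots forced to home (or anchor 0)
        seq = np.empty(cfg.fixes_per_day, dtype=int)
        night_site = 0 if night_at_home[d] else 1
        seq[night] = night_site
        seq[~night] = site_idx[:n_day]
        # travel fixes: the first fix of each new segment sits at the midpoint
        # of the leg, emulating a fix caught in transit
        lat = np.array([sites[s][0] for s in seq])
        lon = np.array([sites[s][1] for s in seq])
        trans = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        is_travel = np.zeros(cfg.fixes_per_day, dtype=bool)
        for i in trans:
            # interpolate only when the segment keeps >= 2 fixes, so the
            # observed polyline still passes through every visited site
            if i + 1 < len(seq) and seq[i + 1] == seq[i]:
                lat[i] = 0.5 * (lat[i - 1] + sites[seq[i]][0])
                lon[i] = 0.5 * (lon[i - 1] + sites[seq[i]][1])
                is_travel[i] = True
        # generative truth, computed on the noiseless positions
        at_site = seq.copy()
        at_home = (seq == 0) & ~is_travel
        site_counts = np.bincount(at_site[~is_travel], minlength=len(sites))
        p = site_counts[site_counts > 0] / site_counts.sum()
        entropy_true = float(-(p * np.log(p)).sum())
        path_km = 0.0
        prev = seq[0]
        for s in seq[1:]:
            if s != prev:
                path_km += _site_dist_km(sites[prev], sites[s])
                prev = s
        truth_rows.append(
            {
                "participant_id": participant,
                "day_index": d,
                "observed": bool(observed[d]),
                "home_fraction": float(at_home.mean()),
                "homestay_true_h": float(at_home.mean() * 24.0),
                "entropy_true_nats": entropy_true,
                "distance_true_km": path_km,
                "n_travel_fixes": int(is_travel.sum()),
            }
        )
        if not observed[d]:
            continue
        if cfg.gps_jitter_m > 0:
            jd = cfg.gps_jitter_m / 1000.0 / EARTH_RADIUS_KM * math.degrees(1.0)
            lat = lat + rng.normal(0.0, jd, size=len(lat))
            lon = lon + rng.normal(
                0.0, jd / math.cos(math.radians(home[0])), size=len(lon)
            )
        all_rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant,
                    "day_index": d,
                    "minute": minutes,
                    "lat": lat,
                    "lon": lon,
                }
            )
        )
    gps = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else pd.DataFrame(columns=["participant_id", "day_index", "minute", "lat", "lon"])
    )
    return gps, pd.DataFrame(truth_rows), home


def _site_dist_km(a, b):
    dlat = math.radians(b[0] - a[0])
    dlon = math.radians(b[1] - a[1])
    x = dlon * math.cos(math.radians(0.5 * (a[0] + b[0]))) * EARTH_RADIUS_KM
    y = dlat * EARTH_RADIUS_KM
    return math.hypot(x, y)


def latent_weekly_panel(daily_truth: pd.DataFrame) -> pd.DataFrame:
    """Weekly means of the latent (noiseless, no-missingness) daily truth."""
    df = daily_truth.copy()
    df["week_index"] = df["day_index"] // 7
    wk = (
        df.groupby(["participant_id", "week_index"], sort=True)
        .agg(
            homestay=("homestay_true_h", "mean"),
            entropy=("entropy_true_nats", "mean"),
            distance=("distance_true_km", "mean"),
        )
        .reset_index()
    )
    return wk


def _standardize_latent(wk: pd.DataFrame) -> pd.DataFrame:
    """Within/between decomposition of the latent weekly features."""
    out = wk.copy()
    for col in ("homestay", "entropy", "distance"):
        pm = out.groupby("participant_id")[col].transform("mean")
        centered = out[col] - pm
        sd_w = centered.std(ddof=1)
        person_means = out.groupby("participant_id")[col].mean()
        sd_b = person_means.std(ddof=1)
        out[f"{col}_within"] = centered / (sd_w if sd_w > 0 else 1.0)
        out[f"{col}_between"] = (pm - person_means.mean()) / (sd_b if sd_b > 0 else 1.0)
    return out


def simulate_outcomes(
    cfg: SimConfig, latent_weekly: pd.DataFrame, rng: np.random.Generator
):
    """Weekly events and survey responses from the generative logistic model.

    Events in week T (T >= 1) are Bernoulli draws with log-odds
    ``event_intercept + beta . x_{T-1} + u_i``; ideation flags use the
    ideation intercept, the between-person homestay term, and the same
    random intercept, and appear only on responded weeks.

    Raises ``ValueError`` if the implied marginal event rate exceeds 20%
    (outside the rare-event regime; signals misconfiguration).
    """
    std = _standardize_latent(latent_weekly)
    beta = SimConfig.true_beta.fget(cfg)
    pids = std["participant_id"].unique()
    u = dict(zip(pids, rng.normal(0.0, cfg.random_intercept_sd, size=len(pids))))
    std = std.sort_values(["participant_id", "week_index"]).reset_index(drop=True)
    lagged = std.groupby("participant_id")[
        ["homestay_within", "entropy_within", "distance_within"]
    ].shift(1)
    eta = (
        cfg.event_intercept
        + beta["homestay_within"] * lagged["homestay_within"].fillna(0.0)
        + beta["entropy_within"] * lagged["entropy_within"].fillna(0.0)
        + beta["distance_within"] * lagged["distance_within"].fillna(0.0)
        + beta["homestay_between"] * std["homestay_between"]
        + beta["entropy_between"] * std["entropy_between"]
        + beta["distance_between"] * std["distance_between"]
        + beta["weeks_since_baseline"] * std["week_index"]
        + std["participant_id"].map(u).astype(float)
    )
    p_event = _SIGMOID(eta.to_numpy())
    first_week = lagged["homestay_within"].isna().to_numpy()
    p_event = np.where(first_week, 0.0, p_event)  # no lagged exposure in week 0
    if p_event[~first_week].mean() > 0.20:
        raise ValueError(
            "implied marginal event rate exceeds 20%; outside the rare-event "
            "regime this generator targets — lower event_intercept or effects"
        )
    event = rng.random(len(std)) < p_event

    responded = rng.random(len(std)) < cfg.esm_response_prob
    eta_idea = (
        cfg.ideation_intercept
        + cfg.ideation_between_homestay_logor * std["homestay_between"]
        + std["participant_id"].map(u).astype(float)
    )
    ideation_flag = rng.random(len(std)) < _SIGMOID(eta_idea.to_numpy())

    out = std[["participant_id", "week_index"]].copy()
    out["event"] = event.astype(int)
    out["responded"] = responded.astype(int)
    out["ideation_flag"] = np.where(responded, ideation_flag.astype(int), -1)
    return out, u


def simulate_panel_direct(
    n_participants: int = 186,
    n_weeks: int = 25,
    beta: dict[str, float] | None = None,
    sigma_u: float = 0.6,
    intercept: float = -4.6,
    seed: int = 0,
    ar1_rho: float = 0.0,
) -> pd.DataFrame:
    """Weekly panel drawn directly from the random-intercept logistic model.

    Skips GPS simulation entirely: within-person terms are standard-normal
    AR(1) series (already person-centred and scaled), between-person terms
    are standard-normal participant constants, and the outcome is Bernoulli
    with log-odds ``intercept + x'beta + u_i``.  This is the generative
    inverse of the weekly event model, used for parameter-recovery and
    error-rate experiments where the design must be exactly the model's.
    """
    b = dict.fromkeys(DESIGN_TERMS, 0.0)
    if beta:
        b.update(beta)
    rng = np.random.default_rng(seed)
    n = n_participants * n_weeks
    pid = np.repeat(np.arange(n_participants), n_weeks)
    week = np.tile(np.arange(n_weeks), n_participants)
    cols = {}
    for f in ("homestay", "entropy", "distance"):
        if ar1_rho:
            x = np.empty((n_participants, n_weeks))
            x[:, 0] = rng.standard_normal(n_participants)
            innov = math.sqrt(1.0 - ar1_rho**2)
            for t in range(1, n_weeks):
                x[:, t] = ar1_rho * x[:, t - 1] + innov * rng.standard_normal(n_participants)
            cols[f"{f}_within"] = x.ravel()
        else:
            cols[f"{f}_within"] = rng.standard_normal(n)
        cols[f"{f}_between"] = np.repeat(rng.standard_normal(n_participants), n_weeks)
    u = np.repeat(rng.normal(0.0, sigma_u, n_participants), n_weeks)
    eta = intercept + u
    for term in DESIGN_TERMS:
        x = cols[term] if term in cols else week
        eta = eta + b[term] * x
    y = (rng.random(n) < _SIGMOID(eta)).astype(int)
    return pd.DataFrame(
        {"participant_id": pid, "week_index": week, "outcome": y,
         **cols, "weeks_since_baseline": week}
    )


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate the full cohort: GPS, ESM, events, baseline, ground truth."""
    root = np.random.SeedSequence(cfg.seed)
    ss_geo, ss_out, ss_meta = root.spawn(3)
    geo_streams = ss_geo.spawn(cfg.n_participants)
    start = pd.Timestamp(cfg.study_start)
    meta_rng = np.random.default_rng(ss_meta)
    # staggered enrollment (any weekday); week bins downstream snap to Wednesdays
    enroll_offsets = meta_rng.integers(0, cfg.enrollment_spread_days, cfg.n_participants)

    gps_parts, truth_parts, homes = [], [], {}
    for i in range(cfg.n_participants):
        rng = np.random.default_rng(geo_streams[i])
        g, tr, home = simulate_mobility(cfg, i, rng)
        enroll = start + pd.Timedelta(days=int(enroll_offsets[i]))
        # align day 0 with the participant's week-0 Wednesday
        week0 = enroll - pd.Timedelta(days=int((enroll.dayofweek - 2) % 7))
        if len(g):
            g = g.copy()
            g["t"] = week0 + pd.to_timedelta(g["day_index"] * 1440 + g["minute"], unit="m")
            g["accuracy_m"] = cfg.gps_jitter_m
        tr = tr.copy()
        tr["date"] = (week0 + pd.to_timedelta(tr["day_index"], unit="D")).dt.date
        tr["enrollment_date"] = enroll.date()
        gps_parts.append(g[["participant_id", "t", "lat", "lon", "accuracy_m"]] if len(g) else g)
        truth_parts.append(tr)
        homes[i] = home
    gps = pd.concat([g for g in gps_parts if len(g)], ignore_index=True) if any(
        len(g) for g in gps_parts
    ) else pd.DataFrame(columns=["participant_id", "t", "lat", "lon", "accuracy_m"])
    daily_truth = pd.concat(truth_parts, ignore_index=True) if truth_parts else pd.DataFrame()

    out_rng = np.random.default_rng(ss_out)
    latent = latent_weekly_panel(daily_truth) if len(daily_truth) else pd.DataFrame(
        columns=["participant_id", "week_index", "homestay", "entropy", "distance"]
    )
    if len(latent):
        outcomes, u = simulate_outcomes(cfg, latent, out_rng)
    else:
        outcomes = pd.DataFrame(
            columns=["participant_id", "week_index", "event", "responded", "ideation_flag"]
        )
        u = {}

    week0_by_pid = {
        i: pd.Timestamp(cfg.study_start)
        + pd.Timedelta(days=int(enroll_offsets[i]))
        - pd.Timedelta(
            days=int(
                (
                    (pd.Timestamp(cfg.study_start) + pd.Timedelta(days=int(enroll_offsets[i]))).dayofweek
                    - 2
                )
                % 7
            )
        )
        for i in range(cfg.n_participants)
    }

    esm_rows, event_rows = [], []
    for _, r in outcomes.iterrows():
        pid = int(r["participant_id"])
        wk_start = week0_by_pid[pid] + pd.Timedelta(weeks=int(r["week_index"]))
        survey_date = wk_start + pd.Timedelta(days=7)  # next Wednesday, past-week recall
        responded = int(r["responded"])
        flag = int(r["ideation_flag"])
        if responded:
            if flag == 1:
                if out_rng.random() < 0.25:
                    ideation, plan = int(out_rng.integers(1, 4)), "yes"
                else:
                    ideation, plan = int(out_rng.integers(4, 6)), ("yes" if out_rng.random() < 0.3 else "no")
            else:
                ideation, plan = int(out_rng.integers(1, 4)), "no"
            attempt = "yes" if (r["event"] and out_rng.random() < 0.5) else "no"
        else:
            ideation, plan, attempt = "", "", ""
        esm_rows.append(
            {
                "participant_id": pid,
                "survey_date": survey_date.date(),
                "responded": responded,
                "ideation_1to5": ideation,
                "plan_yn": plan,
                "attempt_yn": attempt,
            }
        )
        if r["event"]:
            day = int(out_rng.integers(0, 7))
            edate = wk_start + pd.Timedelta(days=day)
            etype = _ATTEMPT_TYPES[int(out_rng.integers(0, 3))]
            event_rows.append(
                {"participant_id": pid, "event_date": edate.date(), "event_type": etype}
            )
            # sometimes care contact (ED/hospitalization) follows within 7 days;
            # downstream merging should fold it back into one event
            if out_rng.random() < 0.3:
                follow = edate + pd.Timedelta(days=int(out_rng.integers(0, 6)))
                ftype = "ED visit" if out_rng.random() < 0.6 else "hospitalization"
                event_rows.append(
                    {
                        "participant_id": pid,
                        "event_date": follow.date(),
                        "event_type": ftype,
                    }
                )
    esm = pd.DataFrame(
        esm_rows,
        columns=["participant_id", "survey_date", "responded", "ideation_1to5", "plan_yn", "attempt_yn"],
    )
    events = pd.DataFrame(event_rows, columns=["participant_id", "event_date", "event_type"])

    z = meta_rng.standard_normal(cfg.n_participants)
    u_vec = np.array([u.get(i, 0.0) for i in range(cfg.n_participants)])
    u_std = u_vec / cfg.random_intercept_sd if cfg.random_intercept_sd > 0 else u_vec
    lam = cfg.ssi_intercept_corr
    ssi = np.clip(
        np.round(10.0 + 6.0 * (lam * u_std + math.sqrt(max(0.0, 1 - lam**2)) * z)), 0, 38
    ).astype(int)
    baseline = pd.DataFrame(
        {
            "participant_id": np.arange(cfg.n_participants),
            "ssi": ssi,
            "site": np.where(meta_rng.random(cfg.n_participants) < 0.45, "NY", "PITT"),
            "sex": np.where(meta_rng.random(cfg.n_participants) < 0.80, "F", "M"),
            "age": meta_rng.integers(13, 19, cfg.n_participants),
            "device": np.where(meta_rng.random(cfg.n_participants) < 0.7, "iOS", "Android"),
            "enrollment_date": [
                (pd.Timestamp(cfg.study_start) + pd.Timedelta(days=int(o))).date()
                for o in enroll_offsets
            ],
        }
    )

    truth = GroundTruth(
        true_beta={"intercept": cfg.event_intercept, **SimConfig.true_beta.fget(cfg)},
        true_sigma_u=cfg.random_intercept_sd,
        event_intercept=cfg.event_intercept,
        homes=homes,
        random_intercepts={int(k): float(v) for k, v in u.items()},
        latent_weekly=latent,
        daily_truth=daily_truth,
    )
    return Cohort(gps=gps, esm=esm, events=events, baseline=baseline, truth=truth, config=cfg)


def write_cohort(directory: str | os.PathLike, cohort: Cohort, overwrite: bool = False) -> list[str]:
    """Write gps/esm/events/baseline CSVs plus ground_truth.json.

    Refuses to overwrite existing files unless ``overwrite=True``.  Output
    is byte-deterministic for a fixed :class:`SimConfig` seed.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        name: os.path.join(directory, f"{name}.csv")
        for name in ("gps", "esm", "events", "baseline")
    }
    paths["ground_truth"] = os.path.join(directory, "ground_truth.json")
    if not overwrite:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists; pass overwrite=True to replace it")
    gps = cohort.gps.copy()
    if len(gps):
        gps["t"] = pd.to_datetime(gps["t"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        gps["lat"] = gps["lat"].map(lambda v: f"{v:.7f}")
        gps["lon"] = gps["lon"].map(lambda v: f"{v:.7f}")
    gps.rename(
        columns={"t": "timestamp_iso8601_local", "lat": "lat_deg", "lon": "lon_deg"}
    ).to_csv(paths["gps"], index=False)
    cohort.esm.to_csv(paths["esm"], index=False)
    cohort.events.to_csv(paths["events"], index=False)
    cohort.baseline.to_csv(paths["baseline"], index=False)
    gt = {
        "true_beta": cohort.truth.true_beta,
        "true_sigma_u": cohort.truth.true_sigma_u,
        "homes": {str(k): list(v) for k, v in cohort.truth.homes.items()},
        "random_intercepts": cohort.truth.random_intercepts,
        "config": {k: v for k, v in asdict(cohort.config).items()},
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sorted(paths.values())
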