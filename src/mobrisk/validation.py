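"""Predictive validation: leave-future-out weeks and between-person splits.

Two designs mirror how a weekly risk model would be audited:

* **leave-future-out** — for each participant, the first half of their
  observed span trains the model and only their later weeks are scored,
  so no future information leaks into training.  Risk scores use fixed
  effects only (random intercepts would let past outcomes predict
  themselves).  AUC uncertainty comes from a percentile bootstrap over
  test rows.
* **between-person** — geolocation features aggregated over each
  participant's first month predict who has any event (or any ideation
  week) later; a 70/30 participant split is redrawn ``reps`` times and the
  AUC distribution over repetitions gives the interval.

AUC uses the Mann-Whitney formulation with midrank tie handling, which
equals trapezoidal ROC integration; it and the bootstrap are implemented
here rather than imported so they can be verified against brute-force
pairwise counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import glmm
from .panel import FEATURES

BASELINE_TERMS = ("ssi", "site_pitt", "sex_male", "age", "device_android")

MODEL_CARDS: dict[int, tuple[str, ...]] = {
    1: tuple(f"{f}_within" for f in FEATURES) + tuple(f"{f}_between" for f in FEATURES),
    2: ("homestay_within", "homestay_between"),
    3: BASELINE_TERMS,
    4: ("homestay_within", "homestay_between") + BASELINE_TERMS,
    5: tuple(f"{f}_within" for f in FEATURES)
    + tuple(f"{f}_between" for f in FEATURES)
    + BASELINE_TERMS,
}

CARD_NAMES = {
    1: "all-geo",
    2: "homestay-only",
    3: "baseline-only",
    4: "homestay+baseline",
    5: "all-geo+baseline",
}

# between-person design uses first-month aggregate levels, not weekly terms
BETWEEN_CARDS: dict[int, tuple[str, ...]] = {
    1: ("agg_homestay", "agg_entropy", "agg_distance"),
    2: ("agg_homestay",),
    3: BASELINE_TERMS,
    4: ("agg_homestay",) + BASELINE_TERMS,
    5: ("agg_homestay", "agg_entropy", "agg_distance") + BASELINE_TERMS,
}


@dataclass
class ValidationResult:
    model_id: int
    design: str  # "leave-future-out" | "between-person"
    outcome: str  # "events" | "ideation"
    auc: float
    ci_low: float
    ci_high: float
    n_test_rows: int
    n_positive: int
    above_chance: bool
    defined: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["model"] = CARD_NAMES[self.model_id]
        return d


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg);
    ties contribute 1/2.  Raises on single-class labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(
    scores,
    labels,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for AUC over i.i.d. resamples of test rows.

    Resamples with a single-class draw are redrawn implicitly by being
    skipped (they carry no AUC); with rare positives this matches the
    behaviour of returning percentiles over defined resamples.
    """
    rng = rng or np.random.default_rng()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    idx = rng.integers(0, n, size=(n_boot, n))
    lab = labels[idx]
    n_pos = (lab == 1).sum(axis=1)
    ok = (n_pos > 0) & (n_pos < n)
    vals = np.empty(ok.sum())
    for i, b in enumerate(np.flatnonzero(ok)):
        vals[i] = auc(scores[idx[b]], lab[b])
    alpha = 1.0 - level
    lo, hi = np.percentile(vals, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return float(lo), float(hi)


def _panel_with_baseline(panel: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    b = encode_baseline(baseline)
    return panel.merge(b, on="participant_id", how="left")


def encode_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Numeric coding of baseline covariates (SSI, site, sex, age, device)."""
    b = baseline.copy()
    out = pd.DataFrame(
        {
            "participant_id": b["participant_id"],
            "ssi": pd.to_numeric(b["ssi"]),
            "site_pitt": (b["site"].astype(str).str.upper() != "NY").astype(float),
            "sex_male": (b["sex"].astype(str).str.upper().str.startswith("M")).astype(float),
            "age": pd.to_numeric(b["age"]),
            "device_android": (
                b["device"].astype(str).str.lower().str.contains("android")
            ).astype(float),
        }
    )
    return out


def leave_future_out(
    panel: pd.DataFrame,
    baseline: pd.DataFrame,
    outcome: str = "events",
    cards: dict[int, tuple[str, ...]] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    n_quad_nodes: int = 25,
) -> list[ValidationResult]:
    """Leave-future-out weekly prediction for each model card.

    Each participant's weeks are split at the midpoint of their own span
    of panel weeks; models are fit on the pooled first halves (random
    intercept in the likelihood) and held-out second-half weeks are scored
    by fixed effects only.
    """
    cards = cards or MODEL_CARDS
    df = _panel_with_baseline(panel, baseline)
    mid = df.groupby("participant_id")["week_index"].transform(
        lambda w: (w.min() + w.max()) / 2.0
    )
    train = df[df["week_index"] <= mid]
    test = df[df["week_index"] > mid]
    assert int(train["week_index"].count()) + int(test["week_index"].count()) == len(df)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2001]))
    results = []
    for mid_, feats in sorted(cards.items()):
        sub_train = train.dropna(subset=list(feats))
        sub_test = test.dropna(subset=list(feats))
        n_pos = int((sub_test["outcome"] == 1).sum())
        if n_pos == 0 or n_pos == len(sub_test):
            results.append(
                ValidationResult(
                    mid_, "leave-future-out", outcome, np.nan, np.nan, np.nan,
                    len(sub_test), n_pos, False, defined=False,
                    note="no positive (or no negative) test rows",
                )
            )
            continue
        spec = glmm.GlmmSpec(outcome="outcome", fixed_terms=tuple(feats), n_quad_nodes=n_quad_nodes)
        f = glmm.fit(spec, sub_train)
        scores = glmm.predict_fixed(f, sub_test)
        a = auc(scores, sub_test["outcome"].to_numpy())
        lo, hi = bootstrap_auc_ci(
            scores, sub_test["outcome"].to_numpy(), n_boot=n_boot, rng=rng
        )
        results.append(
            ValidationResult(
                mid_, "leave-future-out", outcome, a, lo, hi,
                len(sub_test), n_pos, bool(lo >= 0.5),
            )
        )
    return results


def first_month_aggregate(
    daily: pd.DataFrame,
    enrollment: pd.Series | dict,
    window_days: int = 28,
    min_days: int = 12,
) -> pd.DataFrame:
    """Mean daily features over the first ``window_days`` from enrollment.

    Participants with fewer than ``min_days`` observed days in the window
    are flagged ``insufficient`` (and excluded from between-person models).
    """
    if isinstance(enrollment, dict):
        enrollment = pd.Series(enrollment)
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    enr = df["participant_id"].map(lambda p: pd.Timestamp(enrollment.loc[p]))
    keep = (df["date"] >= enr) & (df["date"] < enr + pd.Timedelta(days=window_days))
    df = df[keep]
    agg = (
        df.groupby("participant_id")
        .agg(
            agg_homestay=("homestay_h", "mean"),
            agg_entropy=("entropy_nats", "mean"),
            agg_distance=("distance_km", "mean"),
            n_days=("date", "nunique"),
        )
        .reset_index()
    )
    agg["insufficient"] = agg["n_days"] < min_days
    return agg


def between_person(
    aggregates: pd.DataFrame,
    baseline: pd.DataFrame,
    outcome_by_pid: pd.Series,
    outcome: str = "events",
    cards: dict[int, tuple[str, ...]] | None = None,
    train_frac: float = 0.7,
    reps: int = 10_000,
    seed: int = 0,
) -> list[ValidationResult]:
    """Who-is-at-risk identification from first-month aggregates.

    One plain logistic regression per card per repetition on a random
    ``train_frac`` participant split; reported AUC is the mean over
    repetitions and the interval is the 2.5/97.5 percentile of the AUC
    distribution.  Splits whose test side lacks a positive (or negative)
    participant are redrawn and counted.
    """
    cards = cards or BETWEEN_CARDS
    df = aggregates[~aggregates["insufficient"]].merge(
        encode_baseline(baseline), on="participant_id", how="left"
    )
    df = df.merge(
        outcome_by_pid.rename("y"), left_on="participant_id", right_index=True, how="inner"
    ).dropna(subset=["y"])
    y_all = df["y"].to_numpy(dtype=float)
    if int(y_all.sum()) < 3:
        raise ValueError(
            "fewer than 3 positive participants overall; increase the simulated "
            "effect or cohort size before running between-person validation"
        )
    n = len(df)
    n_train = int(round(train_frac * n))
    results = []
    for cid, feats in sorted(cards.items()):
        X = np.column_stack([np.ones(n)] + [df[f].to_numpy(dtype=float) for f in feats])
        # per-card child streams so the first repetition is identical
        # whatever the total number of repetitions
        child = np.random.SeedSequence([seed, 3000 + cid]).spawn(reps)
        aucs = np.empty(reps)
        redraws = 0
        for r in range(reps):
            rng = np.random.default_rng(child[r])
            for _ in range(1000):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                if 0 < y_all[te].sum() < len(te) and 0 < y_all[tr].sum() < len(tr):
                    break
                redraws += 1
            beta = glmm.logistic_irls(X[tr], y_all[tr], ridge=1e-4)
            aucs[r] = auc(X[te] @ beta, y_all[te])
        mean_auc = float(aucs.mean())
        lo, hi = (
            (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
            if reps > 1
            else (float(aucs[0]), float(aucs[0]))
        )
        results.append(
            ValidationResult(
                cid, "between-person", outcome, mean_auc, lo, hi,
                n - n_train, int(y_all.sum()), bool(lo >= 0.5),
                note=f"{redraws} splits redrawn" if redraws else "",
            )
        )
    return results


def outcome_after_first_month(
    outcomes: pd.DataFrame,
    kind: str = "events",
    first_weeks: int = 4,
    all_pids=None,
) -> pd.Series:
    """Binary per-participant outcome: any event (or ideation week) after
    the first month of participation.

    Events are exhaustively ascertained, so participants with no later
    event record are 0 (pass ``all_pids`` to include participants with no
    outcome rows at all); ideation depends on survey response, so
    participants with no responded later week are missing.
    """
    later = outcomes[outcomes["week_index"] > first_weeks]
    col = "event_flag" if kind == "events" else "ideation_flag"
    flags = later.groupby("participant_id")[col].apply(
        lambda s: float((s == 1).any()) if (kind == "events" or s.notna().any()) else np.nan
    )
    if all_pids is not None:
        flags = flags.reindex(pd.Index(all_pids, name="participant_id"))
        if kind == "events":
            flags = flags.fillna(0.0)
    return flags
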