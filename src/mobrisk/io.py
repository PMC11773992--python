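"""Schema-validating readers and writers for the pipeline's CSV formats.

All interchange is plain CSV with fixed column schemas (GPS fixes, weekly
survey responses, event records, baseline covariates, daily features,
weekly panels).  Readers collect row-level problems and raise a single
aggregated :class:`SchemaError` naming offending rows.
"""

from __future__ import annotations

import pandas as pd

from .simulate import EVENT_TYPES

GPS_COLUMNS = ["participant_id", "timestamp_iso8601_local", "lat_deg", "lon_deg", "accuracy_m"]
ESM_COLUMNS = ["participant_id", "survey_date", "responded", "ideation_1to5", "plan_yn", "attempt_yn"]
EVENT_COLUMNS = ["participant_id", "event_date", "event_type"]
BASELINE_COLUMNS = ["participant_id", "ssi", "site", "sex", "age", "device", "enrollment_date"]


class SchemaError(ValueError):
    """Aggregated validation failure with row references."""

    def __init__(self, path: str, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        more = "" if len(problems) <= 20 else f"\n  ... and {len(problems) - 20} more"
        super().__init__(f"{path}: {len(problems)} validation problem(s):\n  {shown}{more}")


def _require_columns(df: pd.DataFrame, cols: list[str], path: str) -> list[str]:
    missing = [c for c in cols if c not in df.columns]
    return [f"missing column {c!r}" for c in missing]


def read_gps(path: str) -> pd.DataFrame:
    """Read and validate gps.csv -> columns participant_id, t, lat, lon, accuracy."""
    df = pd.read_csv(path)
    problems = _require_columns(df, GPS_COLUMNS[:4], path)
    if problems:
        raise SchemaError(path, problems)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "t": pd.to_datetime(df["timestamp_iso8601_local"], errors="coerce"),
            "lat": pd.to_numeric(df["lat_deg"], errors="coerce"),
            "lon": pd.to_numeric(df["lon_deg"], errors="coerce"),
        }
    )
    if "accuracy_m" in df.columns:
        out["accuracy"] = pd.to_numeric(df["accuracy_m"], errors="coerce")
    for i in out.index[out["t"].isna()][:5]:
        problems.append(f"row {i}: unparseable timestamp {df.at[i, 'timestamp_iso8601_local']!r}")
    bad_lat = out.index[~out["lat"].between(-90, 90) | out["lat"].isna()]
    bad_lon = out.index[~out["lon"].between(-180, 180) | out["lon"].isna()]
    for i in bad_lat[:5]:
        problems.append(f"row {i}: latitude out of bounds ({df.at[i, 'lat_deg']!r})")
    for i in bad_lon[:5]:
        problems.append(f"row {i}: longitude out of bounds ({df.at[i, 'lon_deg']!r})")
    # strictly increasing timestamps within participant
    if not problems:
        for pid, grp in out.groupby("participant_id"):
            dt = grp["t"].diff().dt.total_seconds()
            bad = grp.index[(dt <= 0).fillna(False)]
            for i in bad[:3]:
                problems.append(f"row {i}: timestamp order violation for participant {pid!r}")
    if problems:
        raise SchemaError(path, problems)
    return out


def read_esm(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require_columns(df, ESM_COLUMNS, path)
    if problems:
        raise SchemaError(path, problems)
    dates = pd.to_datetime(df["survey_date"], errors="coerce")
    for i in df.index[dates.isna()][:5]:
        problems.append(f"row {i}: unparseable survey_date {df.at[i, 'survey_date']!r}")
    responded = pd.to_numeric(df["responded"], errors="coerce")
    ideation = pd.to_numeric(df["ideation_1to5"], errors="coerce")
    bad = df.index[(responded == 1) & (~ideation.between(1, 5) | ideation.isna())]
    for i in bad[:5]:
        problems.append(f"row {i}: ideation_1to5 outside 1-5 on a responded row")
    if problems:
        raise SchemaError(path, problems)
    out = df.copy()
    out["survey_date"] = dates
    return out


def read_events(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require_columns(df, EVENT_COLUMNS, path)
    if problems:
        raise SchemaError(path, problems)
    dates = pd.to_datetime(df["event_date"], errors="coerce")
    for i in df.index[dates.isna()][:5]:
        problems.append(f"row {i}: unparseable event_date {df.at[i, 'event_date']!r}")
    bad = df.index[~df["event_type"].isin(EVENT_TYPES)]
    for i in bad[:5]:
        problems.append(
            f"row {i}: unknown event_type {df.at[i, 'event_type']!r}; allowed {list(EVENT_TYPES)}"
        )
    if problems:
        raise SchemaError(path, problems)
    out = df.copy()
    out["event_date"] = dates
    return out


def read_baseline(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = _require_columns(df, BASELINE_COLUMNS, path)
    if problems:
        raise SchemaError(path, problems)
    dates = pd.to_datetime(df["enrollment_date"], errors="coerce")
    for i in df.index[dates.isna()][:5]:
        problems.append(f"row {i}: unparseable enrollment_date")
    if problems:
        raise SchemaError(path, problems)
    out = df.copy()
    out["enrollment_date"] = dates
    return out


def read_inputs(
    gps_path: str, esm_path: str, events_path: str, baseline_path: str
) -> dict[str, pd.DataFrame]:
    """Validate and load the four pipeline inputs."""
    return {
        "gps": read_gps(gps_path),
        "esm": read_esm(esm_path),
        "events": read_events(events_path),
        "baseline": read_baseline(baseline_path),
    }
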