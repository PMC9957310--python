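"""Perceived-exertion survey handling: validation, baseline deltas, and the
end-of-shift CR10 change.

Three instruments are administered at four timepoints (T0 pre-shift, T1 end
of the first work bout, T2 after the rest break, T3 end of shift): the Borg
RPE (6-20, whole body), the Omni RPE (0-10, whole body, pictorial), and the
Borg CR10 (0-10, one rating per shoulder). Analyses use changes from the T0
baseline rather than raw ratings.
"""

from __future__ import annotations

import pandas as pd

from .schedule import PERIODS

REQUIRED_COLUMNS = ["subject_id", "timepoint", "scale", "body_site", "value"]

#: inclusive numeric range per scale; Omni's 0-10 is the standard format and
#: is overridable here if a variant instrument is used
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "BorgRPE": (6.0, 20.0),
    "OmniRPE": (0.0, 10.0),
    "BorgCR10": (0.0, 10.0),
}

OVERALL_SCALES = ("BorgRPE", "OmniRPE")
SHOULDER_SITES = ("left_shoulder", "right_shoulder")


class FormatError(ValueError):
    """Raised when a survey table is missing required columns."""


def validate_responses(
    raw: pd.DataFrame,
    scale_ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a raw survey table; returns (accepted, rejected-with-reason).

    Rejected rows: unknown scale or timepoint, value outside the scale range,
    wrong body site for the scale (whole-body scales must be 'overall', CR10
    must name a shoulder), and duplicate (subject, timepoint, scale, site)
    keys (first occurrence wins).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"survey table missing column(s): {missing}")
    ranges = scale_ranges or SCALE_RANGES
    df = raw[REQUIRED_COLUMNS].copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    reasons = pd.Series("", index=df.index)

    reasons[~df.scale.isin(ranges)] = "unknown scale"
    reasons[(reasons == "") & ~df.timepoint.isin(PERIODS)] = "unknown timepoint"
    ok_site = (
        (df.scale.isin(OVERALL_SCALES) & (df.body_site == "overall"))
        | ((df.scale == "BorgCR10") & df.body_site.isin(SHOULDER_SITES))
    )
    reasons[(reasons == "") & ~ok_site] = "invalid body site for scale"
    lo = df.scale.map(lambda s: ranges.get(s, (0, 0))[0])
    hi = df.scale.map(lambda s: ranges.get(s, (0, 0))[1])
    bad_value = df.value.isna() | (df.value < lo) | (df.value > hi)
    reasons[(reasons == "") & bad_value] = "value out of range"
    dup = df.duplicated(subset=["subject_id", "timepoint", "scale", "body_site"])
    reasons[(reasons == "") & dup] = "duplicate response"

    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""])
    accepted = df[reasons == ""].reset_index(drop=True)
    return accepted, rejected.reset_index(drop=True)


def delta_from_baseline(responses: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rating changes from T0 per (subject, scale, site) at T1-T3.

    Returns (deltas, missing): a (subject, scale, site) lacking its T0 row
    produces one missing-data record instead of silently dropping or zeroing.
    """
    key = ["subject_id", "scale", "body_site"]
    t0 = responses[responses.timepoint == "T0"].set_index(key)["value"]
    later = responses[responses.timepoint.isin(["T1", "T2", "T3"])]
    deltas, missing = [], []
    for (sid, scale, site), sub in later.groupby(key):
        try:
            base = t0.loc[(sid, scale, site)]
        except KeyError:
            missing.append(
                {"subject_id": sid, "scale": scale, "body_site": site,
                 "reason": "no T0 baseline"}
            )
            continue
        for _, r in sub.iterrows():
            deltas.append(
                {
                    "subject_id": sid,
                    "timepoint": r.timepoint,
                    "scale": scale,
                    "body_site": site,
                    "delta": float(r.value - base),
                }
            )
    return pd.DataFrame(deltas), pd.DataFrame(
        missing, columns=["subject_id", "scale", "body_site", "reason"]
    )


def cr10_shift_change(
    responses: pd.DataFrame, roster: pd.DataFrame
) -> pd.DataFrame:
    """End-of-shift CR10 change (T3 minus T0) per subject and shoulder.

    Shoulders are additionally labelled dominant / non-dominant by joining
    the roster's handedness, since the fatigue analysis distinguishes sides
    that way. Missing endpoints yield rows with NaN change and missing=True.
    """
    cr = responses[responses.scale == "BorgCR10"]
    dom = roster.set_index("subject_id")["dominant_side"]
    rows = []
    for sid in roster.subject_id:
        for site in SHOULDER_SITES:
            side = site.replace("_shoulder", "")
            sub = cr[(cr.subject_id == sid) & (cr.body_site == site)]
            v0 = sub.loc[sub.timepoint == "T0", "value"]
            v3 = sub.loc[sub.timepoint == "T3", "value"]
            ok = len(v0) == 1 and len(v3) == 1
            rows.append(
                {
                    "subject_id": sid,
                    "body_site": site,
                    "side": side,
                    "dominance": (
                        "dominant" if side == dom.get(sid) else "non_dominant"
                    ),
                    "cr10_change": float(v3.iloc[0] - v0.iloc[0]) if ok else float("nan"),
                    "missing": not ok,
                }
            )
    return pd.DataFrame(rows)
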