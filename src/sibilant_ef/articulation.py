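"""Per-child articulation profiles.

Each child produces nine tokens of each target sibilant.  A child's
articulation is summarised by the arithmetic mean token centroid per
phoneme and by the differentiation score

    D = mean centroid of [s] - mean centroid of [ʃ]   (Hz),

where a larger D means a crisper acoustic contrast between the two
fricatives.  Transcription accuracy labels, when present, are tallied into
error-rate tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class TokenMeasurement:
    """Centroid (and optional transcription judgement) of one token."""

    child_id: str
    word: str
    phoneme: str  # 's' or 'sh'
    centroid_hz: float
    transcription_correct: bool | None = None


@dataclass(frozen=True)
class ChildProfile:
    """Per-child aggregate articulation measures."""

    child_id: str
    age_days: int
    mean_centroid_s_hz: float
    mean_centroid_sh_hz: float
    differentiation_hz: float
    n_tokens_s: int
    n_tokens_sh: int
    n_errors: int


def child_profiles(
    measurements: list[TokenMeasurement],
    ages: dict[str, int] | pd.DataFrame,
    aggregator: str = "mean",
) -> list[ChildProfile]:
    """Aggregate token centroids into one profile per child.

    ``ages`` maps child_id to age in days (a dict, or a DataFrame with
    ``child_id`` and ``age_days`` columns).  Children missing tokens for
    either phoneme cannot have a differentiation score and are excluded
    with a logged reason.  ``aggregator`` is 'mean' (default) or 'median'.
    """
    if isinstance(ages, pd.DataFrame):
        ages = dict(zip(ages["child_id"].astype(str), ages["age_days"].astype(int)))
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    agg = np.mean if aggregator == "mean" else np.median

    by_child: dict[str, dict[str, list[TokenMeasurement]]] = {}
    for m in measurements:
        by_child.setdefault(m.child_id, {"s": [], "sh": []})[m.phoneme].append(m)

    profiles = []
    for child_id in sorted(by_child):
        tokens = by_child[child_id]
        if not tokens["s"] or not tokens["sh"]:
            missing = "s" if not tokens["s"] else "sh"
            logger.warning(
                "child %s excluded: no [%s] tokens", child_id, missing
            )
            continue
        mean_s = float(agg([t.centroid_hz for t in tokens["s"]]))
        mean_sh = float(agg([t.centroid_hz for t in tokens["sh"]]))
        n_errors = sum(
            1
            for ph in ("s", "sh")
            for t in tokens[ph]
            if t.transcription_correct is False
        )
        profiles.append(
            ChildProfile(
                child_id=child_id,
                age_days=int(ages.get(child_id, -1)),
                mean_centroid_s_hz=mean_s,
                mean_centroid_sh_hz=mean_sh,
                differentiation_hz=mean_s - mean_sh,
                n_tokens_s=len(tokens["s"]),
                n_tokens_sh=len(tokens["sh"]),
                n_errors=n_errors,
            )
        )
    return profiles


def profiles_frame(profiles: list[ChildProfile]) -> pd.DataFrame:
    """Profiles as a tidy DataFrame (one row per child)."""
    return pd.DataFrame(
        {
            "child_id": [p.child_id for p in profiles],
            "age_days": [p.age_days for p in profiles],
            "age_years": [int(p.age_days // DAYS_PER_YEAR) for p in profiles],
            "mean_centroid_s_hz": [p.mean_centroid_s_hz for p in profiles],
            "mean_centroid_sh_hz": [p.mean_centroid_sh_hz for p in profiles],
            "differentiation_hz": [p.differentiation_hz for p in profiles],
            "n_tokens_s": [p.n_tokens_s for p in profiles],
            "n_tokens_sh": [p.n_tokens_sh for p in profiles],
            "n_errors": [p.n_errors for p in profiles],
        }
    )


def group_summary(profiles: list[ChildProfile]) -> pd.DataFrame:
    """Mean ± sample SD of the centroids and differentiation by age year.

    Rows are whole-year age groups (floor of age in days / 365.25); columns
    give n, mean and SD (n-1 denominator) for the [s] centroid, the [ʃ]
    centroid and their difference.  Single-child groups report SD as NaN.
    """
    if not profiles:
        raise ValueError("no profiles to summarise")
    df = profiles_frame(profiles)
    rows = []
    for age, grp in df.groupby("age_years"):
        n = len(grp)
        sd = lambda v: float(np.std(v, ddof=1)) if n > 1 else np.nan
        rows.append(
            {
                "age_years": int(age),
                "n": n,
                "mean_s_hz": float(grp["mean_centroid_s_hz"].mean()),
                "sd_s_hz": sd(grp["mean_centroid_s_hz"]),
                "mean_sh_hz": float(grp["mean_centroid_sh_hz"].mean()),
                "sd_sh_hz": sd(grp["mean_centroid_sh_hz"]),
                "mean_diff_hz": float(grp["differentiation_hz"].mean()),
                "sd_diff_hz": sd(grp["differentiation_hz"]),
            }
        )
    return pd.DataFrame(rows).sort_values("age_years").reset_index(drop=True)


def error_rate_summary(
    measurements: list[TokenMeasurement],
    ages: dict[str, int] | None = None,
) -> dict:
    """Transcription error bookkeeping.

    Percentages use one common denominator — all scored target tokens — so
    the by-phoneme (and by-age, when ages are given) shares sum to the total
    rate before rounding.  Reported to one decimal.
    """
    scored = [m for m in measurements if m.transcription_correct is not None]
    if not scored:
        raise ValueError(
            "no transcription judgements present; cannot compute error rates"
        )
    total_tokens = len(scored)
    errors = [m for m in scored if m.transcription_correct is False]
    total_errors = len(errors)
    pct = lambda k: round(100.0 * k / total_tokens, 1)
    out = {
        "total_errors": total_errors,
        "total_tokens": total_tokens,
        "pct_total": pct(total_errors),
        "pct_by_phoneme": {
            ph: pct(sum(1 for m in errors if m.phoneme == ph)) for ph in ("s", "sh")
        },
    }
    if ages is not None:
        by_age: dict[int, int] = {}
        for m in errors:
            age_y = int(ages[m.child_id] // DAYS_PER_YEAR)
            by_age[age_y] = by_age.get(age_y, 0) + 1
        out["pct_by_age"] = {age: pct(k) for age, k in sorted(by_age.items())}
    return out
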