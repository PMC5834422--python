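"""End-to-end study runs: audio -> centroids -> profiles -> statistics -> tables.

`run_study` executes the whole analysis on either real input files (audio
directory + segment annotations + EF ratings CSV) or an in-memory synthetic
cohort, and writes one CSV per report table:

* ``table2_ef_by_age.csv``       — BRIEF scale means ± SD by age group
* ``table3_centroids.csv``       — centroid means ± SD and differentiation by age
* ``table4_correlations.csv``    — differentiation vs BRIEF scales with BH control
* ``table5_regression_gec_to_diff.csv`` — differentiation ~ GEC (+ age)
* ``table6_regression_diff_to_gec.csv`` — GEC ~ differentiation (+ age)
* ``errors.csv``                 — transcription error rates (when labels exist)

Everything is a pure function of (config, seed): rerunning an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import audio_io, efstats
from .articulation import (
    TokenMeasurement,
    child_profiles,
    error_rate_summary,
    group_summary,
    profiles_frame,
)
from .efstats import BRIEF_SCALES, correlation_table, moderation, ols, read_ef_csv
from .spectral import SpectralConfig, token_centroid
from .synthetic_data import Cohort, CohortSpec, synth_cohort

logger = logging.getLogger(__name__)

ROUND_R = 2       # printed precision of correlations
ROUND_P = 3       # and of p-values / BH thresholds
ROUND_COEF = 2    # and of regression B / SE


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one study run.

    Exactly one of ``audio_dir``+``segments``+``ef_csv`` (real data) or
    ``cohort`` (synthetic) must be provided.
    """

    audio_dir: Path | None = None
    segments: Path | None = None
    ef_csv: Path | None = None
    cohort: CohortSpec | None = None
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    fdr_q: float = 0.05
    out_dir: Path = Path("results")

    def __post_init__(self) -> None:
        real = self.segments is not None
        if real == (self.cohort is not None):
            raise ValueError("provide exactly one of real input paths or a cohort spec")
        if not (0 < self.fdr_q < 1):
            raise ValueError(f"fdr_q must be in (0,1), got {self.fdr_q}")


def measure_real(
    audio_dir: Path, segments_path: Path, config: SpectralConfig
) -> list[TokenMeasurement]:
    """Centroid of every annotated token in a directory of recordings."""
    annotations = audio_io.read_segments_tsv(segments_path)
    # optional transcription column rides along in the same TSV
    correctness = _read_transcription_column(segments_path)
    cache: dict[int, object] = {}
    measurements = []
    waves: dict[str, audio_io.Waveform] = {}
    for k, ann in enumerate(annotations):
        if ann.recording_id not in waves:
            waves[ann.recording_id] = audio_io.read_wav(
                Path(audio_dir) / f"{ann.recording_id}.wav"
            )
        segment = audio_io.extract_segment(waves[ann.recording_id], ann)
        measurements.append(
            TokenMeasurement(
                child_id=ann.child_id,
                word=ann.word,
                phoneme=ann.target_phoneme,
                centroid_hz=token_centroid(segment, config, taper_cache=cache),
                transcription_correct=correctness[k] if correctness else None,
            )
        )
    return measurements


def _read_transcription_column(segments_path: Path) -> list[bool] | None:
    df = pd.read_csv(segments_path, sep="\t")
    if "transcription_correct" not in df.columns:
        return None
    df = df[df["phoneme"].isin(audio_io.TARGET_PHONEMES)]
    return [bool(int(v)) for v in df["transcription_correct"]]


def measure_cohort(cohort: Cohort, config: SpectralConfig) -> list[TokenMeasurement]:
    """Centroid of every synthetic token, without touching the filesystem."""
    cache: dict[int, object] = {}
    return [
        TokenMeasurement(
            child_id=tok.child_id,
            word=tok.word,
            phoneme=tok.phoneme,
            centroid_hz=token_centroid(tok.waveform(), config, taper_cache=cache),
            transcription_correct=tok.transcription_correct,
        )
        for tok in cohort.tokens
    ]


def correlation_frame(results) -> pd.DataFrame:
    """Correlation rows rounded to report precision (r: 2 dp, p/BH: 3 dp)."""
    return pd.DataFrame(
        {
            "variable": [c.variable for c in results],
            "r": [round(c.r, ROUND_R) for c in results],
            "p": [round(c.p, ROUND_P) for c in results],
            "n": [c.n for c in results],
            "rank": [c.rank_i for c in results],
            "bh_critical": [round(c.bh_critical, ROUND_P) for c in results],
            "passes_fdr": [c.passes_fdr for c in results],
            "adjusted_p": [round(c.adjusted_p, ROUND_P) for c in results],
        }
    )


def regression_frame(model1, model2) -> pd.DataFrame:
    """Two nested models as one report table in printed precision."""
    rows = []
    for model_name, res in (("model1", model1), ("model2", model2)):
        for term in res.terms:
            rows.append(
                {
                    "model": model_name,
                    "term": term.name,
                    "B": round(term.b, ROUND_COEF),
                    "SE": round(term.se, ROUND_COEF),
                    "beta": round(term.beta, ROUND_R),
                    "t": round(term.t, ROUND_COEF),
                    "p": round(term.p, ROUND_P),
                    "F": round(res.f, 1),
                    "df1": res.df1,
                    "df2": res.df2,
                    "r_squared": round(res.r_squared, ROUND_P),
                    "adj_r_squared": round(res.adj_r_squared, ROUND_P),
                }
            )
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> dict:
    """Run the full analysis chain and write the report bundle.

    Returns a dict with the in-memory results (profiles DataFrame,
    correlation results, regression results, error summary) plus the paths
    written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        cohort = synth_cohort(config.cohort)
        measurements = measure_cohort(cohort, config.spectral)
        ef_df = cohort.ef_ratings
    else:
        measurements = measure_real(config.audio_dir, config.segments, config.spectral)
        ef_df = read_ef_csv(config.ef_csv)

    ages = dict(zip(ef_df["child_id"].astype(str), ef_df["age_days"].astype(int)))
    profiles = child_profiles(measurements, ages)
    prof_df = profiles_frame(profiles)

    tables: dict[str, pd.DataFrame] = {}
    tables["table2_ef_by_age"] = efstats.ef_group_summary(ef_df)
    t3 = group_summary(profiles).round(1)
    tables["table3_centroids"] = t3

    corr = correlation_table(prof_df, ef_df, q=config.fdr_q)
    tables["table4_correlations"] = correlation_frame(corr)

    merged = prof_df[["child_id", "differentiation_hz"]].merge(ef_df, on="child_id")
    diff = merged["differentiation_hz"].to_numpy()
    gec = merged["gec"].to_numpy()
    age = merged["age_days"].to_numpy(dtype=float)

    reg1_m1 = ols(diff, pd.DataFrame({"gec": gec}))
    reg1_m2 = ols(diff, pd.DataFrame({"gec": gec, "age_days": age}))
    mod1 = moderation(diff, gec, age, names=("gec", "age_days"))
    tables["table5_regression_gec_to_diff"] = regression_frame(reg1_m1, reg1_m2)

    reg2_m1 = ols(gec, pd.DataFrame({"diff_hz": diff}))
    reg2_m2 = ols(gec, pd.DataFrame({"diff_hz": diff, "age_days": age}))
    mod2 = moderation(gec, diff, age, names=("diff_hz", "age_days"))
    tables["table6_regression_diff_to_gec"] = regression_frame(reg2_m1, reg2_m2)

    errors = None
    if any(m.transcription_correct is not None for m in measurements):
        errors = error_rate_summary(
            [m for m in measurements if m.transcription_correct is not None], ages
        )
        err_df = pd.DataFrame(
            [
                {"quantity": "total_errors", "value": errors["total_errors"]},
                {"quantity": "total_tokens", "value": errors["total_tokens"]},
                {"quantity": "pct_total", "value": errors["pct_total"]},
                {"quantity": "pct_s", "value": errors["pct_by_phoneme"]["s"]},
                {"quantity": "pct_sh", "value": errors["pct_by_phoneme"]["sh"]},
            ]
            + [
                {"quantity": f"pct_age_{a}", "value": v}
                for a, v in errors.get("pct_by_age", {}).items()
            ]
        )
        tables["errors"] = err_df

    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    run_log = {
        "spectral": asdict(config.spectral),
        "fdr_q": config.fdr_q,
        "n_children": len(profiles),
        "n_tokens": len(measurements),
        "cohort": asdict(config.cohort) if config.cohort is not None else None,
        "rounding": {"r": ROUND_R, "p": ROUND_P, "coef": ROUND_COEF},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    return {
        "profiles": prof_df,
        "correlations": corr,
        "regressions": {
            "diff_on_gec": (reg1_m1, reg1_m2, mod1),
            "gec_on_diff": (reg2_m1, reg2_m2, mod2),
        },
        "errors": errors,
        "tables": tables,
        "paths": paths,
    }
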