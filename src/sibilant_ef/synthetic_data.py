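"""Synthetic fricative tokens and child cohorts.

No recordings are distributed with the study design this package analyses,
so every pipeline stage is exercised on synthetic data with analytically
known structure:

* a *token* is white Gaussian noise shaped in the frequency domain by a
  spectral envelope (Gaussian bump or flat band) whose power-weighted
  centroid is computable in closed form or by quadrature, making the
  centroid estimator testable against an analytic oracle;
* a *cohort* draws per-child latent target centroids for [s] and [ʃ],
  jitters them per token, and generates BRIEF-style Global Executive
  Composite t-scores as a linear mix of the standardised latent
  differentiation and independent noise, so the population correlation
  between true differentiation and GEC equals ``rho_ef`` exactly.

All randomness descends from the single cohort seed through
``numpy.random.SeedSequence`` spawning (one child stream per child, one
token stream per token), so an identical spec reproduces identical bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import Waveform, write_wav
from .efstats import BRIEF_SCALES

#: the nine [s]- and nine [ʃ]-initial target words of the repetition task
S_WORDS = ("sick", "sit", "silly", "salad", "salmon", "sandwich", "sun", "sucker", "subway")
SH_WORDS = ("ship", "shin", "shiver", "shadow", "shallow", "shack", "shuffle", "shut", "shovel")

_PEAK = 0.9  # peak normalisation target; leaves headroom for 16-bit PCM


@dataclass(frozen=True)
class EnvelopeSpec:
    """Spectral amplitude envelope of a synthetic fricative.

    shape 'gaussian': E(f) = exp(-(f - center)² / (2·width²)), truncated to
    ``band_hz``.  shape 'flat_band': E(f) = 1 on ``band_hz``, 0 outside
    (center/width unused).  The realised *power* spectrum follows E(f)², so
    the analytic centroid integrates f·E² over the band.
    """

    shape: str
    center_hz: float = 0.0
    width_hz: float = 0.0
    band_hz: tuple[float, float] = (0.0, 22050.0)

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "flat_band"):
            raise ValueError(f"unknown envelope shape {self.shape!r}")
        low, high = self.band_hz
        if not (0 <= low < high):
            raise ValueError(f"invalid band {self.band_hz}")
        if self.shape == "gaussian":
            if not (low <= self.center_hz <= high):
                raise ValueError("center_hz must lie within band_hz")
            if self.width_hz <= 0:
                raise ValueError("width_hz must be > 0")

    def amplitude(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Envelope amplitude sampled on a frequency grid."""
        low, high = self.band_hz
        in_band = (freqs_hz >= low) & (freqs_hz <= high)
        if self.shape == "flat_band":
            return in_band.astype(float)
        env = np.exp(-((freqs_hz - self.center_hz) ** 2) / (2 * self.width_hz**2))
        return np.where(in_band, env, 0.0)

    def analytic_centroid_hz(self, n_grid: int = 20001) -> float:
        """Power-weighted mean frequency ∫f·E(f)²df / ∫E(f)²df over the band."""
        low, high = self.band_hz
        if self.shape == "flat_band":
            return 0.5 * (low + high)
        f = np.linspace(low, high, n_grid)
        w = self.amplitude(f) ** 2
        return float(np.trapezoid(f * w, f) / np.trapezoid(w, f))


def synth_fricative(
    duration_s: float,
    sample_rate_hz: int,
    envelope: EnvelopeSpec,
    seed: int | np.random.Generator,
) -> Waveform:
    """Fricative-like noise with the given spectral envelope.

    White Gaussian noise is shaped in the frequency domain by the envelope
    magnitude, transformed back, and peak-normalised to 0.9.  The same seed
    always yields bit-identical samples.
    """
    if duration_s < 0.05:
        raise ValueError(f"duration must be >= 50 ms, got {duration_s * 1e3:.0f} ms")
    nyquist = sample_rate_hz / 2.0
    if envelope.band_hz[1] > nyquist:
        raise ValueError(
            f"envelope band {envelope.band_hz} exceeds Nyquist {nyquist:.0f} Hz"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * sample_rate_hz))
    noise = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    shaped = np.fft.irfft(np.fft.rfft(noise) * envelope.amplitude(freqs), n=n)
    peak = np.max(np.abs(shaped))
    if peak == 0:
        raise ValueError("envelope produced a silent signal")
    return Waveform(samples=shaped * (_PEAK / peak), sample_rate_hz=sample_rate_hz)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated child cohort.

    Defaults describe a cohort on the scale of the study design this
    package targets: 31 analysable children aged 4-6 years, nine tokens per
    sibilant, population mean centroids near 7.4 kHz for [s] and 5.1 kHz
    for [ʃ], between-child SD 900 Hz, within-child token SD 400 Hz, and a
    latent differentiation-GEC correlation of -0.56 on the t-score scale
    (mean 50, SD 10; lower = better executive function).
    """

    n_children: int = 31
    age_range_days: tuple[int, int] = (1461, 2556)  # 4.0 to <7.0 years
    mu_s_hz: float = 7400.0
    mu_sh_hz: float = 5100.0
    sd_between_hz: float = 900.0
    sd_within_hz: float = 400.0
    tokens_per_phoneme: int = 9
    rho_ef: float = -0.56
    gec_mean: float = 50.0
    gec_sd: float = 10.0
    subscale_noise_sd: float = 5.0
    envelope_width_hz: float = 800.0
    token_duration_s: tuple[float, float] = (0.10, 0.18)
    sample_rate_hz: int = 44100
    error_rate_sh: float = 0.17   # per-token mistranscription probability, [ʃ]
    error_rate_s: float = 0.02    # and [s]; both modulated by articulation skill
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tokens_per_phoneme < 1:
            raise ValueError("tokens_per_phoneme must be >= 1")
        if abs(self.rho_ef) >= 1:
            raise ValueError("|rho_ef| must be < 1")
        if min(self.sd_between_hz, self.sd_within_hz) < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class SyntheticToken:
    """Metadata of one synthetic token; audio is regenerated on demand."""

    child_id: str
    word: str
    phoneme: str
    envelope: EnvelopeSpec
    duration_s: float
    sample_rate_hz: int
    token_seed: int
    transcription_correct: bool

    def waveform(self) -> Waveform:
        return synth_fricative(
            self.duration_s, self.sample_rate_hz, self.envelope, self.token_seed
        )


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: tokens, EF ratings, and the latent truth table."""

    spec: CohortSpec
    tokens: tuple[SyntheticToken, ...]
    ef_ratings: pd.DataFrame   # child_id, version, age_days, six t-score scales
    truth: pd.DataFrame        # child_id, true_s_hz, true_sh_hz, true_diff_hz, true_gec, age_days


def _child_words(spec: CohortSpec) -> list[tuple[str, str]]:
    words = []
    for k in range(spec.tokens_per_phoneme):
        words.append(("s", S_WORDS[k % len(S_WORDS)]))
        words.append(("sh", SH_WORDS[k % len(SH_WORDS)]))
    return words


def synth_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort under ``spec``.

    Latent structure: per child, target centroids c_s ~ N(mu_s, sd_between²)
    and c_sh ~ N(mu_sh, sd_between²); true differentiation Δ = c_s - c_sh.
    GEC t-score = gec_mean + gec_sd·(ρ·z + sqrt(1-ρ²)·ε) with
    z = (Δ - (mu_s - mu_sh)) / (sqrt(2)·sd_between) and ε ~ N(0,1), so the
    population correlation of (Δ, GEC) is exactly ρ = rho_ef.  Subscales
    add independent noise to the GEC.  Per token, the envelope centre is
    the child's target jittered by N(0, sd_within²).
    """
    root = np.random.SeedSequence(spec.seed)
    nyquist = spec.sample_rate_hz / 2.0
    if spec.mu_s_hz + 4 * spec.sd_between_hz > nyquist:
        raise ValueError("mu_s_hz too close to Nyquist for the cohort spread")
    noise_floor = np.sqrt(1 - spec.rho_ef**2)
    child_seqs = root.spawn(spec.n_children)
    delta_pop_sd = np.sqrt(2.0) * spec.sd_between_hz

    tokens: list[SyntheticToken] = []
    ef_rows, truth_rows = [], []
    width = len(str(spec.n_children))
    for i, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        child_id = f"c{i + 1:0{width}d}"
        age_days = int(rng.integers(spec.age_range_days[0], spec.age_range_days[1] + 1))
        c_s = spec.mu_s_hz + spec.sd_between_hz * rng.standard_normal()
        c_sh = spec.mu_sh_hz + spec.sd_between_hz * rng.standard_normal()
        delta = c_s - c_sh
        z = (delta - (spec.mu_s_hz - spec.mu_sh_hz)) / delta_pop_sd if delta_pop_sd > 0 else 0.0
        gec = spec.gec_mean + spec.gec_sd * (
            spec.rho_ef * z + noise_floor * rng.standard_normal()
        )
        gec = float(np.clip(gec, 20.0, 120.0))
        ef_row = {
            "child_id": child_id,
            "version": "BRIEF-P" if age_days < int(5.5 * 365.25) else "BRIEF",
            "age_days": age_days,
        }
        for scale in BRIEF_SCALES:
            if scale == "gec":
                ef_row[scale] = round(gec, 1)
            else:
                sub = gec + spec.subscale_noise_sd * rng.standard_normal()
                ef_row[scale] = round(float(np.clip(sub, 20.0, 120.0)), 1)
        ef_rows.append(ef_row)
        truth_rows.append(
            {
                "child_id": child_id,
                "true_s_hz": c_s,
                "true_sh_hz": c_sh,
                "true_diff_hz": delta,
                "true_gec": gec,
                "age_days": age_days,
            }
        )
        # articulation skill shifts mistranscription odds: well-separated
        # children (z > 0) make fewer errors
        skill = float(np.clip(1.0 - 0.5 * z, 0.05, 2.0))
        token_seqs = seq.spawn(2 * spec.tokens_per_phoneme)
        for (phoneme, word), tok_seq in zip(_child_words(spec), token_seqs):
            target = c_s if phoneme == "s" else c_sh
            center = target + spec.sd_within_hz * rng.standard_normal()
            center = float(np.clip(center, 600.0 + 3 * spec.envelope_width_hz, nyquist - 100.0))
            duration = float(rng.uniform(*spec.token_duration_s))
            p_err = (spec.error_rate_s if phoneme == "s" else spec.error_rate_sh) * skill
            correct = bool(rng.uniform() >= min(p_err, 1.0))
            tokens.append(
                SyntheticToken(
                    child_id=child_id,
                    word=word,
                    phoneme=phoneme,
                    envelope=EnvelopeSpec(
                        shape="gaussian",
                        center_hz=center,
                        width_hz=spec.envelope_width_hz,
                        band_hz=(100.0, nyquist),
                    ),
                    duration_s=duration,
                    sample_rate_hz=spec.sample_rate_hz,
                    token_seed=int(tok_seq.generate_state(1)[0] % (2**31)),
                    transcription_correct=correct,
                )
            )
    return Cohort(
        spec=spec,
        tokens=tuple(tokens),
        ef_ratings=pd.DataFrame(ef_rows),
        truth=pd.DataFrame(truth_rows),
    )


def write_fixture(cohort: Cohort, out_dir: str | Path, gap_s: float = 0.05) -> dict[str, Path]:
    """Write a cohort to disk in the formats the analysis pipeline reads.

    One WAV per child (tokens separated by silence), ``segments.tsv`` with
    the token annotations (including per-token transcription judgements in
    an extra column), ``ef_ratings.csv`` and ``truth.csv``.
    """
    out = Path(out_dir)
    audio_dir = out / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    fs = cohort.spec.sample_rate_hz
    gap = int(round(gap_s * fs))

    seg_rows = []
    by_child: dict[str, list[SyntheticToken]] = {}
    for tok in cohort.tokens:
        by_child.setdefault(tok.child_id, []).append(tok)
    for child_id, toks in by_child.items():
        pieces, cursor = [], gap
        pieces.append(np.zeros(gap))
        for tok in toks:
            w = tok.waveform()
            start_s = cursor / fs
            end_s = (cursor + len(w)) / fs
            seg_rows.append(
                (child_id, child_id, tok.word, tok.phoneme,
                 f"{start_s:.6f}", f"{end_s:.6f}",
                 "1" if tok.transcription_correct else "0")
            )
            pieces.append(w.samples)
            pieces.append(np.zeros(gap))
            cursor += len(w) + gap
        write_wav(audio_dir / f"{child_id}.wav",
                  Waveform(np.concatenate(pieces), fs))

    segments_path = out / "segments.tsv"
    with open(segments_path, "w", encoding="utf-8") as fh:
        fh.write("recording_id\tchild_id\tword\tphoneme\tstart_s\tend_s\ttranscription_correct\n")
        for row in seg_rows:
            fh.write("\t".join(row) + "\n")

    ef_path = out / "ef_ratings.csv"
    cohort.ef_ratings.to_csv(ef_path, index=False)
    truth_path = out / "truth.csv"
    cohort.truth.to_csv(truth_path, index=False)
    return {
        "audio_dir": audio_dir,
        "segments": segments_path,
        "ef_csv": ef_path,
        "truth": truth_path,
    }
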