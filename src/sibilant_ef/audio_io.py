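"""Audio and annotation input/output.

Recordings are mono PCM WAV files (the study microphone chain recorded at
44,100 Hz, but any positive sample rate is carried through the analysis).
Fricative tokens are located by hand-placed interval annotations — either a
plain TSV table or a Praat TextGrid interval tier — that tie each [s]/[ʃ]
token to a child, a word and a time span.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Phonemes the analysis targets.  Everything else in an annotation file is
#: treated as filler material and skipped (the word lists interleave 35
#: filler words with the 18 sibilant-initial targets).
TARGET_PHONEMES = ("s", "sh")

_PCM16_SCALE = 32768.0  # 2**15


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes in [-1, 1] (PCM-normalised).
    sample_rate_hz : int
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(
                f"Waveform must be single-channel 1-D, got shape {samples.shape}"
            )
        if samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SegmentAnnotation:
    """A labelled token interval within one recording."""

    recording_id: str
    child_id: str
    word: str
    target_phoneme: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.target_phoneme not in TARGET_PHONEMES:
            raise ValueError(
                f"target_phoneme must be one of {TARGET_PHONEMES}, "
                f"got {self.target_phoneme!r}"
            )
        if not (0.0 <= self.start_s < self.end_s):
            raise ValueError(
                f"require 0 <= start_s < end_s, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_wav(path: str | Path) -> Waveform:
    """Read a mono 16-bit PCM WAV file into a normalised :class:`Waveform`.

    Multichannel files are rejected rather than silently downmixed (mixing
    would distort the fricative spectrum); non-PCM encodings are rejected.
    """
    path = Path(path)
    with wave.open(str(path), "rb") as wf:
        n_channels = wf.getnchannels()
        if n_channels != 1:
            raise ValueError(
                f"{path.name}: expected mono audio, got {n_channels} channels; "
                "refusing to downmix"
            )
        sampwidth = wf.getsampwidth()
        comptype = wf.getcomptype()
        if comptype != "NONE":
            raise ValueError(
                f"{path.name}: expected PCM encoding, got compression {comptype!r}"
            )
        if sampwidth != 2:
            raise ValueError(
                f"{path.name}: expected 16-bit PCM, got {8 * sampwidth}-bit"
            )
        rate = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(np.float64) / _PCM16_SCALE
    return Waveform(samples=samples, sample_rate_hz=rate)


def write_wav(path: str | Path, waveform: Waveform) -> None:
    """Write a :class:`Waveform` as mono 16-bit PCM.

    Samples must already lie in [-1, 1]; out-of-range input is an error so
    that clipping never happens silently.
    """
    samples = waveform.samples
    if np.max(np.abs(samples)) > 1.0:
        raise ValueError(
            f"samples out of range [-1, 1] (max |x| = {np.max(np.abs(samples)):.4f}); "
            "normalise before writing"
        )
    quantised = np.clip(np.round(samples * _PCM16_SCALE), -32768, 32767).astype("<i2")
    with wave.open(str(Path(path)), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(waveform.sample_rate_hz)
        wf.writeframes(quantised.tobytes())


def read_segments_tsv(
    path: str | Path,
    filler_phonemes: frozenset[str] | set[str] | None = None,
) -> list[SegmentAnnotation]:
    """Read token annotations from a UTF-8 TSV file.

    Required header: ``recording_id  child_id  word  phoneme  start_s  end_s``.
    Rows whose phoneme is in ``filler_phonemes`` are skipped with a logged
    count; any other non-target phoneme is an error (it usually signals a
    typo in hand-made annotations).  By default every non-target label is
    treated as filler.
    """
    path = Path(path)
    required = ["recording_id", "child_id", "word", "phoneme", "start_s", "end_s"]
    annotations: list[SegmentAnnotation] = []
    n_filler = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path.name}: missing TSV columns {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            phoneme = fields[idx["phoneme"]].strip()
            if phoneme not in TARGET_PHONEMES:
                if filler_phonemes is None or phoneme in filler_phonemes:
                    n_filler += 1
                    continue
                raise ValueError(
                    f"{path.name} line {lineno}: unknown phoneme {phoneme!r} "
                    f"(not a target or declared filler)"
                )
            try:
                start = float(fields[idx["start_s"]])
                end = float(fields[idx["end_s"]])
            except ValueError as exc:
                raise ValueError(f"{path.name} line {lineno}: bad time value") from exc
            if not (0.0 <= start < end):
                raise ValueError(
                    f"{path.name} line {lineno}: invalid interval "
                    f"[{start}, {end}] (need 0 <= start < end)"
                )
            annotations.append(
                SegmentAnnotation(
                    recording_id=fields[idx["recording_id"]].strip(),
                    child_id=fields[idx["child_id"]].strip(),
                    word=fields[idx["word"]].strip(),
                    target_phoneme=phoneme,
                    start_s=start,
                    end_s=end,
                )
            )
    if n_filler:
        logger.info("%s: skipped %d filler-word rows", path.name, n_filler)
    return annotations


# ---------------------------------------------------------------------------
# Praat TextGrid interval tiers (long and short text formats)
# ---------------------------------------------------------------------------

def _read_textgrid_text(path: Path) -> str:
    raw = path.read_bytes()
    if raw[:2] in (b"\xff\xfe", b"\xfe\xff"):  # Praat writes UTF-16 by default
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


def _parse_textgrid(text: str) -> dict[str, list[tuple[float, float, str]]]:
    """Parse interval tiers out of a TextGrid (long or short text format).

    Returns {tier_name: [(xmin, xmax, label), ...]}.  The two dialects carry
    the same token stream (numbers and quoted strings) in the same order, so
    both are handled by one token-level scan.
    """
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == '"':
            j = i + 1
            buf = []
            while j < n:
                if text[j] == '"':
                    if j + 1 < n and text[j + 1] == '"':  # escaped quote
                        buf.append('"')
                        j += 2
                        continue
                    break
                buf.append(text[j])
                j += 1
            tokens.append('"' + "".join(buf))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] != '"':
                j += 1
            word = text[i:j]
            # long format lines like "xmin = 0.35": keep only the value side
            tokens.append(word)
            i = j
    # Keep only quoted strings and numbers; structural keywords are dropped.
    stream: list[str] = []
    for tok in tokens:
        if tok.startswith('"'):
            stream.append(tok)
        else:
            try:
                float(tok)
            except ValueError:
                continue
            stream.append(tok)

    def is_str(tok: str) -> bool:
        return tok.startswith('"')

    if len(stream) < 3 or not is_str(stream[0]):
        raise ValueError("not a recognisable TextGrid file")
    # stream: "ooTextFile" "TextGrid" xmin xmax [size] then per tier:
    #   "IntervalTier" name xmin xmax n (xmin xmax "label")*n
    pos = 2
    floats_before_tiers = []
    while pos < len(stream) and not is_str(stream[pos]):
        floats_before_tiers.append(stream[pos])
        pos += 1
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    while pos < len(stream):
        tier_class = stream[pos][1:]
        pos += 1
        if pos >= len(stream) or not is_str(stream[pos]):
            raise ValueError("malformed TextGrid: tier name missing")
        tier_name = stream[pos][1:]
        pos += 1
        nums = []
        while pos < len(stream) and not is_str(stream[pos]) and len(nums) < 3:
            nums.append(float(stream[pos]))
            pos += 1
        if len(nums) < 3:
            raise ValueError(f"malformed TextGrid tier {tier_name!r}")
        n_items = int(nums[2])
        intervals: list[tuple[float, float, str]] = []
        if tier_class == "IntervalTier":
            for _ in range(n_items):
                xmin = float(stream[pos]); pos += 1
                xmax = float(stream[pos]); pos += 1
                label = stream[pos][1:]; pos += 1
                intervals.append((xmin, xmax, label))
            tiers[tier_name] = intervals
        else:  # TextTier (points): number "mark" pairs — skip
            for _ in range(n_items):
                pos += 2
    return tiers


def read_textgrid_intervals(
    path: str | Path,
    tier_name: str,
    *,
    recording_id: str | None = None,
    child_id: str = "",
    label_map: dict[str, tuple[str, str]] | None = None,
) -> list[SegmentAnnotation]:
    """Read one interval tier of a Praat TextGrid as annotations.

    Empty-label intervals (silences between tokens) are excluded.  Labels are
    mapped to (word, phoneme) by ``label_map``; without a map the label is
    used as both the word and — lowercased — the phoneme, which matches tiers
    labelled directly ``s`` / ``sh``.  Non-target labels without a mapping
    are skipped as filler.
    """
    path = Path(path)
    tiers = _parse_textgrid(_read_textgrid_text(path))
    if tier_name not in tiers:
        raise ValueError(
            f"{path.name}: no interval tier {tier_name!r}; "
            f"available tiers: {sorted(tiers)}"
        )
    rec = recording_id if recording_id is not None else path.stem
    annotations = []
    for xmin, xmax, label in tiers[tier_name]:
        label = label.strip()
        if not label:
            continue
        if label_map is not None and label in label_map:
            word, phoneme = label_map[label]
        else:
            word, phoneme = label, label.lower()
        if phoneme not in TARGET_PHONEMES:
            continue
        annotations.append(
            SegmentAnnotation(
                recording_id=rec,
                child_id=child_id,
                word=word,
                target_phoneme=phoneme,
                start_s=xmin,
                end_s=xmax,
            )
        )
    return annotations


def extract_segment(waveform: Waveform, annotation: SegmentAnnotation) -> Waveform:
    """Cut one annotated token out of a recording.

    Sample indices follow round(t * fs) with a half-open interval
    [start, end), so abutting annotations never share a sample.
    """
    fs = waveform.sample_rate_hz
    if annotation.end_s > waveform.duration_s + 0.5 / fs:
        raise ValueError(
            f"annotation [{annotation.start_s}, {annotation.end_s}] s extends "
            f"beyond the recording ({waveform.duration_s:.3f} s)"
        )
    i0 = int(round(annotation.start_s * fs))
    i1 = int(round(annotation.end_s * fs))
    i1 = min(i1, waveform.samples.size)
    if i1 <= i0:
        raise ValueError(
            f"annotation [{annotation.start_s}, {annotation.end_s}] s is empty "
            f"after rounding at {fs} Hz"
        )
    return Waveform(samples=waveform.samples[i0:i1].copy(), sample_rate_hz=fs)
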