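"""Reading and writing recordings, event tables, channel metadata and n-grams.

Formats
-------
* signals: EDF (16-bit, one data record per second) or an internal raw
  float32 container with a JSON sidecar;
* events: tab-separated table with columns ``sentence_id``, ``condition``
  and the four anchor-onset columns (seconds, relative to recording start);
* channels: TSV with ``name``, ``hemisphere`` (DH/NDH), ``lobe``, ``gyrus``,
  ``tissue`` (grey/white), ``bad`` (0/1);
* n-grams: TSV with ``token_1``, ``token_2`` (empty for a unigram) and
  ``count``; duplicate keys are summed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ANCHOR_COLUMNS, ChannelInfo, Recording, validate_events

_CHANNEL_COLUMNS = ("name", "hemisphere", "lobe", "gyrus", "tissue", "bad")


@dataclass
class NgramTable:
    """Unigram and bigram counts; lookups default to 0 (missing)."""

    unigrams: dict[str, int] = field(default_factory=dict)
    bigrams: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.unigrams.items():
            if v < 0:
                raise ValueError(f"negative unigram count for {k!r}")
        for k, v in self.bigrams.items():
            if v < 0:
                raise ValueError(f"negative bigram count for {k!r}")

    def unigram(self, token: str) -> int:
        return self.unigrams.get(token, 0)

    def bigram(self, first: str, second: str) -> int:
        return self.bigrams.get((first, second), 0)


def read_ngrams(path: str | Path) -> NgramTable:
    """Parse an n-gram TSV; malformed rows raise with their line number."""
    unigrams: dict[str, int] = {}
    bigrams: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("token_1")):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"line {lineno}: expected 2 or 3 tab-separated fields")
            try:
                count = int(parts[-1])
            except ValueError:
                raise ValueError(f"line {lineno}: count {parts[-1]!r} is not an integer") from None
            if count < 0:
                raise ValueError(f"line {lineno}: negative count {count}")
            token_2 = parts[1] if len(parts) == 3 else ""
            if token_2 == "":
                unigrams[parts[0]] = unigrams.get(parts[0], 0) + count
            else:
                key = (parts[0], token_2)
                bigrams[key] = bigrams.get(key, 0) + count
    return NgramTable(unigrams=unigrams, bigrams=bigrams)


def write_ngrams(table: NgramTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("token_1\ttoken_2\tcount\n")
        for tok, count in table.unigrams.items():
            fh.write(f"{tok}\t\t{count}\n")
        for (a, b), count in table.bigrams.items():
            fh.write(f"{a}\t{b}\t{count}\n")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events)
    cols = ["sentence_id", "condition", *ANCHOR_COLUMNS]
    events[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return validate_events(events)


def write_channels(channels: list[ChannelInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": c.name, "hemisphere": c.hemisphere, "lobe": c.lobe,
             "gyrus": c.gyrus, "tissue": c.tissue, "bad": int(c.bad)}
            for c in channels
        ]
    ).to_csv(path, sep="\t", index=False)


def read_channels(path: str | Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in _CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    return [
        ChannelInfo(
            name=str(r["name"]), hemisphere=str(r["hemisphere"]), lobe=str(r["lobe"]),
            gyrus=str(r["gyrus"]), tissue=str(r["tissue"]), bad=bool(int(r["bad"])),
        )
        for _, r in df.iterrows()
    ]


def channels_frame(channels: list[ChannelInfo]) -> pd.DataFrame:
    """Channel metadata as a DataFrame (the census input)."""
    return pd.DataFrame(
        [
            {"name": c.name, "hemisphere": c.hemisphere, "lobe": c.lobe,
             "gyrus": c.gyrus, "tissue": c.tissue, "bad": c.bad}
            for c in channels
        ]
    )


# ---------------------------------------------------------------------------
# signal containers
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording; ``.edf`` suffix selects EDF, otherwise the internal
    raw-float32 + JSON-sidecar container is used."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        from .edf import write_edf

        write_edf(rec, path)
        return
    data = np.ascontiguousarray(rec.data, dtype=np.float32)
    data.tofile(path)
    sidecar = {
        "format": "seegphrase-raw-f32",
        "fs": rec.fs,
        "start_time": rec.start_time,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "unit": "uV",
        "channel_names": rec.channel_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, channels: list[ChannelInfo]) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf_mne(path, channels)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if sidecar.get("format") != "seegphrase-raw-f32":
        raise ValueError(f"{path}: unrecognized sidecar format")
    data = np.fromfile(path, dtype=np.float32).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    _check_names(sidecar["channel_names"], channels)
    return Recording(
        data=data, fs=float(sidecar["fs"]), channels=channels,
        start_time=float(sidecar["start_time"]),
    )


def _read_edf_mne(path: Path, channels: list[ChannelInfo]) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    _check_names(list(raw.ch_names), channels)
    data_uv = raw.get_data() * 1e6  # MNE returns volts for uV-dimensioned channels
    return Recording(
        data=data_uv, fs=float(raw.info["sfreq"]), channels=channels, start_time=0.0
    )


def _check_names(signal_names: list[str], channels: list[ChannelInfo]) -> None:
    meta_names = [c.name for c in channels]
    if signal_names != meta_names:
        only_signal = sorted(set(signal_names) - set(meta_names))
        only_meta = sorted(set(meta_names) - set(signal_names))
        raise ValueError(
            "channel names in signal file and metadata do not match: "
            f"signal-only {only_signal}, metadata-only {only_meta}"
        )


def read_session(
    signal_path: str | Path, events_path: str | Path, channels_path: str | Path
) -> tuple[Recording, pd.DataFrame]:
    """Assemble a session: recording with channel metadata, plus events.

    Bad channels are flagged, never dropped; all onsets are validated
    (strictly increasing anchors, known condition labels).
    """
    channels = read_channels(channels_path)
    rec = read_recording(signal_path, channels)
    events = read_events(events_path)
    return rec, events
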