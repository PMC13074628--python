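"""Raw four-channel voltage frames to corrected far/close spatial ratios.

The chain is: dark subtraction (removes additive offsets), PTFE reference
normalization (suppresses per-channel multiplicative gains), and formation
of the same-wavelength far/close ratio.  Channels with non-positive raw
signals are flagged low-SNR and the affected wavelength excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Mapping

import pandas as pd

from .constants import CHANNEL_MAP, channel_for
from .errors import LowSNRError, ParseError, ReferenceInvalidError

ROLES = ("sample", "reference")


@dataclass(frozen=True)
class ChannelReading:
    v_on: float
    v_dark: float


@dataclass
class MeasurementFrame:
    """One four-channel acquisition (LED-on and LED-off voltages)."""

    role: str
    readings: dict[str, ChannelReading]
    n_averaged: int = 1

    def __post_init__(self):
        if self.role not in ROLES:
            raise ParseError(f"frame role must be one of {ROLES}, got {self.role!r}")
        missing = set(CHANNEL_MAP) - set(self.readings)
        if missing:
            raise ParseError(f"frame missing channels: {sorted(missing)}")
        for ch, rd in self.readings.items():
            if not (abs(rd.v_on) < float("inf") and abs(rd.v_dark) < float("inf")):
                raise ParseError(f"non-finite voltage on {ch}")


@dataclass
class CorrectedRatios:
    r_corr: dict[int, float]
    excluded: dict[int, str] = field(default_factory=dict)


def dark_subtract(frame: MeasurementFrame) -> dict[str, float]:
    """Per-channel S_raw = v_on - v_dark.  May be <= 0 (flagged downstream)."""
    return {ch: rd.v_on - rd.v_dark for ch, rd in frame.readings.items()}


def normalize_to_reference(sample_s: float, reference_s: float) -> float:
    """S_norm = S_raw(sample) / S_raw(reference)."""
    if reference_s <= 0:
        raise ReferenceInvalidError(
            f"reference signal must be positive, got {reference_s}")
    return sample_s / reference_s


def corrected_ratio(frame_sample: MeasurementFrame,
                    frame_reference: MeasurementFrame, wavelength: int,
                    channel_map: Mapping[str, tuple[int, str]] = CHANNEL_MAP) -> float:
    """Corrected same-wavelength spatial ratio:

        r_corr = (S_far,sample / S_close,sample) * (S_close,ref / S_far,ref)

    Any non-positive raw value among the four terms excludes the wavelength
    (raises :class:`LowSNRError`).  Per-channel gains applied identically to
    sample and reference cancel exactly.
    """
    ch_far = channel_for(wavelength, "far", channel_map)
    ch_close = channel_for(wavelength, "close", channel_map)
    s_sample = dark_subtract(frame_sample)
    s_ref = dark_subtract(frame_reference)
    values = {
        f"{ch_far}/sample": s_sample[ch_far],
        f"{ch_close}/sample": s_sample[ch_close],
        f"{ch_far}/reference": s_ref[ch_far],
        f"{ch_close}/reference": s_ref[ch_close],
    }
    bad = [k for k, v in values.items() if v <= 0]
    if bad:
        raise LowSNRError(
            f"{wavelength} nm excluded: non-positive raw signal on {', '.join(bad)}")
    return (s_sample[ch_far] / s_sample[ch_close]) * (s_ref[ch_close] / s_ref[ch_far])


def corrected_ratios(frame_sample: MeasurementFrame,
                     frame_reference: MeasurementFrame,
                     wavelengths=(1450, 1650),
                     channel_map: Mapping[str, tuple[int, str]] = CHANNEL_MAP
                     ) -> CorrectedRatios:
    """Corrected ratios for every wavelength, collecting per-wavelength
    exclusions instead of raising."""
    out = CorrectedRatios(r_corr={})
    for wl in wavelengths:
        try:
            out.r_corr[wl] = corrected_ratio(frame_sample, frame_reference, wl,
                                             channel_map)
        except LowSNRError as exc:
            out.excluded[wl] = str(exc)
    return out


def average_frames(frames: list[MeasurementFrame]) -> MeasurementFrame:
    """Arithmetic mean of v_on and v_dark per channel across repeated frames."""
    if not frames:
        raise ParseError("cannot average zero frames")
    roles = {f.role for f in frames}
    if len(roles) != 1:
        raise ParseError(f"cannot average frames with mixed roles {sorted(roles)}")
    n = len(frames)
    readings = {}
    for ch in CHANNEL_MAP:
        readings[ch] = ChannelReading(
            v_on=sum(f.readings[ch].v_on for f in frames) / n,
            v_dark=sum(f.readings[ch].v_dark for f in frames) / n,
        )
    return MeasurementFrame(role=roles.pop(), readings=readings, n_averaged=n)


def read_frames_csv(path_or_buf: str | PathLike | IO) -> dict[str, MeasurementFrame]:
    """Read measurement frames from CSV (columns: frame_id, role, channel,
    v_on_V, v_dark_V) and return the averaged frame per role."""
    df = pd.read_csv(path_or_buf, comment="#")
    required = {"frame_id", "role", "channel", "v_on_V", "v_dark_V"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"measurement CSV missing columns: {sorted(missing)}")
    out: dict[str, MeasurementFrame] = {}
    for role, role_df in df.groupby("role"):
        frames = []
        for _, frame_df in role_df.groupby("frame_id"):
            readings = {
                str(r["channel"]): ChannelReading(float(r["v_on_V"]),
                                                  float(r["v_dark_V"]))
                for _, r in frame_df.iterrows()
            }
            frames.append(MeasurementFrame(role=str(role), readings=readings))
        out[str(role)] = average_frames(frames)
    return out


def write_frames_csv(frames: Mapping[str, MeasurementFrame],
                     path: str | PathLike) -> None:
    """Write frames (one per role) to the measurement CSV layout."""
    rows = []
    for role, frame in frames.items():
        for ch, rd in frame.readings.items():
            rows.append({"frame_id": 0, "role": role, "channel": ch,
                         "v_on_V": rd.v_on, "v_dark_V": rd.v_dark})
    pd.DataFrame(rows).to_csv(path, index=False)
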