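"""Domain types shared by all analysis stages, plus session container I/O.

A session is a sequence of blocks (baseline recording / active testing /
conditioning stimulation, repeated), each holding a contiguous multichannel
surface-potential segment with its pulse-event table.  The on-disk container
is HDF5: one group per block with the float32 signal matrix, sampling rate
and event table, plus a channel table and a JSON-serialized protocol.

All times are seconds relative to block start; all time windows throughout
the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

BlockKind = str  # {"baseline", "test", "conditioning"}

_BLOCK_KINDS = ("baseline", "test", "conditioning")


class ValidationError(ValueError):
    """A session, recording or protocol violates a structural invariant."""


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one electrode on the grid.

    ``area`` is data, not inferred from geometry: the anatomical boundary
    (e.g. a sulcus) that separates the two areas on the grid is assigned
    upstream.
    """

    channel_id: int
    grid_row: int
    grid_col: int
    area: str  # "M1" or "S1"
    good: bool = True

    def __post_init__(self):
        if self.area not in ("M1", "S1"):
            raise ValidationError(f"unknown area {self.area!r} for channel {self.channel_id}")


@dataclass(frozen=True)
class PulseEvent:
    """One light pulse: onset (s from block start), laser identity, width (s)."""

    onset_time: float
    laser_id: int
    pulse_width: float

    def __post_init__(self):
        if self.onset_time < 0:
            raise ValidationError(f"negative event onset {self.onset_time}")
        if self.pulse_width <= 0:
            raise ValidationError(f"non-positive pulse width {self.pulse_width}")


@dataclass
class Recording:
    """A contiguous multichannel segment with channel metadata and events.

    ``data`` is channels x samples in microvolts (stored float32); rows are
    ordered as ``channels``.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    events: list[PulseEvent] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be 2-D (channels x samples)")
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def good_mask(self) -> np.ndarray:
        return np.array([c.good for c in self.channels], dtype=bool)

    def good_indices(self) -> np.ndarray:
        return np.flatnonzero(self.good_mask)

    def channel_index(self, channel_id: int) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise ValidationError(f"unknown channel id {channel_id}")

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"non-positive sampling rate {self.fs}")
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channels"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate channel ids")
        coords = [(c.grid_row, c.grid_col) for c in self.channels if c.good]
        if len(set(coords)) != len(coords):
            raise ValidationError("duplicate grid coordinates among good channels")
        last = -np.inf
        for ev in self.events:
            if ev.onset_time <= last:
                raise ValidationError(
                    f"event onsets not strictly increasing at t={ev.onset_time}"
                )
            last = ev.onset_time
        if self.events and self.events[-1].onset_time >= self.duration:
            raise ValidationError("event onset beyond segment end")


@dataclass
class SessionProtocol:
    """Ordered block structure of one experiment.

    The canonical protocol repeats baseline -> test -> conditioning
    ``n_repeats`` times; an optional trailing baseline (and test) block
    provides a post-conditioning measurement after the final repeat.

    ``laser_sites`` maps each laser to the channel nearest its cortical
    target.  ``inter_laser_latency`` is the onset lag of laser 1 behind
    laser 0 during two-laser conditioning.
    """

    blocks: list[tuple[BlockKind, float]]
    laser_sites: list[tuple[int, int]]  # (laser_id, channel_id)
    cond_rate: float = 5.0
    inter_laser_latency: float | None = None
    n_repeats: int = 5
    test_rate: float = 5.0
    test_pulses: int = 100  # per laser, alternated in sub-blocks of 10

    def __post_init__(self):
        self.validate()

    @classmethod
    def standard(
        cls,
        laser_sites: list[tuple[int, int]],
        baseline_s: float = 30.0,
        test_pulses: int = 100,
        test_rate: float = 5.0,
        conditioning_s: float = 600.0,
        cond_rate: float = 5.0,
        inter_laser_latency: float | None = None,
        n_repeats: int = 5,
        final_measurement: bool = False,
    ) -> "SessionProtocol":
        """Build the repeating baseline/test/conditioning protocol.

        Test blocks deliver ``test_pulses`` pulses through each laser at
        ``test_rate`` Hz, alternated between lasers in sub-blocks of 10.
        """
        test_s = test_pulses * len(laser_sites) / test_rate
        blocks: list[tuple[BlockKind, float]] = []
        for _ in range(n_repeats):
            blocks += [("baseline", baseline_s), ("test", test_s),
                       ("conditioning", conditioning_s)]
        if final_measurement:
            blocks += [("baseline", baseline_s), ("test", test_s)]
        return cls(
            blocks=blocks,
            laser_sites=list(laser_sites),
            cond_rate=cond_rate,
            inter_laser_latency=inter_laser_latency,
            n_repeats=n_repeats,
            test_rate=test_rate,
            test_pulses=test_pulses,
        )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_indices(self, kind: BlockKind) -> list[int]:
        return [i for i, (k, _) in enumerate(self.blocks) if k == kind]

    def validate(self) -> None:
        if not 1 <= len(self.laser_sites) <= 2:
            raise ValidationError("laser_sites must list one or two lasers")
        if self.cond_rate <= 0:
            raise ValidationError("conditioning rate must be positive")
        for i, (kind, dur) in enumerate(self.blocks):
            if kind not in _BLOCK_KINDS:
                raise ValidationError(f"block {i}: unknown kind {kind!r}")
            if dur <= 0:
                raise ValidationError(f"block {i}: non-positive duration")
        # repeating B,T,C pattern with an optional trailing B or B,T
        kinds = [k for k, _ in self.blocks]
        n_full = len(kinds) // 3
        for r in range(n_full):
            if kinds[3 * r : 3 * r + 3] != ["baseline", "test", "conditioning"]:
                raise ValidationError(
                    f"blocks {3*r}..{3*r+2} do not follow baseline/test/conditioning"
                )
        tail = kinds[3 * n_full :]
        if tail not in ([], ["baseline"], ["baseline", "test"]):
            raise ValidationError(f"invalid trailing blocks {tail}")


@dataclass
class SessionData:
    """A protocol plus one recorded segment per block."""

    protocol: SessionProtocol
    segments: dict[int, Recording]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for i in range(self.protocol.n_blocks):
            if i not in self.segments:
                raise ValidationError(f"block {i}: missing segment")
        ref = self.segments[0].channels
        for i, rec in self.segments.items():
            if rec.channels != ref:
                raise ValidationError(f"block {i}: channel metadata differs from block 0")

    def blocks_of_kind(self, kind: BlockKind) -> list[tuple[int, Recording]]:
        return [(i, self.segments[i]) for i in self.protocol.block_indices(kind)]


# ---------------------------------------------------------------------------
# HDF5 container

_EVENT_DTYPE = np.dtype(
    [("onset_time", "f8"), ("laser_id", "i8"), ("pulse_width", "f8")]
)
_CHANNEL_DTYPE = np.dtype(
    [("channel_id", "i8"), ("grid_row", "i8"), ("grid_col", "i8"),
     ("area", "S4"), ("good", "?")]
)


def _events_to_array(events: list[PulseEvent]) -> np.ndarray:
    arr = np.zeros(len(events), dtype=_EVENT_DTYPE)
    for i, ev in enumerate(events):
        arr[i] = (ev.onset_time, ev.laser_id, ev.pulse_width)
    return arr


def _channels_to_array(channels: list[ChannelInfo]) -> np.ndarray:
    arr = np.zeros(len(channels), dtype=_CHANNEL_DTYPE)
    for i, c in enumerate(channels):
        arr[i] = (c.channel_id, c.grid_row, c.grid_col, c.area.encode(), c.good)
    return arr


def write_session(session: SessionData, path) -> None:
    """Write a validated session to the HDF5 container at ``path``.

    Signal arrays are stored float32 and round-trip bit-exactly.
    """
    session.validate()
    for rec in session.segments.values():
        rec.validate()
    proto = session.protocol
    proto_json = json.dumps(
        {
            "blocks": proto.blocks,
            "laser_sites": proto.laser_sites,
            "cond_rate": proto.cond_rate,
            "inter_laser_latency": proto.inter_laser_latency,
            "n_repeats": proto.n_repeats,
            "test_rate": proto.test_rate,
            "test_pulses": proto.test_pulses,
        }
    )
    with h5py.File(path, "w") as f:
        f.attrs["protocol"] = proto_json
        f.create_dataset("channels", data=_channels_to_array(session.segments[0].channels))
        grp = f.create_group("blocks")
        for i in range(proto.n_blocks):
            rec = session.segments[i]
            b = grp.create_group(str(i))
            b.create_dataset("data", data=rec.data.astype(np.float32))
            b.create_dataset("fs", data=float(rec.fs))
            b.create_dataset("events", data=_events_to_array(rec.events))


def read_session(path) -> SessionData:
    """Read and fully validate a session container written by `write_session`."""
    with h5py.File(path, "r") as f:
        try:
            proto_raw = json.loads(f.attrs["protocol"])
        except KeyError as e:
            raise ValidationError("container has no protocol attribute") from e
        proto = SessionProtocol(
            blocks=[(str(k), float(d)) for k, d in proto_raw["blocks"]],
            laser_sites=[(int(a), int(b)) for a, b in proto_raw["laser_sites"]],
            cond_rate=float(proto_raw["cond_rate"]),
            inter_laser_latency=proto_raw["inter_laser_latency"],
            n_repeats=int(proto_raw["n_repeats"]),
            test_rate=float(proto_raw["test_rate"]),
            test_pulses=int(proto_raw["test_pulses"]),
        )
        chan_arr = f["channels"][:]
        channels = [
            ChannelInfo(
                channel_id=int(r["channel_id"]),
                grid_row=int(r["grid_row"]),
                grid_col=int(r["grid_col"]),
                area=r["area"].decode(),
                good=bool(r["good"]),
            )
            for r in chan_arr
        ]
        segments: dict[int, Recording] = {}
        for i in range(proto.n_blocks):
            key = f"blocks/{i}"
            if key not in f:
                raise ValidationError(f"block {i}: segment missing from container")
            b = f[key]
            ev_arr = b["events"][:]
            events = [
                PulseEvent(float(r["onset_time"]), int(r["laser_id"]), float(r["pulse_width"]))
                for r in ev_arr
            ]
            try:
                segments[i] = Recording(
                    data=b["data"][:], fs=float(b["fs"][()]),
                    channels=channels, events=events,
                )
            except ValidationError as e:
                raise ValidationError(f"block {i}: {e}") from e
    return SessionData(protocol=proto, segments=segments)


# ---------------------------------------------------------------------------
# CSV export

def events_to_frame(rec: Recording) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.onset_time, e.laser_id, e.pulse_width) for e in rec.events],
        columns=["onset_time", "laser_id", "pulse_width"],
    )


def channels_to_frame(channels: list[ChannelInfo]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in channels])


def export_events_csv(rec: Recording, path) -> None:
    events_to_frame(rec).to_csv(path, index=False)


def export_channels_csv(channels: list[ChannelInfo], path) -> None:
    channels_to_frame(channels).to_csv(path, index=False)
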