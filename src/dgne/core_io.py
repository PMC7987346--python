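"""Session containers, validation and plain-text bundle I/O.

A recording session is held in :class:`SessionRecording`: a binary event-onset
raster (cells x frames), optional continuous dF/F traces, running speed and belt
position, and optional bulk MPP fluorescence and pupil-diameter channels.  On
disk a session is a directory of tab-separated tables plus a plain-text manifest
(``manifest.txt``) carrying the metadata — diffable and language neutral.

Frames are 0-based throughout; all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Epochs",
    "SessionRecording",
    "SessionFormatError",
    "read_session",
    "write_session",
    "validate_session",
    "convert_dryad",
]


class SessionFormatError(ValueError):
    """Raised when an on-disk bundle or in-memory session violates the format."""


@dataclass(frozen=True)
class Epochs:
    """Behavioral-state segmentation into run and rest intervals.

    Intervals are half-open ``[start, end)`` frame ranges, sorted and
    non-overlapping.  Frames belonging to neither state (sub-minimum
    supra-threshold movement bouts) are simply absent from both lists.
    """

    run: tuple[tuple[int, int], ...]
    rest: tuple[tuple[int, int], ...]
    n_frames: int

    def __post_init__(self):
        for name, ivals in (("run", self.run), ("rest", self.rest)):
            prev_end = 0
            for s, e in ivals:
                if not (0 <= s < e <= self.n_frames):
                    raise ValueError(f"{name} interval ({s}, {e}) outside [0, {self.n_frames})")
                if s < prev_end:
                    raise ValueError(f"{name} intervals overlap or are unsorted at ({s}, {e})")
                prev_end = e
        rm = self.mask("run")
        sm = self.mask("rest")
        if np.any(rm & sm):
            raise ValueError("run and rest intervals overlap")

    def mask(self, state: str) -> np.ndarray:
        """Boolean per-frame mask for ``state`` ('run' or 'rest')."""
        ivals = {"run": self.run, "rest": self.rest}[state]
        m = np.zeros(self.n_frames, dtype=bool)
        for s, e in ivals:
            m[s:e] = True
        return m

    def frames(self, state: str) -> np.ndarray:
        return np.flatnonzero(self.mask(state))

    def duration_s(self, state: str, frame_rate: float) -> float:
        return sum(e - s for s, e in {"run": self.run, "rest": self.rest}[state]) / frame_rate


@dataclass
class SessionRecording:
    """One imaging session.

    raster : (n_cells, n_frames) int array in {0, 1}; 1 marks an event onset.
    dff    : (n_cells, n_frames) float dF/F traces, or None if unavailable
             (e.g. sessions converted from a binarized-only deposit).
    speed  : per-frame running speed, cm/s, >= 0.
    position : per-frame belt position, cm, in [0, belt_length).
    mpp    : optional bulk MPP fluorescence trace (arbitrary units).
    pupil  : optional normalized pupil diameter; ``blink`` is its binary
             invalid-frame mask (1 = blink/saccade, value unusable).
    """

    raster: np.ndarray
    dff: np.ndarray | None
    speed: np.ndarray
    position: np.ndarray
    frame_rate: float
    belt_length: float
    session_id: str = "session"
    mpp: np.ndarray | None = None
    pupil: np.ndarray | None = None
    blink: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return int(self.raster.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.raster.shape[1])

    def require(self, channel: str) -> np.ndarray:
        """Return an optional channel or fail fast with a named error."""
        val = getattr(self, channel)
        if val is None:
            raise SessionFormatError(
                f"session '{self.session_id}' has no '{channel}' channel, "
                f"required by this analysis stage"
            )
        return val


def validate_session(s: SessionRecording) -> list[str]:
    """Check every container invariant; return a list of violations (never raises)."""
    v: list[str] = []
    if s.raster.ndim != 2:
        return [f"raster must be 2-D (got ndim={s.raster.ndim})"]
    n_frames = s.raster.shape[1]
    bad = ~np.isin(s.raster, (0, 1))
    if bad.any():
        c, f = np.argwhere(bad)[0]
        v.append(f"raster values outside {{0,1}} (first at cell {c}, frame {f})")
    for name in ("dff", "speed", "position", "mpp", "pupil", "blink"):
        arr = getattr(s, name)
        if arr is None:
            continue
        expect = s.raster.shape if name == "dff" else (n_frames,)
        if arr.shape != expect:
            v.append(f"{name} shape {arr.shape} does not match expected {expect}")
    if s.frame_rate <= 0:
        v.append(f"frame_rate must be positive (got {s.frame_rate})")
    if s.belt_length <= 0:
        v.append(f"belt_length must be positive (got {s.belt_length})")
    if s.speed.shape == (n_frames,) and np.any(s.speed < 0):
        v.append(f"speed has negative values (first at frame {int(np.argmax(s.speed < 0))})")
    if s.position.shape == (n_frames,):
        out = (s.position < 0) | (s.position >= s.belt_length)
        if out.any():
            v.append(
                f"position outside [0, {s.belt_length}) "
                f"(first at frame {int(np.argmax(out))})"
            )
    if s.dff is not None and s.dff.shape == s.raster.shape:
        nan = np.isnan(s.dff)
        if nan.any():
            c, f = np.argwhere(nan)[0]
            v.append(f"NaN in dff at cell {c}, frame {f}")
    if s.blink is not None and s.blink.shape == (n_frames,) and not np.isin(s.blink, (0, 1)).all():
        v.append("blink mask has values outside {0,1}")
    if s.pupil is not None and s.blink is None:
        v.append("pupil channel present without a blink mask")
    return v


# ---------------------------------------------------------------------------
# on-disk bundle

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_session(s: SessionRecording, path: str | os.PathLike) -> str:
    """Write ``s`` as a directory bundle of TSV tables plus ``manifest.txt``."""
    violations = validate_session(s)
    if violations:
        raise SessionFormatError("refusing to write invalid session: " + "; ".join(violations))
    path = str(path)
    os.makedirs(path, exist_ok=True)
    channels = ["raster", "behavior"]
    np.savetxt(os.path.join(path, "raster.tsv"), s.raster, fmt="%d", delimiter="\t")
    if s.dff is not None:
        channels.append("dff")
        np.savetxt(os.path.join(path, "dff.tsv"), s.dff, fmt=_FLOAT_FMT, delimiter="\t")
    pd.DataFrame({"speed": s.speed, "position": s.position}).to_csv(
        os.path.join(path, "behavior.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    if s.mpp is not None:
        channels.append("mpp")
        pd.DataFrame({"mpp": s.mpp}).to_csv(
            os.path.join(path, "mpp.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
        )
    if s.pupil is not None:
        channels.append("pupil")
        pd.DataFrame({"diameter": s.pupil, "blink": s.blink.astype(int)}).to_csv(
            os.path.join(path, "pupil.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
        )
    manifest = {
        "session_id": s.session_id,
        "frame_rate": float(s.frame_rate),
        "belt_length": float(s.belt_length),
        "n_cells": s.n_cells,
        "n_frames": s.n_frames,
        "channels": channels,
    }
    with open(os.path.join(path, "manifest.txt"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_session(path: str | os.PathLike) -> SessionRecording:
    """Read a session bundle written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming the offending channel on any
    shape or value inconsistency.
    """
    path = str(path)
    mpath = os.path.join(path, "manifest.txt")
    if not os.path.exists(mpath):
        raise SessionFormatError(f"no manifest.txt in {path}")
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    channels = manifest.get("channels", [])
    raster = np.loadtxt(os.path.join(path, "raster.tsv"), delimiter="\t", ndmin=2)
    if not np.isin(raster, (0, 1)).all():
        raise SessionFormatError("raster: values outside {0,1}")
    raster = raster.astype(np.int8)
    n_cells, n_frames = raster.shape
    if (n_cells, n_frames) != (manifest["n_cells"], manifest["n_frames"]):
        raise SessionFormatError(
            f"raster: shape {raster.shape} does not match manifest "
            f"({manifest['n_cells']}, {manifest['n_frames']})"
        )
    beh = pd.read_csv(os.path.join(path, "behavior.tsv"), sep="\t")
    for col in ("speed", "position"):
        if len(beh[col]) != n_frames:
            raise SessionFormatError(f"{col}: length {len(beh[col])} != n_frames {n_frames}")
    dff = mpp = pupil = blink = None
    if "dff" in channels:
        dff = np.loadtxt(os.path.join(path, "dff.tsv"), delimiter="\t", ndmin=2)
        if dff.shape != raster.shape:
            raise SessionFormatError(f"dff: shape {dff.shape} != raster shape {raster.shape}")
    if "mpp" in channels:
        mpp = pd.read_csv(os.path.join(path, "mpp.tsv"), sep="\t")["mpp"].to_numpy()
        if len(mpp) != n_frames:
            raise SessionFormatError(f"mpp: length {len(mpp)} != n_frames {n_frames}")
    if "pupil" in channels:
        pt = pd.read_csv(os.path.join(path, "pupil.tsv"), sep="\t")
        pupil = pt["diameter"].to_numpy()
        blink = pt["blink"].to_numpy().astype(np.int8)
        if len(pupil) != n_frames:
            raise SessionFormatError(f"pupil: length {len(pupil)} != n_frames {n_frames}")
    s = SessionRecording(
        raster=raster,
        dff=dff,
        speed=beh["speed"].to_numpy(),
        position=beh["position"].to_numpy(),
        frame_rate=float(manifest["frame_rate"]),
        belt_length=float(manifest["belt_length"]),
        session_id=str(manifest.get("session_id", os.path.basename(path))),
        mpp=mpp,
        pupil=pupil,
        blink=blink,
    )
    violations = validate_session(s)
    if violations:
        raise SessionFormatError("; ".join(violations))
    return s


def convert_dryad(
    traces_path: str | os.PathLike,
    out_path: str | os.PathLike,
    frame_rate: float = 15.0,
    belt_length: float = 150.0,
    behavior_path: str | os.PathLike | None = None,
    session_id: str | None = None,
) -> str:
    """Convert a deposited per-session binarized-trace matrix into a bundle.

    ``traces_path`` is a delimited text matrix (cells x frames, values 0/1).
    The deposit carries binarized traces only, so the converted session has no
    dF/F channel; behavior columns (speed, position) can be supplied separately.
    The mapping is best-effort — the deposit's exact layout must be confirmed
    against the archive itself.
    """
    raster = np.loadtxt(traces_path, delimiter=None, ndmin=2)
    if not np.isin(raster, (0, 1)).all():
        raise SessionFormatError("binarized traces: values outside {0,1}")
    n_frames = raster.shape[1]
    if behavior_path is not None:
        beh = pd.read_csv(behavior_path, sep=None, engine="python")
        speed = beh["speed"].to_numpy()
        position = beh["position"].to_numpy()
    else:
        speed = np.zeros(n_frames)
        position = np.zeros(n_frames)
    s = SessionRecording(
        raster=raster.astype(np.int8),
        dff=None,
        speed=speed,
        position=position,
        frame_rate=frame_rate,
        belt_length=belt_length,
        session_id=session_id or os.path.splitext(os.path.basename(str(traces_path)))[0],
    )
    return write_session(s, out_path)
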