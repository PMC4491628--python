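"""Motion-capture container and text readers/writers.

Two plain-text dialects are supported:

* **TRC** — the de-facto standard tab-separated marker-trajectory format
  (header block with ``DataRate``/``NumFrames``/``NumMarkers``, then one row
  per frame: ``Frame# Time X1 Y1 Z1 X2 Y2 Z2 ...``).
* **tabular** — the package's canonical fixture dialect: ``#``-prefixed
  header lines carrying the sample rate and landmark names, then one
  whitespace-separated row per frame with three columns per landmark.

C3D is a binary container and is intentionally not handled here; convert to
TRC upstream.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MotionSequence", "MotionFormatError", "load_motion", "save_motion"]


class MotionFormatError(ValueError):
    """Raised when a motion file cannot be parsed in the declared dialect."""


@dataclass
class MotionSequence:
    """A time series of labeled 3D landmark positions at a fixed sample rate.

    Parameters
    ----------
    frames
        Array of shape ``(T, K, 3)`` holding landmark positions in arbitrary
        length units.
    sample_rate
        Sampling frequency in Hz; must be positive.
    landmark_names
        ``K`` labels, one per landmark column.
    """

    frames: np.ndarray
    sample_rate: float
    landmark_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (T, K, 3), got {self.frames.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.landmark_names:
            self.landmark_names = [f"m{i}" for i in range(self.frames.shape[1])]
        if len(self.landmark_names) != self.frames.shape[1]:
            raise ValueError("landmark_names length must match the landmark count")
        if np.isnan(self.frames).any():
            raise ValueError("NaN positions found for available landmarks")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.frames.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.landmark_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown landmark {name!r}; available: {self.landmark_names}"
            ) from None


def load_motion(path: str | Path, format: str | None = None) -> MotionSequence:
    """Read a :class:`MotionSequence` from ``path``.

    ``format`` is one of ``"trc"`` or ``"tabular"``; when omitted it is
    inferred from the file suffix (``.trc`` vs anything else).
    """
    path = Path(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "tabular"
    format = format.lower()
    if format == "trc":
        return _read_trc(path)
    if format in ("tabular", "tab", "txt"):
        return _read_tabular(path)
    if format == "c3d":
        raise MotionFormatError(
            "C3D is a binary format not handled by this reader; convert to TRC"
        )
    raise MotionFormatError(f"unknown motion format {format!r}")


def save_motion(seq: MotionSequence, path: str | Path, format: str | None = None) -> None:
    """Write ``seq`` to ``path`` in the TRC or tabular dialect."""
    path = Path(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "tabular"
    format = format.lower()
    if format == "trc":
        _write_trc(seq, path)
    elif format in ("tabular", "tab", "txt"):
        _write_tabular(seq, path)
    else:
        raise MotionFormatError(f"unknown motion format {format!r}")


# ---------------------------------------------------------------------------
# tabular dialect

def _read_tabular(path: Path) -> MotionSequence:
    sample_rate = None
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_rate_hz"):
                    sample_rate = float(body.split("=", 1)[1])
                elif body.startswith("landmarks"):
                    names = body.split(":", 1)[1].split()
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise MotionFormatError(f"{path}:{lineno}: non-numeric data row: {exc}") from None
    if not rows:
        raise MotionFormatError(f"{path}: no data rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise MotionFormatError(f"{path}: ragged rows (expected {width} columns everywhere)")
    if width % 3 != 0:
        raise MotionFormatError(f"{path}: row width {width} is not a multiple of 3")
    frames = np.asarray(rows, dtype=float).reshape(len(rows), width // 3, 3)
    if sample_rate is None:
        sample_rate = 120.0
    if names and len(names) != frames.shape[1]:
        raise MotionFormatError(
            f"{path}: {len(names)} landmark names for {frames.shape[1]} landmark columns"
        )
    if np.isnan(frames).any():
        raise MotionFormatError(f"{path}: NaN coordinates in data rows")
    return MotionSequence(frames, sample_rate, names or [])


def _write_tabular(seq: MotionSequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz = {seq.sample_rate!r}\n")
        fh.write("# landmarks: " + " ".join(seq.landmark_names) + "\n")
        flat = seq.frames.reshape(seq.n_frames, -1)
        for row in flat:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# TRC dialect

def _read_trc(path: Path) -> MotionSequence:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise MotionFormatError(f"{path}: truncated TRC header")
    try:
        meta_keys = lines[1].split("\t")
        meta_vals = lines[2].split("\t")
        meta = dict(zip(meta_keys, meta_vals))
        sample_rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
    except (KeyError, ValueError, IndexError) as exc:
        raise MotionFormatError(f"{path}: bad TRC metadata block: {exc}") from None
    header_cells = lines[3].split("\t")
    names = [c for c in header_cells[2:] if c.strip()]
    if len(names) != n_markers:
        raise MotionFormatError(
            f"{path}: header names {len(names)} != NumMarkers {n_markers}"
        )
    rows = []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        toks = line.split("\t")
        vals = toks[2 : 2 + 3 * n_markers]
        if len(vals) != 3 * n_markers:
            raise MotionFormatError(
                f"{path}:{lineno}: expected {3 * n_markers} coordinate columns, got {len(vals)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise MotionFormatError(f"{path}:{lineno}: non-numeric coordinate") from None
    if not rows:
        raise MotionFormatError(f"{path}: no data rows")
    frames = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    if np.isnan(frames).any():
        raise MotionFormatError(f"{path}: NaN coordinates in data rows")
    return MotionSequence(frames, sample_rate, names)


def _write_trc(seq: MotionSequence, path: Path) -> None:
    T, K = seq.n_frames, seq.n_landmarks
    rate = seq.sample_rate
    buf = _stdio.StringIO()
    buf.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
    buf.write(
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
    )
    buf.write(f"{rate!r}\t{rate!r}\t{T}\t{K}\tm\t{rate!r}\t1\t{T}\n")
    buf.write("Frame#\tTime\t" + "\t\t\t".join(seq.landmark_names) + "\t\t\t\n")
    coords = "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(K))
    buf.write(f"\t\t{coords}\n")
    for t in range(T):
        row = "\t".join(format(v, ".17g") for v in seq.frames[t].ravel())
        buf.write(f"{t + 1}\t{t / rate:.6f}\t{row}\n")
    path.write_text(buf.getvalue())
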