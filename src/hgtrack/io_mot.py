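"""MOTChallenge CSV reading/writing.

Record layout: ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,...`` with
1-based frame and id in files.  Parsing is lossless and tolerant of blank
lines and a header line; malformed lines raise with their line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = ["MotRecord", "read_mot", "write_mot"]


@dataclass(frozen=True)
class MotRecord:
    frame: int          # 1-based
    track_id: int
    left: float
    top: float
    width: float
    height: float
    conf: float = 1.0
    extra: tuple = (-1.0, -1.0, -1.0)

    def __post_init__(self):
        if self.frame < 1:
            raise ValueError("frame must be >= 1")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width/height must be > 0")

    @property
    def box(self) -> tuple[float, float, float, float]:
        return (self.left, self.top, self.width, self.height)


def read_mot(path: str | Path) -> list[MotRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[MotRecord] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if not parts[0].lstrip("-").replace(".", "", 1).isdigit():
                log.warning("%s:%d: skipping non-numeric line", path, ln)
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 comma-separated fields")
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                nums = [float(p) for p in parts[2:]]
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: {e}") from None
            conf = nums[4] if len(nums) > 4 else 1.0
            extra = tuple(nums[5:8]) if len(nums) > 5 else (-1.0, -1.0, -1.0)
            records.append(MotRecord(frame, tid, nums[0], nums[1], nums[2], nums[3],
                                     conf, extra))
    return records


def write_mot(records: list[MotRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            extra = ",".join(f"{v:g}" for v in r.extra)
            fh.write(f"{r.frame},{r.track_id},{r.left:g},{r.top:g},"
                     f"{r.width:g},{r.height:g},{r.conf:g},{extra}\n")
    return path
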