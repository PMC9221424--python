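"""Reading and writing scan frames as multi-page TIFF.

One file per frame, one page per channel in the fixed order DAPI, CK, Vim,
CD45/CD31; the channel order and pixel scale are recorded in the TIFF
description tag so round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import CHANNELS, ImmunoFrame


def write_frame(frame: ImmunoFrame, path: str | Path) -> None:
    stack = np.stack([frame.channels[c] for c in CHANNELS]).astype(np.float32)
    meta = {"channels": list(CHANNELS), "um_per_px": frame.um_per_px,
            "frame_index": frame.index}
    tifffile.imwrite(path, stack, description=json.dumps(meta),
                     photometric="minisblack", planarconfig="separate")


def read_frame(path: str | Path) -> ImmunoFrame:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    channels = {c: stack[i].astype(np.float64)
                for i, c in enumerate(meta["channels"])}
    return ImmunoFrame(index=int(meta["frame_index"]), channels=channels,
                       um_per_px=float(meta["um_per_px"]))


def write_frames(frames: list[ImmunoFrame], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = directory / f"frame_{f.index:04d}.tif"
        write_frame(f, p)
        paths.append(p)
    return paths


def read_frames(directory: str | Path) -> list[ImmunoFrame]:
    return [read_frame(p) for p in sorted(Path(directory).glob("frame_*.tif"))]
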