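"""File formats: multi-page TIFF stacks with plain-text YAML sidecars.

Raw acquisitions are stored the way downstream SIM reconstruction packages
expect them: one multi-page TIFF with the frames ordered exactly as the
pattern sequence (angle-major, phase-minor), plus a human-readable sidecar
recording the optical configuration, the pattern specs, the noise model
and seed.  Pattern repertoires export as 8-bit TIFFs (0/255) with a
matching sidecar; import reverses the export bit-exactly.

Sidecars are schema-versioned YAML; unknown keys survive a read/write
round trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import OpticalConfig
from .patterns import PatternSequence, PatternSpec
from .simulate import NoiseModel, RawStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_pattern_sequence",
    "read_pattern_sequence",
    "write_timing_table",
    "sidecar_path",
]

SCHEMA_VERSION = 1


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".yaml")


def _dump_sidecar(path: Path, payload: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _load_sidecar(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sequence_to_dict(seq: PatternSequence) -> dict:
    return {
        "shape": [int(v) for v in seq.shape],
        "specs": [s.to_dict() for s in seq.specs],
    }


def _sequence_from_dict(d: dict, masks=None) -> PatternSequence:
    specs = [PatternSpec(**s) for s in d["specs"]]
    shape = tuple(d["shape"])
    if masks is None:
        from .patterns import make_line_pattern

        masks = [make_line_pattern(s, shape) for s in specs]
    return PatternSequence(masks=list(masks), specs=specs, shape=shape)


def write_stack(path: str | Path, stack: RawStack) -> None:
    """Write frames as a 32-bit float multi-page TIFF plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    payload: dict = {"kind": "raw_stack", "n_frames": len(stack)}
    payload["optical_config"] = stack.config.to_dict()
    if stack.sequence is not None:
        payload["pattern_sequence"] = _sequence_to_dict(stack.sequence)
    if stack.noise is not None:
        payload["noise"] = stack.noise.to_dict()
    _dump_sidecar(sidecar_path(path), payload)


def read_stack(path: str | Path) -> RawStack:
    """Read a raw stack; a missing sidecar loads a bare stack with a warning."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    sc = sidecar_path(path)
    if not sc.exists():
        warnings.warn(
            f"no sidecar found for {path}; loading bare stack without metadata",
            stacklevel=2,
        )
        return RawStack(frames=frames, sequence=None, config=OpticalConfig())
    meta = _load_sidecar(sc)
    if meta.get("n_frames") not in (None, len(frames)):
        raise ValueError(
            f"sidecar declares {meta['n_frames']} frames but the TIFF has "
            f"{len(frames)} pages"
        )
    config = OpticalConfig.from_dict(meta["optical_config"])
    seq = None
    if "pattern_sequence" in meta:
        seq = _sequence_from_dict(meta["pattern_sequence"])
    noise = NoiseModel(**meta["noise"]) if "noise" in meta else None
    return RawStack(frames=frames, sequence=seq, config=config, noise=noise)


def write_pattern_sequence(path: str | Path, seq: PatternSequence) -> None:
    """Export a repertoire as an 8-bit TIFF (0/255) plus sidecar."""
    path = Path(path)
    pages = np.stack([m.astype(np.uint8) * 255 for m in seq.masks])
    tifffile.imwrite(path, pages)
    _dump_sidecar(
        sidecar_path(path),
        {"kind": "pattern_sequence", **_sequence_to_dict(seq)},
    )


def read_pattern_sequence(path: str | Path) -> PatternSequence:
    """Import a repertoire written by :func:`write_pattern_sequence`."""
    path = Path(path)
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:
        pages = pages[None]
    masks = [(p > 127).astype(np.uint8) for p in pages]
    meta = _load_sidecar(sidecar_path(path))
    return _sequence_from_dict(meta, masks=masks)


def write_timing_table(path: str | Path, scheme) -> None:
    """Export a timing scheme as a tab-delimited event table."""
    with open(path, "w") as fh:
        fh.write("channel\tstate\tt_start_us\tduration_us\n")
        for e in scheme.events:
            fh.write(f"{e.channel}\t{e.state}\t{e.t_start}\t{e.duration}\n")
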