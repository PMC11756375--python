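"""File I/O: TIFF stacks, YAML configuration, and run logging."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__

log = logging.getLogger("junctrack")


def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a T×H×W stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack))


def load_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a T×H×W array (2D inputs gain a T axis)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D TIFF, got {arr.ndim}D")
    return arr


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file; None or a missing file yields defaults only."""
    if path is None:
        return {}
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file {p} does not exist")
    with open(p) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {p} must contain a mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    """Echo the effective configuration (parameters actually used) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def setup_logging(verbose: bool = False, seed: int | None = None) -> None:
    """Configure structured logging stamped with version (and seed if any)."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.info("junctrack %s%s", __version__,
             "" if seed is None else f" (seed={seed})")
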