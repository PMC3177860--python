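"""Packaged configuration constants (loaded from data/defaults.yaml)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = ["defaults"]


@lru_cache(maxsize=1)
def _raw() -> dict:
    with resources.files("warmcool.data").joinpath("defaults.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def defaults() -> dict:
    """Package defaults; the XYZ->LMS matrix is returned as an ndarray."""
    d = dict(_raw())
    d["xyz_to_lms"] = np.asarray(d["xyz_to_lms"], dtype=float)
    return d
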