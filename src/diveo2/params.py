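"""Access to the package's versioned parameter file.

All literature-derived constants (curve anchors, content-formula
coefficients, compartment stores and rates) are read from
``data/printed_constants.yaml`` so that operations never hard-code them.
"""

from __future__ import annotations

import copy
import functools
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


@functools.lru_cache(maxsize=1)
def _load_cached() -> dict[str, Any]:
    ref = resources.files("diveo2").joinpath("data/printed_constants.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_params(path: str | Path | None = None) -> dict[str, Any]:
    """Return the parameter dictionary.

    Parameters
    ----------
    path:
        Optional alternative YAML file; by default the parameter file
        shipped with the package is used. A deep copy is returned so
        callers may mutate the result safely.
    """
    if path is None:
        return copy.deepcopy(_load_cached())
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
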