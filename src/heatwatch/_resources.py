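"""Access to constants tables shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def packaged_data_path(name: str) -> Path:
    """Filesystem path of a packaged data file under ``heatwatch/data``."""
    path = resources.files("heatwatch").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)
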