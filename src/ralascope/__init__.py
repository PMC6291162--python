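"""ralascope: burden, depletion, contact and paralog analyses for
small-GTPase disease-gene cohorts."""

__version__ = "0.1.0"

from importlib import resources as _resources
from pathlib import Path as _Path


def packaged_data(name: str) -> _Path:
    """Path to a packaged fixture file (cohort transcription, synthetic
    region list, site table, known disease positions)."""
    return _Path(str(_resources.files("ralascope") / "data" / name))
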