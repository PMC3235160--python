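"""First-class missing value.

Conservation metrics can be undefined for a region (no alignment available,
region shorter than the scoring window, no binding site inside the aligned
span).  Such cells are carried through the pipeline as ``MISSING`` rather
than raising, and are serialized as ``"nd"`` in TSV output.
"""

from __future__ import annotations

import math

__all__ = ["MISSING", "is_missing"]

ND = "nd"


class _Missing:
    """Singleton marker for an undefined metric value; falsy."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()


def is_missing(x) -> bool:
    """True for MISSING, None, or float NaN."""
    if x is MISSING or x is None:
        return True
    return isinstance(x, float) and math.isnan(x)
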