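"""Machine-parsable warning codes shared across pipeline stages.

Every data-quality warning carries a short upper-case code as the first
token of its message (e.g. ``CLAMPED_COUNTS: ...``) so that logs and
reports can be grepped for specific conditions.
"""

from __future__ import annotations

import warnings

__all__ = ["DataQualityWarning", "warn_code"]


class DataQualityWarning(UserWarning):
    """Non-fatal condition in measured data (clamped counts, slow washout...)."""


#: codes in use
CLAMPED_COUNTS = "CLAMPED_COUNTS"
LAMBDA_BELOW_PHYSICAL = "LAMBDA_BELOW_PHYSICAL"
NON_DECAYING = "NON_DECAYING"
RC_EXTRAPOLATED = "RC_EXTRAPOLATED"


def warn_code(code: str, message: str, stacklevel: int = 3) -> None:
    warnings.warn(f"{code}: {message}", DataQualityWarning, stacklevel=stacklevel)
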