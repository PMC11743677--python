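"""Canonical EEG frequency-band scheme.

Bands are half-open intervals ``[low, high)`` in Hz so that shared edges
(e.g. 4 Hz between delta and theta) are never counted twice.  ``full`` is
the union of the five analysis bands and is used for broadband
connectivity.
"""

from __future__ import annotations

from typing import Dict, Tuple

#: Half-open frequency intervals in Hz.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: Broadband interval covering all analysis bands.
FULL_BAND: Tuple[float, float] = (0.5, 45.0)

#: Band names in canonical order (without 'full').
BAND_NAMES = tuple(BANDS)

#: Band names including the broadband interval, for connectivity.
CONNECTIVITY_BANDS: Dict[str, Tuple[float, float]] = {"full": FULL_BAND, **BANDS}


def band_interval(name: str) -> Tuple[float, float]:
    """Return the ``[low, high)`` interval for a named band ('full' allowed)."""
    try:
        return CONNECTIVITY_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; valid bands: {sorted(CONNECTIVITY_BANDS)}"
        ) from None
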