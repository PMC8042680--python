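"""Published variance-component presets for the two scenario pairings.

Each preset is the printed component column of the corresponding study
table (score-points squared, rounded to 2 decimals as published): the
LAST/MH pairing (10 persons) and the LAST/Hemorrhage pairing (8 persons),
each for the behavioural (BARS) and technical measures.  They serve as
known truth for the synthetic generator and as inputs for D-study
reproduction.
"""

from __future__ import annotations

from .gstudy import VarianceComponents

__all__ = ["COMPONENT_PRESETS", "get_preset"]

COMPONENT_PRESETS: dict[str, dict[str, float]] = {
    # LAST/MH pairing, n_p = 10
    "last_mh_behavioural": {
        "p": 1.10, "t": 0.0, "r": 0.0, "pt": 2.14, "pr": 0.42, "tr": 0.16, "e": 0.81,
    },
    "last_mh_technical": {
        "p": 1.01, "t": 0.0, "r": 0.0, "pt": 1.93, "pr": 0.60, "tr": 0.0, "e": 0.79,
    },
    # LAST/Hemorrhage pairing, n_p = 8
    "last_hem_behavioural": {
        "p": 0.69, "t": 3.51, "r": 0.51, "pt": 1.21, "pr": 0.93, "tr": 0.0, "e": 0.99,
    },
    "last_hem_technical": {
        "p": 0.50, "t": 1.86, "r": 1.70, "pt": 1.14, "pr": 0.49, "tr": 0.0, "e": 2.14,
    },
}

#: persons observed in each pairing's fully crossed study
PAIRING_SIZES = {"last_mh": 10, "last_hem": 8}


def get_preset(name: str) -> VarianceComponents:
    """Published components as a VarianceComponents object (raw == reported)."""
    try:
        values = COMPONENT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(COMPONENT_PRESETS)}"
        ) from None
    pairing = name.rsplit("_", 1)[0]
    return VarianceComponents.from_values(
        values, n_p=PAIRING_SIZES.get(pairing, 0), n_t=2, n_r=2
    )
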