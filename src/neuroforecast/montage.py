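"""10-20 montage constants: canonical channel ordering and neighbor adjacency.

The adjacency table ships as a versioned JSON data file and backs bad-channel
interpolation. Channel names follow the classic 10-20 nomenclature (T3/T4,
T5/T6 rather than the modern T7/T8, P7/P8), matching 20-channel mobile EEG
headsets that include a single auxiliary EOG channel.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

#: canonical ordering of the 19 scalp electrodes
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: auxiliary electrooculogram channel label
EOG_CHANNEL = "EOG"

#: full 20-channel layout used by the synthetic generator
DEFAULT_CHANNELS: tuple[str, ...] = EEG_CHANNELS + (EOG_CHANNEL,)

#: mid-central channels used for inter-subject correlation
ISC_CHANNELS: tuple[str, ...] = ("Cz", "C3", "C4")

#: left / right frontal pair used for frontal alpha asymmetry
FAA_PAIR: tuple[str, str] = ("F3", "F4")


@lru_cache(maxsize=1)
def adjacency() -> dict[str, tuple[str, ...]]:
    """Return the nearest-neighbor adjacency of the 19-channel 10-20 layout."""
    text = resources.files("neuroforecast").joinpath("data/montage_1020.json").read_text()
    table = json.loads(text)["adjacency"]
    return {ch: tuple(nbrs) for ch, nbrs in table.items()}


def neighbors(channel: str) -> tuple[str, ...]:
    """Neighbors of ``channel`` in the 10-20 adjacency table."""
    table = adjacency()
    if channel not in table:
        raise KeyError(f"channel {channel!r} not in the 10-20 adjacency table")
    return table[channel]


def normalize_label(label: str) -> str:
    """Map a raw channel label onto its canonical 10-20 name.

    Handles case differences, common reference suffixes ("EEG F3-REF") and
    the modern temporal aliases T7/T8/P7/P8.
    """
    name = label.strip()
    if name.upper().startswith("EEG "):
        name = name[4:]
    name = name.split("-")[0].strip()
    aliases = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6",
               "FP1": "Fp1", "FP2": "Fp2", "FZ": "Fz", "CZ": "Cz", "PZ": "Pz"}
    upper = name.upper()
    if upper in aliases:
        return aliases[upper]
    for canonical in DEFAULT_CHANNELS:
        if upper == canonical.upper():
            return canonical
    raise ValueError(f"unrecognized channel label: {label!r}")
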