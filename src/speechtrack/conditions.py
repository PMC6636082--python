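"""The experimental condition grid: language × background-noise level.

Eight conditions — {English, Dutch} × {quiet, low, medium, high babble
noise} — define the two stimulus properties of interest:

* **clarity** ``a``: how intelligible the acoustics are for a native
  listener; identical for both languages at the same SNR, 100% in quiet.
* **comprehension** ``c``: how much the listener actually understands;
  equals clarity for the native language (English), 0 for the foreign
  language (Dutch) at every noise level.

Because clarity varies while comprehension is clamped to zero for Dutch,
the two properties vary independently across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LANGUAGES = ("english", "dutch")
BACKGROUNDS = ("quiet", "low", "medium", "high")

#: Nominal SNRs (dB) of the low/medium/high babble-noise levels.
NOISE_SNRS_DB = {"quiet": None, "low": 0.4, "medium": -1.4, "high": -3.2}

_COLUMNS = ["language", "background", "snr_db", "clarity_pct",
            "comprehension_pct"]


@dataclass
class ConditionGrid:
    """Table of the eight acoustic conditions with clarity/comprehension."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"condition grid missing columns {missing}")
        self.table = self.table[_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return (row for _, row in self.table.iterrows())

    @property
    def labels(self) -> list[str]:
        return [f"{r.language}-{r.background}" for r in self]

    def clarity(self) -> np.ndarray:
        """Clarity per condition, as a fraction in [0, 1]."""
        return self.table["clarity_pct"].to_numpy(dtype=float) / 100.0

    def comprehension(self) -> np.ndarray:
        """Comprehension per condition, as a fraction in [0, 1]."""
        return self.table["comprehension_pct"].to_numpy(dtype=float) / 100.0

    def property_values(self, prop: str, percent: bool = True) -> np.ndarray:
        if prop not in ("clarity", "comprehension"):
            raise ValueError(f"unknown property {prop!r}")
        vals = self.table[f"{prop}_pct"].to_numpy(dtype=float)
        return vals if percent else vals / 100.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionGrid":
        return cls(pd.read_csv(path))


def design_grid() -> ConditionGrid:
    """The canonical eight-condition design with its printed percentages.

    Clarity at the three SNRs (0.4, −1.4, −3.2 dB) is 81, 60 and 34%;
    quiet is 100%.  Comprehension mirrors clarity for English and is 0
    for Dutch throughout.
    """
    rows = []
    clarity = {"quiet": 100, "low": 81, "medium": 60, "high": 34}
    for lang in LANGUAGES:
        for bg in BACKGROUNDS:
            rows.append({
                "language": lang,
                "background": bg,
                "snr_db": np.nan if NOISE_SNRS_DB[bg] is None
                else NOISE_SNRS_DB[bg],
                "clarity_pct": clarity[bg],
                "comprehension_pct": clarity[bg] if lang == "english" else 0,
            })
    return ConditionGrid(pd.DataFrame(rows))
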