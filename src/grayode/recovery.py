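"""Shared result container for gray-box recoveries.

Both solver backends (random-projection collocation and the physics-informed
network) emit a :class:`GrayBoxRecovery`: reconstructed state trajectories on
a dense grid, the recovered unknown-term series on the same grid, any
inferred free parameters, and per-stage iteration counts.  The symbolic
module consumes this container regardless of which backend produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GrayBoxRecovery"]


@dataclass
class GrayBoxRecovery:
    model_name: str
    trajectory: pd.DataFrame  # 't' column plus one column per state
    terms: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)
    iterations: list[int] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return self.trajectory["t"].to_numpy()

    def term_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times})
        for slot, series in self.terms.items():
            df[slot] = series
        return df

    def write_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.trajectory.to_csv(directory / "trajectory.csv", index=False)
        if self.terms:
            self.term_frame().to_csv(directory / "terms.csv", index=False)
        if self.params:
            pd.Series(self.params).rename("value").to_csv(directory / "params.csv")
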