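"""Error metrics for recovered terms and inferred parameters.

For a reference series ĥ and recovered series h of length N:
MAE = Σ|ĥ−h|/N, RMSE = sqrt(Σ(ĥ−h)²/N), RE = sqrt(Σ(ĥ−h)²/Σĥ²)·100 (%).
Parameter errors are 100·|nominal − estimate|/|nominal| per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "term_metrics", "param_metrics"]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    re: float
    param_errors: dict[str, float] = field(default_factory=dict)

    def as_table(self) -> dict[str, float]:
        out = {"MAE": self.mae, "RMSE": self.rmse, "RE (%)": self.re}
        out.update({f"RE {k} (%)": v for k, v in self.param_errors.items()})
        return out


def term_metrics(reference, recovered) -> MetricsReport:
    """MAE / RMSE / relative error (%) of a recovered term series."""
    ref = np.asarray(reference, dtype=float).ravel()
    rec = np.asarray(recovered, dtype=float).ravel()
    if ref.size != rec.size or ref.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    err = ref - rec
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    denom = float(np.sum(ref ** 2))
    if denom == 0.0:
        raise ValueError("relative error undefined for an identically zero reference")
    re = float(np.sqrt(np.sum(err ** 2) / denom) * 100.0)
    return MetricsReport(mae=mae, rmse=rmse, re=re)


def param_metrics(nominal: dict[str, float], estimated: dict[str, float]) -> dict[str, float]:
    """Per-parameter relative error in percent."""
    out = {}
    for name, nom in nominal.items():
        if nom == 0:
            raise ValueError(f"relative error undefined for zero nominal {name!r}")
        out[name] = 100.0 * abs(nom - estimated[name]) / abs(nom)
    return out
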