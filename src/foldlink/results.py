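"""Result containers shared by the fitting layer."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import pandas as pd


@dataclass
class FitResult:
    """Point estimates with uncertainties and convergence diagnostics.

    A False ``converged`` flag marks the estimates non-authoritative;
    callers must check it before using the values.
    """

    params: dict[str, float]
    stderr: dict[str, float | None] = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = False
    n_restarts_used: int = 0
    provenance: dict[str, Any] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "provenance": self.provenance,
            "extras": {k: v for k, v in self.extras.items() if _jsonable(v)},
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


@dataclass
class RecoveryReport:
    """Per-parameter recovery statistics over R seeded replicates."""

    table: pd.DataFrame  # columns: param, true, mean, bias, rmse
    n_replicates: int
    n_failed: int
    noise_sd: float
    master_seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def param(self, name: str) -> pd.Series:
        row = self.table[self.table["param"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]
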