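"""Generic observable dataset container.

A :class:`CurveTable` holds one measured (or simulated) curve — or a stack
of curves distinguished by a ``series`` column — together with per-point
uncertainties, the experimental condition metadata, and, for synthetic
data, the provenance (seed and configuration hash) that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

_REQUIRED = ("x", "y")


@dataclass
class CurveTable:
    """Tabular (x, y, sigma) data with condition metadata and provenance.

    Parameters
    ----------
    frame
        DataFrame with at least columns ``x`` and ``y``; optional ``sigma``
        (per-point standard deviation) and ``series`` (label for stacked
        curves, e.g. one melt per protein concentration).
    kind
        Short tag describing the observable ("chem_denaturation",
        "chevron", "thermal_melt", "dsc", "peptide_titration",
        "velocity").
    meta
        Condition metadata: C_tot, T, P_tot, variant label, units.
    provenance
        Generator provenance: master seed, per-dataset seed, config hash.
        Always present for synthetic data.
    """

    frame: pd.DataFrame
    kind: str = ""
    meta: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in _REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"CurveTable frame must contain column {col!r}")
        if "sigma" not in self.frame.columns:
            self.frame = self.frame.assign(sigma=np.nan)

    # -- convenience accessors -------------------------------------------
    @property
    def x(self) -> np.ndarray:
        return self.frame["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(float)

    @property
    def sigma(self) -> np.ndarray:
        return self.frame["sigma"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.frame)

    def series_labels(self) -> list:
        if "series" not in self.frame.columns:
            return []
        return list(pd.unique(self.frame["series"]))

    def get_series(self, label) -> "CurveTable":
        """Single-series view of a stacked table."""
        sub = self.frame[self.frame["series"] == label].reset_index(drop=True)
        meta = dict(self.meta)
        meta["series"] = label
        return CurveTable(sub, kind=self.kind, meta=meta, provenance=self.provenance)

    # -- round-trip -------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the table as CSV with metadata in '#' header comments."""
        with open(path, "w") as fh:
            header = {"kind": self.kind, "meta": self.meta, "provenance": self.provenance}
            fh.write("# " + json.dumps(header, default=str) + "\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CurveTable":
        with open(path) as fh:
            first = fh.readline()
            kind, meta, prov = "", {}, {}
            if first.startswith("#"):
                header = json.loads(first[1:].strip())
                kind = header.get("kind", "")
                meta = header.get("meta", {})
                prov = header.get("provenance", {})
                frame = pd.read_csv(fh)
            else:
                fh.seek(0)
                frame = pd.read_csv(fh)
        return cls(frame, kind=kind, meta=meta, provenance=prov)
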