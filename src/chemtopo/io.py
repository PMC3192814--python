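"""Tabular I/O shared by the pipeline stages (TSV in, TSV/JSON out)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationRecord",
    "read_concentration_table",
    "write_concentration_table",
    "read_feature_table",
    "write_predictions",
]


@dataclass(frozen=True)
class ConcentrationRecord:
    """A measured metabolite concentration (mol/L) and its −Log10 value."""

    id: str
    concentration: float
    neg_log_c: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"{self.id}: concentration must be positive")
        if not math.isclose(self.neg_log_c, -math.log10(self.concentration), abs_tol=1e-9):
            raise ValueError(f"{self.id}: neg_log_c inconsistent with concentration")

    @classmethod
    def from_concentration(cls, met_id: str, concentration: float) -> "ConcentrationRecord":
        return cls(met_id, concentration, -math.log10(concentration))


def read_concentration_table(path: str | Path) -> list[ConcentrationRecord]:
    """TSV with columns id, concentration (mol/L); neg_log_c derived."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "concentration"} <= set(df.columns):
        raise ValueError("concentration table needs columns: id, concentration")
    return [
        ConcentrationRecord.from_concentration(str(r.id), float(r.concentration))
        for r in df.itertuples(index=False)
    ]


def write_concentration_table(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "concentration": [r.concentration for r in records],
            "neg_log_c": [r.neg_log_c for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Feature table TSV (id + numeric feature columns), indexed by id."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "id" not in df.columns:
        raise ValueError("feature table needs an 'id' column")
    df = df.set_index("id")
    return df.astype(float)


def write_predictions(ids: Sequence[str], neg_log_c_pred: Sequence[float], path: str | Path) -> None:
    """Prediction TSV: id, predicted −LogC, and the implied mol/L value."""
    pred = np.asarray(neg_log_c_pred, dtype=float)
    pd.DataFrame(
        {
            "id": list(ids),
            "neg_log_c_pred": pred,
            "concentration_pred": 10.0 ** (-pred),
        }
    ).to_csv(path, sep="\t", index=False)
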