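"""Packaged per-patient SUV measurement tables and their container.

The fixtures hold organ-level SUVmax (``table2``) and SUVmean (``table3``)
values for 10 patients measured with a commercial workstation ("MIM"), a
single 1.2 cm spherical VOI ("one VOI"), and a whole-organ contour
("contour"), plus per-patient tumor TLG at two fractional-SUVmax thresholds
(``table4``).  They are the reference surface the agreement summaries in
:mod:`petquant.compare` are validated against.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PairedMeasurementTable", "load_table_fixture", "available_fixtures"]

_FIXTURES = ("table2", "table3", "table4")


def _norm(text: str) -> str:
    """Canonical key: casefold and strip everything but letters and digits,
    so 'Breast (right)', 'Breast right' and 'breast_right' all match."""
    return re.sub(r"[^a-z0-9]", "", str(text).casefold())


@dataclass
class PairedMeasurementTable:
    """Long-format (patient, organ, method) -> value measurements.

    Each (patient, organ, method) triple appears at most once; lookups
    normalize organ and method spellings (case, punctuation, underscores).
    """

    name: str
    rows: pd.DataFrame  # columns: patient, organ, method, value [, extras]

    def __post_init__(self) -> None:
        required = {"patient", "organ", "method", "value"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"table rows missing columns: {sorted(missing)}")
        key = self.rows[["patient", "organ", "method"]].astype(str).agg("|".join, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate (patient, organ, method) entry: {dup}")

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.rows["method"]))

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.rows["organ"]))

    @property
    def patients(self) -> tuple[int, ...]:
        return tuple(dict.fromkeys(self.rows["patient"]))

    def _resolve(self, column: str, name: str) -> str:
        options = dict.fromkeys(self.rows[column])
        matches = [o for o in options if _norm(o) == _norm(name)]
        if not matches:
            raise KeyError(f"unknown {column} {name!r}; available: {list(options)}")
        return matches[0]

    def value(self, patient: int, organ: str, method: str) -> float:
        """Single measurement; organ/method names are spelling-tolerant."""
        organ = self._resolve("organ", organ)
        method = self._resolve("method", method)
        sel = self.rows[
            (self.rows["patient"] == patient)
            & (self.rows["organ"] == organ)
            & (self.rows["method"] == method)
        ]
        if sel.empty:
            raise KeyError(f"no value for patient {patient}, {organ!r}, {method!r}")
        return float(sel["value"].iloc[0])

    def paired(self, method_a: str, method_b: str, organ: str) -> pd.DataFrame:
        """Per-patient values of both methods for one organ, aligned on patient.

        Raises if either method is missing for any patient of that organ,
        listing the affected patients.
        """
        organ = self._resolve("organ", organ)
        method_a = self._resolve("method", method_a)
        method_b = self._resolve("method", method_b)
        sub = self.rows[self.rows["organ"] == organ]
        wide = sub.pivot(index="patient", columns="method", values="value")
        for m in (method_a, method_b):
            if m not in wide.columns or wide[m].isna().any():
                missing = list(wide.index) if m not in wide.columns else list(wide.index[wide[m].isna()])
                raise ValueError(f"method {m!r} missing for patients {missing} of organ {organ!r}")
        return wide[[method_a, method_b]].rename(columns={method_a: "a", method_b: "b"})


def available_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def load_table_fixture(name: str) -> PairedMeasurementTable:
    """Load a packaged measurement table (``table2``, ``table3`` or ``table4``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available fixtures: {list(_FIXTURES)}")
    with resources.files("petquant.data").joinpath(f"{name}.csv").open("r") as fh:
        rows = pd.read_csv(fh)
    rows["patient"] = rows["patient"].astype(int)
    rows["value"] = rows["value"].astype(float)
    return PairedMeasurementTable(name=name, rows=rows)
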