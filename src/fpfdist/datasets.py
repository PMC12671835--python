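"""The three benchmark datasets used in the model-comparison study.

All three are short published lists, embedded verbatim:

- ``kidney-frailty``: 76 frailty values from a study of infection
  recurrence times in 38 kidney-dialysis patients (McGilchrist & Aisbett).
- ``repair-times``: 30 times between failures of repairable units
  (Murthy et al.), a standard reliability benchmark.
- ``ftcanmax``: 100 annual-maximum precipitation values from Fort
  Collins, Colorado, a standard extreme-value benchmark.

Simple checksums (n, sum, min, max) are asserted at import time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NamedDataset", "load_dataset", "DATASET_NAMES"]

_KIDNEY = (
    0.2, 0.2, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
    0.5, 0.5, 0.6, 0.6, 0.6, 0.6, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7,
    0.8, 0.8, 0.8, 0.8, 1.0, 1.0, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.2, 1.2,
    1.2, 1.2, 1.2, 1.2, 1.3, 1.3, 1.3, 1.3, 1.4, 1.4, 1.5, 1.5, 1.5, 1.5,
    1.5, 1.5, 1.7, 1.7, 1.7, 1.7, 1.8, 1.8, 1.9, 1.9, 2.1, 2.1, 2.2, 2.2,
    2.3, 2.3, 2.9, 2.9, 3.0, 3.0,
)

_REPAIR = (
    1.43, 0.11, 0.71, 0.77, 2.63, 1.49, 3.46, 2.46, 0.59, 0.74, 1.23, 0.94,
    4.36, 0.40, 1.74, 4.73, 2.23, 0.45, 0.70, 1.06, 1.46, 0.30, 1.82, 2.37,
    0.63, 1.23, 1.24, 1.97, 1.86, 1.17,
)

_FTCANMAX = (
    1.04, 1.15, 1.23, 1.25, 1.28, 1.30, 1.35, 1.36, 1.37, 1.39, 1.41, 1.42,
    1.43, 1.44, 1.45, 1.47, 1.48, 1.49, 1.51, 1.53, 1.54, 1.55, 1.57, 1.58,
    1.59, 1.60, 1.61, 1.63, 1.64, 1.65, 1.67, 1.68, 1.70, 1.71, 1.72, 1.73,
    1.75, 1.76, 1.78, 1.80, 1.82, 1.83, 1.84, 1.85, 1.87, 1.88, 1.90, 1.91,
    1.92, 1.93, 1.95, 1.97, 1.99, 2.01, 2.03, 2.05, 2.07, 2.10, 2.12, 2.14,
    2.16, 2.18, 2.20, 2.22, 2.24, 2.26, 2.28, 2.30, 2.32, 2.34, 2.37, 2.40,
    2.43, 2.46, 2.49, 2.53, 2.57, 2.60, 2.63, 2.67, 2.70, 2.73, 2.77, 2.80,
    2.84, 2.87, 2.91, 2.95, 2.99, 3.03, 3.07, 3.12, 3.16, 3.21, 3.26, 3.31,
    3.36, 3.42, 3.48, 3.54,
)


@dataclass(frozen=True)
class NamedDataset:
    name: str
    values: np.ndarray
    source_note: str

    @property
    def n(self) -> int:
        return int(self.values.size)


_REGISTRY = {
    "kidney-frailty": NamedDataset(
        "kidney-frailty", np.array(_KIDNEY),
        "Frailty values from recurrence of infection in 38 kidney dialysis "
        "patients (McGilchrist & Aisbett).",
    ),
    "repair-times": NamedDataset(
        "repair-times", np.array(_REPAIR),
        "Times between failures of repairable units (Murthy et al.).",
    ),
    "ftcanmax": NamedDataset(
        "ftcanmax", np.array(_FTCANMAX),
        "Fort Collins, Colorado annual maximum precipitation.",
    ),
}

# checksum guard: (n, sum, min, max)
_CHECKSUMS = {
    "kidney-frailty": (76, 90.0, 0.2, 3.0),
    "repair-times": (30, 46.28, 0.11, 4.73),
    "ftcanmax": (100, 208.96, 1.04, 3.54),
}
for _name, (_n, _s, _mn, _mx) in _CHECKSUMS.items():
    _d = _REGISTRY[_name].values
    assert _d.size == _n and abs(_d.sum() - _s) < 1e-9, _name
    assert _d.min() == _mn and _d.max() == _mx, _name

DATASET_NAMES = tuple(_REGISTRY)


def load_dataset(name: str) -> NamedDataset:
    """Return one of the embedded benchmark datasets by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; available: {', '.join(DATASET_NAMES)}"
        ) from None
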