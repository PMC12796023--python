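"""Canonical shock-etiology dimensions.

Every etiology vector in the package is a length-9 binary array in this
fixed order. The order is part of the on-disk contract (CSV headers,
truth ledgers) and must never change.
"""
from __future__ import annotations

from collections.abc import Iterable

import numpy as np

ETIOLOGIES: tuple[str, ...] = (
    "septic",
    "cardiogenic",
    "hypovolemic",
    "adrenal",
    "neurogenic",
    "undifferentiated",
    "obstructive",
    "anaphylactic",
    "post_procedural",
)

N_ETIOLOGIES = len(ETIOLOGIES)

_INDEX = {name: i for i, name in enumerate(ETIOLOGIES)}


def etiology_index(name: str) -> int:
    """Position of ``name`` in the canonical order."""
    return _INDEX[name]


def vector_from_names(names: Iterable[str]) -> np.ndarray:
    """Binary vector with ones at the named etiologies."""
    vec = np.zeros(N_ETIOLOGIES, dtype=np.int8)
    for name in names:
        vec[_INDEX[name]] = 1
    return vec


def names_from_vector(vec: np.ndarray) -> tuple[str, ...]:
    """Etiology names set in ``vec``, in canonical order."""
    vec = np.asarray(vec)
    return tuple(name for i, name in enumerate(ETIOLOGIES) if vec[i])


def validate_vector(vec: np.ndarray) -> np.ndarray:
    """Check shape and binary values; returns the array as int8."""
    arr = np.asarray(vec)
    if arr.shape != (N_ETIOLOGIES,):
        raise ValueError(f"etiology vector must have shape ({N_ETIOLOGIES},), got {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("etiology vector components must be 0 or 1")
    return arr.astype(np.int8)
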