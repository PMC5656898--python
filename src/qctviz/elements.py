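"""Bundled per-element data: atomic numbers, display colors, vdW radii,
and promolecular density terms.

Tables ship as versioned JSON files under ``qctviz/data``; see the ``note``
field of each file for provenance.
"""

from __future__ import annotations

import json
import logging
from functools import lru_cache
from importlib import resources

from .units import BOHR_PER_ANGSTROM

log = logging.getLogger(__name__)

#: Fallbacks for elements missing from the bundled tables.
FALLBACK_COLOR = (0.5, 0.5, 0.5)
FALLBACK_VDW_ANGSTROM = 2.0


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("qctviz.data").joinpath(name).open("r", encoding="utf-8") as f:
        return json.load(f)


def element_table() -> dict:
    return _load("elements.json")["elements"]


def promolecular_terms() -> dict:
    return _load("promolecular_terms.json")["elements"]


def is_known_element(symbol: str) -> bool:
    return symbol in element_table()


def atomic_number(symbol: str) -> int:
    try:
        return element_table()[symbol]["Z"]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None


def element_color(symbol: str) -> tuple[float, float, float]:
    """PyMOL-style display RGB in [0,1]; gray fallback with a warning."""
    entry = element_table().get(symbol)
    if entry is None:
        log.warning("element %r not in bundled color table; using gray", symbol)
        return FALLBACK_COLOR
    return tuple(entry["color"])


def vdw_radius_angstrom(symbol: str) -> float:
    entry = element_table().get(symbol)
    if entry is None:
        log.warning("element %r not in bundled vdW table; using %.1f A",
                    symbol, FALLBACK_VDW_ANGSTROM)
        return FALLBACK_VDW_ANGSTROM
    return entry["vdw"]


def vdw_radius_bohr(symbol: str) -> float:
    return vdw_radius_angstrom(symbol) * BOHR_PER_ANGSTROM
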