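"""Loaders for the package's plain-text constants tables.

Three tables ship with the package under ``midaflux/data``:

* isotope natural abundances (per element, nominal-mass shifts),
* amino-acid residue elemental formulas,
* per-residue effective deuterium-incorporation site counts,

plus a YAML registry of GC-MS analytes (composition, effective n, channel
window). All are editable: pass a path to the loader to substitute your own
table. Loaded tables are cached.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

ELEMENTS = ("C", "H", "N", "O", "S")

# Monoisotopic masses of the lightest isotope, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}


def _data_path(name: str) -> Path:
    return Path(resources.files("midaflux").joinpath("data").joinpath(name))


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def isotope_abundances(path: str | None = None) -> dict[str, np.ndarray]:
    """Per-element single-atom isotopologue patterns.

    Returns a mapping ``element -> array`` where entry ``i`` is the
    probability of a nominal-mass shift of ``i`` for one atom. Patterns are
    renormalized so each sums to exactly 1.
    """
    p = Path(path) if path else _data_path("isotope_abundances.tsv")
    rows = _read_tsv(p)
    header, body = rows[0], rows[1:]
    if header != ["element", "shift", "abundance"]:
        raise ValidationError(f"unexpected isotope table header in {p}: {header}")
    by_elem: dict[str, dict[int, float]] = {}
    for elem, shift, ab in body:
        by_elem.setdefault(elem, {})[int(shift)] = float(ab)
    out = {}
    for elem, shifts in by_elem.items():
        arr = np.zeros(max(shifts) + 1)
        for s, a in shifts.items():
            arr[s] = a
        out[elem] = arr / arr.sum()
    return out


@lru_cache(maxsize=None)
def residue_formulas(path: str | None = None) -> dict[str, dict[str, int]]:
    """Residue (amino acid minus water) elemental compositions."""
    p = Path(path) if path else _data_path("residue_formulas.tsv")
    rows = _read_tsv(p)
    header, body = rows[0], rows[1:]
    elems = header[1:]
    return {r[0]: {e: int(v) for e, v in zip(elems, r[1:])} for r in body}


@lru_cache(maxsize=None)
def residue_site_table(path: str | None = None) -> dict[str, float]:
    """Effective deuterium-incorporation sites per residue."""
    p = Path(path) if path else _data_path("residue_deuterium_sites.tsv")
    rows = _read_tsv(p)
    return {r[0]: float(r[1]) for r in rows[1:]}


@lru_cache(maxsize=None)
def analyte_registry(path: str | None = None) -> dict[str, dict]:
    """GC-MS analyte definitions: composition, effective n, channel count."""
    p = Path(path) if path else _data_path("analytes.yaml")
    with open(p) as fh:
        reg = yaml.safe_load(fh)
    for name, entry in reg.items():
        missing = {"composition", "n_sites", "channels"} - set(entry)
        if missing:
            raise ValidationError(f"analyte {name!r} missing keys: {sorted(missing)}")
    return reg
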