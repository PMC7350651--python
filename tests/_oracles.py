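"""Independent first-principles oracles for the test suite.

Everything here is deliberately written without the package's spectrum code:
per-element spectra come from explicit multinomial enumeration over isotope
assignments, compositions are combined with explicit double loops, and the
labeling solve uses scipy's NNLS.  Only the packaged abundance JSON document
is shared, so both routes see identical constants.
"""

from __future__ import annotations

import itertools
import json
import math
from importlib import resources

import numpy as np
from scipy.optimize import nnls


def load_abundance_rows() -> dict[str, list[tuple[int, float]]]:
    """Raw [shift, probability] rows straight from the packaged JSON."""
    with resources.as_file(
        resources.files("isotrace.data") / "isotope_abundances.json"
    ) as p:
        doc = json.loads(p.read_text(encoding="utf-8"))
    return {el: [(int(s), float(pr)) for s, pr in rows] for el, rows in doc["elements"].items()}


def _compositions(total: int, bins: int):
    """All ways to distribute `total` identical atoms over `bins` isotopes."""
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, bins - 1):
            yield (first,) + rest


def element_spectrum_enum(
    element: str, count: int, max_shift: int, rows=None
) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of one element, by explicit
    multinomial enumeration."""
    rows = (rows or load_abundance_rows())[element]
    out = np.zeros(max_shift + 1)
    if count == 0:
        out[0] = 1.0
        return out
    for combo in _compositions(count, len(rows)):
        shift = sum(c * s for c, (s, _) in zip(combo, rows))
        if shift > max_shift:
            continue
        weight = math.factorial(count)
        prob = 1.0
        for c, (_, p) in zip(combo, rows):
            weight //= math.factorial(c)
            prob *= p ** c
        out[shift] += weight * prob
    return out


def composition_spectrum_enum(
    comp: dict[str, int], max_shift: int, rows=None
) -> np.ndarray:
    """Whole-composition spectrum by combining per-element enumerations with
    explicit double loops."""
    rows = rows or load_abundance_rows()
    spec = np.zeros(max_shift + 1)
    spec[0] = 1.0
    for element, count in comp.items():
        if count == 0:
            continue
        es = element_spectrum_enum(element, count, max_shift, rows)
        new = np.zeros(max_shift + 1)
        for i in range(max_shift + 1):
            if spec[i] == 0.0:
                continue
            for j in range(max_shift + 1 - i):
                new[i + j] += spec[i] * es[j]
        spec = new
    return spec


def per_atom_spectrum_enum(comp: dict[str, int], rows=None) -> np.ndarray:
    """Ultra-brute-force spectrum: iterate the cartesian product of isotope
    choices of every single atom.  Only viable for a handful of atoms."""
    rows = rows or load_abundance_rows()
    atoms = []
    for element, count in comp.items():
        atoms.extend([rows[element]] * count)
    n_max = sum(r[-1][0] for r in atoms) if atoms else 0
    out = np.zeros(n_max + 1)
    if not atoms:
        return np.array([1.0])
    for choice in itertools.product(*atoms):
        shift = sum(s for s, _ in choice)
        prob = math.prod(p for _, p in choice)
        out[shift] += prob
    return out


def oracle_correction_matrix(
    comp: dict[str, int],
    n_labelable: int,
    tracer_element: str,
    channels: int,
    label_shift: int = 1,
    rows=None,
) -> np.ndarray:
    """Correction matrix built column-by-column from whole-composition
    enumeration: for j true labels the unlabeled remainder is the composition
    with j tracer atoms deleted, and the column is its spectrum shifted up by
    j label masses."""
    rows = rows or load_abundance_rows()
    cols = np.zeros((channels, n_labelable + 1))
    for j in range(n_labelable + 1):
        remainder = dict(comp)
        remainder[tracer_element] = remainder[tracer_element] - j
        spec = composition_spectrum_enum(remainder, channels - 1, rows)
        offset = j * label_shift
        if offset < channels:
            cols[offset:, j] = spec[: channels - offset]
    return cols


def oracle_correct(raw: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Non-negative least squares solve, renormalized to fractions."""
    x, _ = nnls(matrix, np.asarray(raw, dtype=float))
    total = x.sum()
    return x / total if total > 0 else x


def random_fragment(rng: np.random.Generator, max_tracer: int = 8):
    """A random plausible GC-MS fragment composition and labelable count."""
    n_label = int(rng.integers(1, max_tracer + 1))
    comp = {
        "C": n_label + int(rng.integers(0, 10)),
        "H": int(rng.integers(1, 40)),
        "O": int(rng.integers(0, 7)),
        "N": int(rng.integers(0, 3)),
        "Si": int(rng.integers(0, 4)),
        "S": int(rng.integers(0, 2)),
    }
    comp = {el: n for el, n in comp.items() if n > 0}
    return comp, n_label
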