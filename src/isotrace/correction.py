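"""Natural isotope abundance (NIA) correction for single-tracer data.

For a fragment with total ion composition ``F`` and ``N`` labelable tracer
atoms, the correction matrix column for ``j`` true labels is the theoretical
spectrum of the composition with the ``N`` labelable atoms removed, convolved
with the natural pattern of the remaining ``N - j`` unlabeled tracer atoms,
and shifted up by ``j`` label mass units.  Measured channel intensities
``raw`` then satisfy ``M @ x = raw`` where ``x`` is the underlying labeling
distribution; we solve by ordinary least squares, clamp negative components
to zero, and renormalize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chem
from .chem import AbundanceTable
from .exceptions import AlreadyCorrectedError, UnderMeasuredError

logger = logging.getLogger(__name__)

__all__ = [
    "TracerSpec",
    "FragmentSpec",
    "CorrectionMatrix",
    "IsotopologueVector",
    "CorrectionResult",
    "build_correction_matrix",
    "correct_vector",
    "correct_dataset",
]


@dataclass(frozen=True)
class TracerSpec:
    """An isotopic tracer: element symbol plus mass shift per label (1 for
    13C, 15N, and 2H)."""

    element: str
    label_shift: int = 1

    def __post_init__(self) -> None:
        if self.label_shift < 1:
            raise ValueError("label_shift must be >= 1")

    _ALIASES = {
        "13C": ("C", 1), "C13": ("C", 1),
        "15N": ("N", 1), "N15": ("N", 1),
        "2H": ("H", 1), "H2": ("H", 1), "D": ("H", 1),
    }

    @classmethod
    def parse(cls, token: str) -> "TracerSpec":
        """Accepts tokens like ``13C``, ``C13``, ``15N``, ``2H`` or a bare
        element symbol."""
        key = token.strip()
        if key in cls._ALIASES:
            return cls(*cls._ALIASES[key])
        if key in chem.default_table():
            return cls(key, 1)
        raise ValueError(f"unrecognized tracer {token!r}")

    def __str__(self) -> str:
        return f"{self.element}+{self.label_shift}"


@dataclass(frozen=True)
class FragmentSpec:
    """A measured metabolite fragment.

    ``composition`` is the TOTAL ion formula including derivatization atoms;
    only ``n_labelable`` tracer-element atoms can carry label, all remaining
    tracer-element atoms contribute natural abundance.
    """

    name: str
    bigg_id: str = ""
    label: str = ""
    composition: dict[str, int] | None = None
    n_labelable: int = 0

    def __post_init__(self) -> None:
        if self.n_labelable < 0:
            raise ValueError(f"{self.name}: n_labelable must be >= 0")

    @property
    def correctable(self) -> bool:
        return self.composition is not None


@dataclass
class IsotopologueVector:
    """Ordered channel intensities M0..M(R-1) for one fragment in one sample."""

    fragment: str
    sample: str
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("values must be a 1-D vector of length >= 1")


@dataclass(frozen=True)
class CorrectionMatrix:
    """R x (N+1) matrix; entry [i, j] is the probability that a molecule with
    exactly j tracer labels is observed at mass shift i."""

    matrix: np.ndarray
    fragment: FragmentSpec
    tracer: TracerSpec

    @property
    def channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_labelable(self) -> int:
        return self.matrix.shape[1] - 1


def build_correction_matrix(
    frag: FragmentSpec,
    tracer: TracerSpec,
    channels: int,
    table: AbundanceTable | None = None,
) -> CorrectionMatrix:
    """Build the NIA correction matrix for ``frag`` observed over ``channels``
    mass channels.

    Requires ``channels >= n_labelable + 1`` (otherwise the system is
    underdetermined and the fragment is rejected as under-measured).
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    if frag.composition is None:
        raise ValueError(f"{frag.name}: no elemental composition")
    table = table or chem.default_table()
    n = frag.n_labelable
    in_comp = frag.composition.get(tracer.element, 0)
    if n > in_comp:
        raise ValueError(
            f"{frag.name}: {n} labelable {tracer.element} atoms exceed the "
            f"{in_comp} present in the composition"
        )
    if channels < n + 1:
        raise UnderMeasuredError(
            f"{frag.name}: {channels} measured channels cannot resolve "
            f"{n + 1} labeled states"
        )
    max_shift = channels - 1
    base_comp = dict(frag.composition)
    base_comp[tracer.element] = in_comp - n
    base = chem.composition_spectrum(base_comp, max_shift, table)
    pattern = table[tracer.element].dense()

    cols = np.zeros((channels, n + 1))
    # spectrum of the N-j unlabeled tracer atoms, built down from j = N
    unlabeled = np.zeros(max_shift + 1)
    unlabeled[0] = 1.0
    for j in range(n, -1, -1):
        col = chem.convolve(base, unlabeled, max_shift)
        offset = j * tracer.label_shift
        if offset <= max_shift:
            cols[offset:, j] = col[: channels - offset]
        unlabeled = chem.convolve(unlabeled, pattern, max_shift)
    return CorrectionMatrix(cols, frag, tracer)


@dataclass
class CorrectionResult:
    """Outcome of correcting one measured vector."""

    fractions: np.ndarray
    scale: float
    empty: bool = False


def correct_vector(raw, cm: CorrectionMatrix) -> CorrectionResult:
    """Solve ``cm.matrix @ x = raw`` by least squares; clamp negatives and
    renormalize to a labeling-fraction simplex.

    ``scale`` is the pre-normalization sum of the clamped solution (the
    corrected absolute intensity, usable for abundance work).  An all-zero
    input yields a flagged empty result, not an exception.
    """
    values = np.asarray(
        raw.values if isinstance(raw, IsotopologueVector) else raw, dtype=float
    )
    if isinstance(raw, IsotopologueVector) and raw.corrected:
        raise AlreadyCorrectedError(f"{raw.fragment}/{raw.sample} is already corrected")
    if values.shape != (cm.channels,):
        raise ValueError(
            f"vector length {values.shape} does not match {cm.channels} matrix rows"
        )
    n_states = cm.n_labelable + 1
    if not np.any(values):
        return CorrectionResult(np.zeros(n_states), 0.0, empty=True)
    x, *_ = np.linalg.lstsq(cm.matrix, values, rcond=None)
    x = np.clip(x, 0.0, None)
    scale = float(x.sum())
    if scale == 0.0:
        return CorrectionResult(np.zeros(n_states), 0.0, empty=True)
    return CorrectionResult(x / scale, scale, empty=False)


def correct_dataset(data, tracer: TracerSpec | None = None):
    """NIA-correct every fragment x sample vector of a dataset in place
    (returns the same dataset, flagged corrected).

    Fragments without a formula or with too few channels are skipped with a
    logged warning.  Correcting an already corrected dataset is rejected.
    """
    if data.corrected:
        raise AlreadyCorrectedError(
            "dataset is already natural-abundance corrected; correction is "
            "not idempotent-safe"
        )
    tracer = tracer or data.tracer
    if tracer is None:
        raise ValueError("no tracer given and none recorded on the dataset")
    table = chem.default_table()
    for fd in data.fragments.values():
        if not fd.spec.correctable:
            logger.warning("skipping %s: no elemental formula", fd.spec.name)
            continue
        try:
            cm = build_correction_matrix(fd.spec, tracer, fd.channels, table)
        except (UnderMeasuredError, ValueError) as exc:
            logger.warning("skipping %s: %s", fd.spec.name, exc)
            continue
        fractions = np.zeros_like(fd.raw.values, dtype=float)
        scales = np.zeros(fd.raw.shape[1])
        for k, sample in enumerate(fd.raw.columns):
            res = correct_vector(fd.raw[sample].to_numpy(), cm)
            if res.empty:
                logger.warning("empty measurement: %s / %s", fd.spec.name, sample)
            m = min(len(res.fractions), fractions.shape[0])
            fractions[:m, k] = res.fractions[:m]
            scales[k] = res.scale
        fd.set_corrected(fractions[: cm.n_labelable + 1], scales)
    data.corrected = True
    data.tracer = tracer
    return data
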