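"""Quantities derived from corrected counts: MIDs, enrichment, abundances,
normalization chains, group statistics, kinetic series, and cross-metabolite
comparisons."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import MissingInputError

if TYPE_CHECKING:  # pragma: no cover
    from .io import TraceDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SampleGroup",
    "GroupStat",
    "NormalizationSpec",
    "mid",
    "enrichment",
    "total_abundance",
    "abundance_frame",
    "mid_frame",
    "normalize_abundances",
    "quantitative_abundance",
    "group_stats",
    "kinetic_series",
    "compare_metabolites",
    "isotopologue_view",
    "sample_values",
]


@dataclass
class SampleGroup:
    """Named set of sample columns sharing an experimental condition."""

    name: str
    samples: list[str]
    time: float | None = None
    cell_count: float | None = None
    color: str | None = None


@dataclass
class GroupStat:
    """Mean +/- sample SD of one quantity over one group's replicates."""

    group: str
    mean: float
    sd: float
    n: int
    values: list[float] | None = None
    time: float | None = None

    @property
    def absent(self) -> bool:
        return self.n == 0


@dataclass
class NormalizationSpec:
    """Optional abundance normalization steps, applied in fixed order:
    internal standard -> cell counts -> reference group."""

    internal_standard: str | None = None
    cell_counts: dict[str, float] | None = None  # group name -> count
    reference_group: str | None = None
    standards: dict[str, tuple[float, float]] | None = None  # frag -> (amount, response)


def mid(raw_counts) -> np.ndarray | None:
    """Mass isotopomer distribution: each channel divided by the channel sum.

    Returns ``None`` for an all-zero vector (flagged empty, propagated as
    missing rather than NaN arithmetic).
    """
    values = np.asarray(
        getattr(raw_counts, "values", raw_counts), dtype=float
    ).ravel()
    if np.any(values < 0):
        raise ValueError("negative channel intensity")
    total = values.sum()
    if total == 0:
        return None
    return values / total


def enrichment(mid_vec, n_tracer_atoms: int) -> float:
    """Mole percent enrichment: sum(i * mid[i]) / N, in [0, 1]."""
    if n_tracer_atoms < 1:
        raise ValueError("n_tracer_atoms must be >= 1")
    values = np.asarray(mid_vec, dtype=float)
    if len(values) > n_tracer_atoms + 1:
        raise ValueError(
            f"MID of length {len(values)} is impossible with "
            f"{n_tracer_atoms} labelable atoms"
        )
    return float(np.arange(len(values)) @ values / n_tracer_atoms)


def total_abundance(raw_counts) -> float:
    """Sum of baseline-corrected measured channels (pre-NIA by convention)."""
    values = np.asarray(getattr(raw_counts, "values", raw_counts), dtype=float)
    if np.any(values < 0):
        raise ValueError("negative channel intensity")
    return float(values.sum())


def abundance_frame(data: "TraceDataset", basis: str = "raw") -> pd.DataFrame:
    """Per fragment x sample total abundance.

    ``basis='raw'`` sums the measured channels; ``basis='corrected'`` uses the
    corrected absolute scales instead.
    """
    if basis not in ("raw", "corrected"):
        raise ValueError("basis must be 'raw' or 'corrected'")
    rows = {}
    for name, fd in data.fragments.items():
        if basis == "corrected" and fd.scales is not None:
            rows[name] = fd.scales
        else:
            rows[name] = fd.raw.sum(axis=0)
    return pd.DataFrame(rows).T.reindex(columns=data.samples)


def mid_frame(data: "TraceDataset", fragment: str) -> pd.DataFrame:
    """Channels x samples MID fractions for one fragment.

    Corrected fractions when available, otherwise the raw channel values
    normalized per sample.  All-zero samples become NaN columns (missing).
    """
    fd = data.fragments[fragment]
    frame = fd.corrected if fd.corrected is not None else fd.raw
    sums = frame.sum(axis=0)
    return frame.div(sums.where(sums > 0), axis=1)  # all-zero samples -> NaN


def normalize_abundances(data: "TraceDataset", spec: NormalizationSpec) -> "TraceDataset":
    """Apply the abundance normalization chain and store the result on the
    dataset (``data.normalized_abundance``).

    Per sample s: A' = A / A(std, s); per group g: A'' = A' / cellcount(g);
    then, with reference group r: A''' = A'' / mean_r(A'').  Each step is
    optional; the order is fixed.  Samples in which the internal standard is
    zero are flagged (set to NaN) and excluded from group statistics.
    """
    frame = abundance_frame(data, basis=data.abundance_basis)
    if spec.internal_standard is not None:
        if spec.internal_standard not in frame.index:
            raise KeyError(f"internal standard {spec.internal_standard!r} not in dataset")
        std = frame.loc[spec.internal_standard]
        bad = std[std == 0].index.tolist()
        if bad:
            logger.warning(
                "internal standard %s is zero in samples %s; flagged missing",
                spec.internal_standard, bad,
            )
        frame = frame / std.replace(0, np.nan)
    if spec.cell_counts:
        cell_counts = spec.cell_counts
        for group in data.groups:
            if group.name not in cell_counts:
                raise MissingInputError(f"no cell count for group {group.name!r}")
            cc = cell_counts[group.name]
            if cc <= 0:
                raise ValueError(f"cell count for {group.name!r} must be > 0")
            frame[group.samples] = frame[group.samples] / cc
    if spec.reference_group is not None:
        ref = data.group(spec.reference_group)
        ref_mean = frame[ref.samples].mean(axis=1)
        frame = frame.div(ref_mean, axis=0)
    data.normalization = spec
    data.normalized_abundance = frame
    return data


def quantitative_abundance(
    data: "TraceDataset", spec: NormalizationSpec
) -> tuple[pd.DataFrame, list[str]]:
    """Single-point linear calibration: amount = A * known / response.

    Returns (amounts frame, unquantified fragment names).  Fragments without
    a usable standard (missing, or zero response) are unquantified.
    """
    standards = spec.standards or {}
    frame = abundance_frame(data, basis=data.abundance_basis)
    rows, unquantified = {}, []
    for name in frame.index:
        std = standards.get(name)
        if std is None or std[1] == 0:
            unquantified.append(name)
            continue
        known, response = std
        rows[name] = frame.loc[name] * known / response
    amounts = pd.DataFrame(rows).T
    if amounts.empty:
        amounts = pd.DataFrame(columns=frame.columns)
    return amounts, unquantified


def group_stats(
    values: Mapping[str, float | None],
    groups: Iterable[SampleGroup],
    keep_values: bool = False,
) -> list[GroupStat]:
    """Per-group mean and sample SD (ddof=1; SD is 0 for singletons).

    Missing values (``None``/NaN) are excluded with ``n`` reduced; a group
    empty after exclusions yields a flagged ``n=0`` stat.
    """
    out = []
    for group in groups:
        vals = [
            float(values[s])
            for s in group.samples
            if s in values and values[s] is not None and not math.isnan(values[s])
        ]
        if not vals:
            out.append(GroupStat(group.name, math.nan, math.nan, 0,
                                 [] if keep_values else None, group.time))
            continue
        mean = float(np.mean(vals))
        if len(vals) < 2 or len(set(vals)) == 1:
            sd = 0.0  # identical replicates: exactly zero, no float residue
        else:
            sd = float(np.std(vals, ddof=1))
        out.append(GroupStat(group.name, mean, sd, len(vals),
                             vals if keep_values else None, group.time))
    return out


def sample_values(
    data: "TraceDataset",
    fragment: str,
    quantity: str,
    isotopologue: int | None = None,
) -> dict[str, float | None]:
    """Per-sample scalar values of one quantity for one fragment.

    ``quantity`` is one of ``abundance``, ``normalized_abundance``,
    ``quantitative_abundance``, ``enrichment``, ``isotopologue_fraction``,
    ``isotopologue_abundance``.  Isotopologue quantities index by M-number
    (M0-based).
    """
    fd = data.fragments[fragment]
    if quantity == "abundance":
        return abundance_frame(data, basis=data.abundance_basis).loc[fragment].to_dict()
    if quantity == "normalized_abundance":
        if data.normalized_abundance is None:
            raise MissingInputError("abundances have not been normalized")
        return data.normalized_abundance.loc[fragment].to_dict()
    if quantity == "quantitative_abundance":
        if data.normalization is None or not data.normalization.standards:
            raise MissingInputError("quantitative standards have not been entered")
        amounts, unquantified = quantitative_abundance(data, data.normalization)
        if fragment in unquantified:
            raise MissingInputError(f"{fragment} has no usable quantitative standard")
        return amounts.loc[fragment].to_dict()

    mids = mid_frame(data, fragment)
    if quantity == "enrichment":
        if fd.spec.n_labelable < 1:
            raise MissingInputError(
                f"{fragment}: element count of tracer of interest not entered"
            )
        out = {}
        for sample in mids.columns:
            col = mids[sample].to_numpy()
            out[sample] = (
                None if np.isnan(col).any()
                else enrichment(col, fd.spec.n_labelable)
            )
        return out
    if quantity in ("isotopologue_fraction", "isotopologue_abundance"):
        if isotopologue is None:
            raise ValueError("isotopologue index required")
        if not 0 <= isotopologue < mids.shape[0]:
            raise IndexError(
                f"M{isotopologue} out of range for {fragment} "
                f"({mids.shape[0]} channels)"
            )
        frac = mids.iloc[isotopologue]
        if quantity == "isotopologue_abundance":
            frac = frac * abundance_frame(data, basis=data.abundance_basis).loc[fragment]
        return {s: (None if pd.isna(v) else float(v)) for s, v in frac.items()}
    raise ValueError(f"unknown quantity {quantity!r}")


def kinetic_series(
    data: "TraceDataset",
    fragment: str,
    quantity: str,
    isotopologue: int | None = None,
    keep_values: bool = False,
) -> list[GroupStat]:
    """Group stats ordered by ascending time point (group-name tie-break).

    Every group must carry a time point; missing ones are listed in the
    rejection.
    """
    missing = [g.name for g in data.groups if g.time is None]
    if missing:
        raise MissingInputError(f"groups without time points: {missing}")
    values = sample_values(data, fragment, quantity, isotopologue)
    stats = group_stats(values, data.groups, keep_values)
    return sorted(stats, key=lambda s: (s.time, s.group))


def compare_metabolites(
    data: "TraceDataset",
    metabolites: list[str],
    groups: list[str],
    quantity: str,
    isotopologue: int | None = None,
) -> tuple[dict[tuple[str, str], GroupStat], list[tuple[str, str]]]:
    """(metabolite x group) -> GroupStat table for grouped bar figures.

    Returns (table, skipped) where ``skipped`` lists (metabolite, reason)
    for absent metabolites or out-of-range isotopologue selections.
    """
    table: dict[tuple[str, str], GroupStat] = {}
    skipped: list[tuple[str, str]] = []
    selected_groups = [data.group(g) for g in groups]
    for met in metabolites:
        if met not in data.fragments:
            skipped.append((met, "not in dataset"))
            continue
        try:
            values = sample_values(data, met, quantity, isotopologue)
        except (IndexError, MissingInputError) as exc:
            skipped.append((met, str(exc)))
            continue
        for stat in group_stats(values, selected_groups):
            table[(met, stat.group)] = stat
    return table, skipped


def isotopologue_view(data: "TraceDataset", fragment: str, limit: int) -> pd.DataFrame:
    """Display view of a fragment's MIDs truncated to M0..M(limit-1).

    Purely a view: underlying data is unchanged and the fractions are NOT
    renormalized.
    """
    mids = mid_frame(data, fragment)
    if not 1 <= limit <= mids.shape[0]:
        raise ValueError(
            f"isotopologue limit {limit} out of range 1..{mids.shape[0]} "
            f"for {fragment}"
        )
    return mids.iloc[:limit]
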