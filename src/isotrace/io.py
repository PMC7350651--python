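"""Readers and writers: measurement CSV dialects, the workspace JSON, and
Escher map JSON; BiGG-ID mapping between data and map nodes.

CSV dialect (long format, UTF-8, comma-separated, header row first)::

    metabolite,bigg_id,formula,n_labelable,isotopologue,<sample1>,<sample2>,...

One row per fragment-channel; ``isotopologue`` is written ``M0``, ``M1``, ...
and must be contiguous from M0 within a fragment.  The uncorrected dialect
carries baseline-corrected raw counts and requires ``formula``/``n_labelable``
for correction; the corrected dialect carries NIA-corrected values (fractions
or intensities) and ignores formula requirements.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .analytics import NormalizationSpec, SampleGroup
from .correction import FragmentSpec, IsotopologueVector, TracerSpec
from .exceptions import CsvFormatError, SchemaError

logger = logging.getLogger(__name__)

WORKSPACE_SCHEMA_VERSION = 1

_FIXED_COLUMNS = ["metabolite", "bigg_id", "formula", "n_labelable", "isotopologue"]

__all__ = [
    "FragmentData",
    "DisplaySettings",
    "TraceDataset",
    "MapNode",
    "EscherMapView",
    "read_uncorrected_csv",
    "read_corrected_csv",
    "write_csv",
    "save_workspace",
    "load_workspace",
    "read_escher_map",
    "map_data_to_nodes",
]


@dataclass
class FragmentData:
    """One fragment's measurements across all samples.

    ``raw`` holds the values as uploaded (counts for uncorrected data);
    ``corrected``/``scales`` are filled by NIA correction (fraction matrix of
    shape (n_labelable+1, samples) plus per-sample absolute scales).
    """

    spec: FragmentSpec
    raw: pd.DataFrame  # index M0..M(R-1), columns = samples
    corrected: pd.DataFrame | None = None
    scales: pd.Series | None = None

    @property
    def channels(self) -> int:
        return self.raw.shape[0]

    def vector(self, sample: str, corrected: bool = False) -> IsotopologueVector:
        frame = self.corrected if corrected else self.raw
        if frame is None:
            raise ValueError(f"{self.spec.name}: no corrected values")
        return IsotopologueVector(
            self.spec.name, sample, frame[sample].to_numpy(), corrected=corrected
        )

    def set_corrected(self, fractions: np.ndarray, scales: np.ndarray) -> None:
        self.corrected = pd.DataFrame(
            fractions,
            index=[f"M{i}" for i in range(fractions.shape[0])],
            columns=self.raw.columns,
        )
        self.scales = pd.Series(scales, index=self.raw.columns)

    def equals(self, other: "FragmentData") -> bool:
        if self.spec != other.spec or not self.raw.equals(other.raw):
            return False
        for a, b in ((self.corrected, other.corrected), (self.scales, other.scales)):
            if (a is None) != (b is None):
                return False
            if a is not None and not a.equals(b):
                return False
        return True


@dataclass
class DisplaySettings:
    """Presentation state carried in the workspace."""

    metabolites_to_display: list[str] | None = None  # None = all
    isotopologue_limits: dict[str, int] = field(default_factory=dict)
    color_scheme: str = "default15"


@dataclass
class TraceDataset:
    """All fragments x samples with grouping, normalization state, and
    display settings — the unit the workspace serializes."""

    fragments: dict[str, FragmentData]
    samples: list[str]
    groups: list[SampleGroup] = field(default_factory=list)
    tracer: TracerSpec | None = None
    corrected: bool = False
    normalization: NormalizationSpec | None = None
    normalized_abundance: pd.DataFrame | None = None
    display: DisplaySettings = field(default_factory=DisplaySettings)
    abundance_basis: str = "raw"  # 'raw' or 'corrected' sums for abundance
    abundance_table_version: str = ""

    def __post_init__(self) -> None:
        if not self.abundance_table_version:
            self.abundance_table_version = chem.default_table().version
        seen: set[str] = set()
        for g in self.groups:
            dup = seen.intersection(g.samples)
            if dup:
                raise ValueError(f"samples in multiple groups: {sorted(dup)}")
            seen.update(g.samples)

    def group(self, name: str) -> SampleGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no group named {name!r}")

    def set_groups(self, groups: list[SampleGroup]) -> None:
        known = set(self.samples)
        for g in groups:
            unknown = [s for s in g.samples if s not in known]
            if unknown:
                raise ValueError(f"group {g.name!r} references unknown samples {unknown}")
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        self.groups = list(groups)
        self.__post_init__()

    def equals(self, other: "TraceDataset") -> bool:
        if (
            self.samples != other.samples
            or self.groups != other.groups
            or self.tracer != other.tracer
            or self.corrected != other.corrected
            or self.normalization != other.normalization
            or self.display != other.display
            or self.abundance_basis != other.abundance_basis
            or self.abundance_table_version != other.abundance_table_version
            or list(self.fragments) != list(other.fragments)
        ):
            return False
        if (self.normalized_abundance is None) != (other.normalized_abundance is None):
            return False
        if self.normalized_abundance is not None and not self.normalized_abundance.equals(
            other.normalized_abundance
        ):
            return False
        return all(
            self.fragments[k].equals(other.fragments[k]) for k in self.fragments
        )


def _parse_csv(path: str | Path, require_formula: bool) -> TraceDataset:
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CsvFormatError(f"{path}: no data rows") from None
    if list(table.columns[: len(_FIXED_COLUMNS)]) != _FIXED_COLUMNS:
        raise CsvFormatError(
            f"{path}: header must start with {','.join(_FIXED_COLUMNS)}; "
            f"got {','.join(table.columns[:len(_FIXED_COLUMNS)])}"
        )
    sample_cols = list(table.columns[len(_FIXED_COLUMNS):])
    if not sample_cols:
        raise CsvFormatError(f"{path}: no sample columns")
    if len(table) == 0:
        raise CsvFormatError(f"{path}: no data rows")

    dup = table.duplicated(subset=["metabolite", "isotopologue"], keep=False)
    if dup.any():
        rows = [int(i) + 2 for i in table.index[dup]]  # 1-based incl. header
        raise CsvFormatError(f"{path}: duplicate (metabolite, isotopologue) rows {rows}")

    fragments: dict[str, FragmentData] = {}
    for met, block in table.groupby("metabolite", sort=False):
        channels = []
        for row_idx, iso in block["isotopologue"].items():
            if not (iso.startswith("M") and iso[1:].isdigit()):
                raise CsvFormatError(
                    f"{path}: bad isotopologue label {iso!r} in row {row_idx + 2}"
                )
            channels.append(int(iso[1:]))
        block = block.iloc[np.argsort(channels, kind="stable")]
        if sorted(channels) != list(range(len(channels))):
            raise CsvFormatError(
                f"{path}: {met}: isotopologue channels must be contiguous from M0"
            )
        values = np.empty((len(block), len(sample_cols)))
        for j, col in enumerate(sample_cols):
            for i, (row_idx, cell) in enumerate(block[col].items()):
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise CsvFormatError(
                        f"{path}: non-numeric value {cell!r} at row "
                        f"{row_idx + 2}, column {col!r}"
                    ) from None

        first = block.iloc[0]
        formula_text = first["formula"].strip()
        composition = None
        if formula_text:
            composition = chem.parse_formula(formula_text)
        elif require_formula:
            logger.warning("%s: no formula; fragment loaded but uncorrectable", met)
        n_text = first["n_labelable"].strip()
        n_labelable = int(n_text) if n_text else 0
        spec = FragmentSpec(
            name=str(met),
            bigg_id=first["bigg_id"].strip(),
            composition=composition,
            n_labelable=n_labelable,
        )
        frame = pd.DataFrame(
            values,
            index=[f"M{i}" for i in range(len(block))],
            columns=sample_cols,
        )
        fragments[str(met)] = FragmentData(spec=spec, raw=frame)
    return TraceDataset(fragments=fragments, samples=sample_cols)


def read_uncorrected_csv(path: str | Path) -> TraceDataset:
    """Read a baseline-corrected but NIA-uncorrected counts CSV."""
    data = _parse_csv(path, require_formula=True)
    data.corrected = False
    return data


def read_corrected_csv(path: str | Path, tol: float = 1e-3) -> TraceDataset:
    """Read a pre-corrected CSV (correction operations will refuse it).

    Values whose per-sample sums deviate from 1 by more than ``tol`` are
    accepted but a renormalization warning is emitted (MIDs are always
    computed by normalizing).
    """
    data = _parse_csv(path, require_formula=False)
    data.corrected = True
    off = []
    for name, fd in data.fragments.items():
        sums = fd.raw.sum(axis=0)
        if ((sums > 0) & ((sums - 1.0).abs() > tol)).any():
            off.append(name)
    if off:
        warnings.warn(
            f"corrected values for {off} do not sum to 1 per sample; "
            "they will be renormalized when computing MIDs",
            stacklevel=2,
        )
    return data


def write_csv(data: TraceDataset, path: str | Path, corrected: bool | None = None) -> None:
    """Write the dataset in the CSV dialect.

    ``corrected=None`` writes whatever the dataset holds as primary values
    (raw counts for uncorrected data, stored values for pre-corrected data);
    ``corrected=True`` writes the NIA-corrected fractions.
    """
    if corrected is None:
        corrected = False
    rows = []
    for name, fd in data.fragments.items():
        frame = fd.raw
        if corrected and not data.corrected:
            raise ValueError("dataset has not been corrected")
        if corrected and fd.corrected is not None:
            frame = fd.corrected
        spec = fd.spec
        for i, iso in enumerate(frame.index):
            row = {
                "metabolite": name,
                "bigg_id": spec.bigg_id,
                "formula": chem.formula_to_text(spec.composition)
                if spec.composition
                else "",
                "n_labelable": spec.n_labelable,
                "isotopologue": iso,
            }
            for sample in data.samples:
                row[sample] = repr(float(frame.loc[iso, sample]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# workspace JSON


def _frame_to_json(frame: pd.DataFrame | None):
    if frame is None:
        return None
    return {
        "index": list(frame.index),
        "columns": list(frame.columns),
        "values": frame.to_numpy().tolist(),
    }


def _frame_from_json(doc) -> pd.DataFrame | None:
    if doc is None:
        return None
    return pd.DataFrame(doc["values"], index=doc["index"], columns=doc["columns"])


def save_workspace(data: TraceDataset, path: str | Path) -> None:
    """Serialize the full dataset to versioned workspace JSON (lossless)."""
    doc = {
        "schema_version": WORKSPACE_SCHEMA_VERSION,
        "abundance_table_version": data.abundance_table_version,
        "samples": data.samples,
        "corrected": data.corrected,
        "abundance_basis": data.abundance_basis,
        "tracer": None
        if data.tracer is None
        else {"element": data.tracer.element, "label_shift": data.tracer.label_shift},
        "groups": [
            {
                "name": g.name,
                "samples": g.samples,
                "time": g.time,
                "cell_count": g.cell_count,
                "color": g.color,
            }
            for g in data.groups
        ],
        "normalization": None
        if data.normalization is None
        else {
            "internal_standard": data.normalization.internal_standard,
            "cell_counts": data.normalization.cell_counts,
            "reference_group": data.normalization.reference_group,
            "standards": None
            if data.normalization.standards is None
            else {k: list(v) for k, v in data.normalization.standards.items()},
        },
        "normalized_abundance": _frame_to_json(data.normalized_abundance),
        "display": {
            "metabolites_to_display": data.display.metabolites_to_display,
            "isotopologue_limits": data.display.isotopologue_limits,
            "color_scheme": data.display.color_scheme,
        },
        "fragments": [
            {
                "name": fd.spec.name,
                "bigg_id": fd.spec.bigg_id,
                "label": fd.spec.label,
                "composition": fd.spec.composition,
                "n_labelable": fd.spec.n_labelable,
                "raw": _frame_to_json(fd.raw),
                "corrected": _frame_to_json(fd.corrected),
                "scales": None if fd.scales is None else fd.scales.to_list(),
            }
            for fd in data.fragments.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_workspace(path: str | Path) -> TraceDataset:
    """Load a workspace saved by :func:`save_workspace`."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    version = doc.get("schema_version")
    if version != WORKSPACE_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: workspace schema version {version!r} is not supported "
            f"(this build reads version {WORKSPACE_SCHEMA_VERSION})"
        )
    fragments: dict[str, FragmentData] = {}
    for fdoc in doc["fragments"]:
        spec = FragmentSpec(
            name=fdoc["name"],
            bigg_id=fdoc["bigg_id"],
            label=fdoc.get("label", ""),
            composition=fdoc["composition"],
            n_labelable=fdoc["n_labelable"],
        )
        raw = _frame_from_json(fdoc["raw"])
        fd = FragmentData(spec=spec, raw=raw)
        fd.corrected = _frame_from_json(fdoc["corrected"])
        if fdoc["scales"] is not None:
            fd.scales = pd.Series(fdoc["scales"], index=raw.columns)
        fragments[spec.name] = fd
    norm = doc["normalization"]
    data = TraceDataset(
        fragments=fragments,
        samples=doc["samples"],
        groups=[SampleGroup(**g) for g in doc["groups"]],
        tracer=None if doc["tracer"] is None else TracerSpec(**doc["tracer"]),
        corrected=doc["corrected"],
        normalization=None
        if norm is None
        else NormalizationSpec(
            internal_standard=norm["internal_standard"],
            cell_counts=norm["cell_counts"],
            reference_group=norm["reference_group"],
            standards=None
            if norm["standards"] is None
            else {k: tuple(v) for k, v in norm["standards"].items()},
        ),
        normalized_abundance=_frame_from_json(doc["normalized_abundance"]),
        display=DisplaySettings(**doc["display"]),
        abundance_basis=doc["abundance_basis"],
        abundance_table_version=doc["abundance_table_version"],
    )
    return data


# ---------------------------------------------------------------------------
# Escher maps


@dataclass(frozen=True)
class MapNode:
    node_id: str
    bigg_id: str
    x: float
    y: float
    label_x: float
    label_y: float
    name: str = ""


@dataclass
class EscherMapView:
    """Metabolite nodes and canvas extent extracted from an Escher map."""

    name: str
    nodes: list[MapNode]
    canvas: dict[str, float]


def read_escher_map(path: str | Path) -> EscherMapView:
    """Extract metabolite-type nodes from standard Escher map JSON (a
    two-element array of header + map body).

    Midmarker/multimarker nodes are excluded.  A map without metabolite
    nodes yields an empty view with a warning.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    if not (isinstance(doc, list) and len(doc) == 2 and isinstance(doc[1], dict)):
        raise SchemaError(
            f"{path}: expected a two-element [header, body] Escher map array"
        )
    header, body = doc
    if "nodes" not in body:
        raise SchemaError(f"{path}: map body has no 'nodes' section")
    nodes = []
    for node_id, node in body["nodes"].items():
        if node.get("node_type") != "metabolite":
            continue
        try:
            nodes.append(
                MapNode(
                    node_id=str(node_id),
                    bigg_id=node["bigg_id"],
                    x=float(node["x"]),
                    y=float(node["y"]),
                    label_x=float(node.get("label_x", node["x"])),
                    label_y=float(node.get("label_y", node["y"])),
                    name=node.get("name", ""),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed node {node_id!r} ({exc})") from None
    if not nodes:
        warnings.warn(f"{path}: map contains no metabolite nodes", stacklevel=2)
    canvas = body.get("canvas") or _bounding_canvas(nodes)
    return EscherMapView(
        name=str(header.get("map_name", "")) if isinstance(header, dict) else "",
        nodes=nodes,
        canvas={k: float(canvas[k]) for k in ("x", "y", "width", "height")},
    )


def _bounding_canvas(nodes: list[MapNode]) -> dict[str, float]:
    if not nodes:
        return {"x": 0.0, "y": 0.0, "width": 1000.0, "height": 1000.0}
    xs = [n.x for n in nodes]
    ys = [n.y for n in nodes]
    pad = 200.0
    return {
        "x": min(xs) - pad,
        "y": min(ys) - pad,
        "width": (max(xs) - min(xs)) + 2 * pad,
        "height": (max(ys) - min(ys)) + 2 * pad,
    }


def map_data_to_nodes(
    data: TraceDataset,
    view: EscherMapView,
    ignore_compartment: bool = False,
) -> tuple[dict[str, list[MapNode]], list[str]]:
    """Match fragments to map nodes by exact BiGG ID.

    A fragment maps to ALL nodes sharing its ID (compartment duplicates
    included); fragments with empty or unmatched IDs are returned unmapped in
    dataset order.  ``ignore_compartment`` strips a trailing ``_<tag>`` from
    both sides before matching.
    """

    def key(bigg: str) -> str:
        if ignore_compartment and "_" in bigg:
            head, _, tail = bigg.rpartition("_")
            if head and len(tail) <= 2:
                return head
        return bigg

    index: dict[str, list[MapNode]] = {}
    for node in view.nodes:
        index.setdefault(key(node.bigg_id), []).append(node)
    mapped: dict[str, list[MapNode]] = {}
    unmapped: list[str] = []
    for name, fd in data.fragments.items():
        bigg = fd.spec.bigg_id
        hits = index.get(key(bigg), []) if bigg else []
        if hits:
            mapped[name] = list(hits)
        else:
            unmapped.append(name)
    return mapped, unmapped
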