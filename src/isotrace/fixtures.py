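"""Synthetic datasets and toy Escher maps with known ground truth.

The forward model is the exact inverse of the correction path: raw channel
counts are ``scale * (M @ true_mid)`` with optional multiplicative Gaussian
noise (truncated at -1) per channel, where ``M`` is the fragment's natural
abundance correction matrix.  With zero noise, correction recovers the
planted MIDs to solver precision.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytics import NormalizationSpec, SampleGroup
from .correction import FragmentSpec, TracerSpec, build_correction_matrix
from .chem import parse_formula

__all__ = [
    "FragmentSim",
    "GroupSim",
    "SimulationSpec",
    "simulate_uncorrected",
    "make_scale_fixture",
    "make_huh7_like_fixture",
    "Huh7Fixture",
]


@dataclass(frozen=True)
class FragmentSim:
    name: str
    formula: str
    n_labelable: int
    bigg_id: str = ""


@dataclass(frozen=True)
class GroupSim:
    name: str
    n_replicates: int
    time: float | None = None
    cell_count: float | None = None


@dataclass
class SimulationSpec:
    """Ground truth for a synthetic uncorrected dataset."""

    fragments: list[FragmentSim]
    groups: list[GroupSim]
    true_mids: dict[tuple[str, str], list[float]]  # (fragment, group) -> simplex
    abundances: dict[tuple[str, str], float] = field(default_factory=dict)
    cv: float = 0.0  # multiplicative noise coefficient of variation
    seed: int = 42
    tracer: TracerSpec = field(default_factory=lambda: TracerSpec("C", 1))
    extra_channels: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for key, mid in self.true_mids.items():
            arr = np.asarray(mid, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"true MID for {key} is not a simplex")

    def sample_names(self) -> list[str]:
        return [
            f"{g.name}_{r + 1}" for g in self.groups for r in range(g.n_replicates)
        ]


def simulate_uncorrected(spec: SimulationSpec) -> str:
    """Forward-simulate raw (NIA-uncorrupted... uncorrected) counts; returns
    the uncorrected CSV dialect as text.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_names()
    rows = []
    for frag in spec.fragments:
        comp = parse_formula(frag.formula)
        channels = frag.n_labelable + 1 + spec.extra_channels
        fs = FragmentSpec(
            name=frag.name, bigg_id=frag.bigg_id,
            composition=comp, n_labelable=frag.n_labelable,
        )
        cm = build_correction_matrix(fs, spec.tracer, channels)
        columns: dict[str, np.ndarray] = {}
        for group in spec.groups:
            mid = np.asarray(spec.true_mids[(frag.name, group.name)], dtype=float)
            if len(mid) != frag.n_labelable + 1:
                raise ValueError(
                    f"true MID for ({frag.name}, {group.name}) must have "
                    f"{frag.n_labelable + 1} entries"
                )
            scale = spec.abundances.get((frag.name, group.name), 1e6)
            clean = scale * (cm.matrix @ mid)
            for r in range(group.n_replicates):
                noise = rng.normal(0.0, spec.cv, size=channels) if spec.cv else 0.0
                factors = np.maximum(1.0 + noise, 0.0)  # truncated at -1
                columns[f"{group.name}_{r + 1}"] = clean * factors
        for i in range(channels):
            row = {
                "metabolite": frag.name,
                "bigg_id": frag.bigg_id,
                "formula": frag.formula,
                "n_labelable": frag.n_labelable,
                "isotopologue": f"M{i}",
            }
            for s in samples:
                row[s] = repr(float(columns[s][i]))
            rows.append(row)
    buf = _stdio.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()


def groups_from_spec(spec: SimulationSpec) -> list[SampleGroup]:
    return [
        SampleGroup(
            name=g.name,
            samples=[f"{g.name}_{r + 1}" for r in range(g.n_replicates)],
            time=g.time,
            cell_count=g.cell_count,
        )
        for g in spec.groups
    ]


def _random_simplex(rng: np.random.Generator, k: int) -> list[float]:
    x = rng.dirichlet(np.ones(k))
    return x.tolist()


def make_scale_fixture(
    n_samples: int = 100, n_groups: int = 40, seed: int = 0
) -> SimulationSpec:
    """Large-scale smoke fixture: ``n_samples`` spread over ``n_groups``."""
    if n_samples < n_groups:
        raise ValueError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_samples, n_groups)
    groups = [
        GroupSim(f"g{i:02d}", base + (1 if i < extra else 0)) for i in range(n_groups)
    ]
    fragments = [
        FragmentSim("cit459", "C20H39O6Si3", 6, "cit_c"),
        FragmentSim("suc289", "C12H25O4Si2", 4, "succ_c"),
        FragmentSim("lac261", "C11H25O3Si2", 3, "lac__L_c"),
    ]
    true_mids = {
        (f.name, g.name): _random_simplex(rng, f.n_labelable + 1)
        for f in fragments
        for g in groups
    }
    return SimulationSpec(
        fragments=fragments, groups=groups, true_mids=true_mids,
        cv=0.03, seed=seed,
    )


@dataclass
class Huh7Fixture:
    """Two-condition TCA fixture with a planted reductive-carboxylation
    signature (M5 citrate elevated in the low-oxygen condition)."""

    csv_text: str
    map_json: list
    groups: list[SampleGroup]
    normalization: NormalizationSpec
    spec: SimulationSpec
    m5_citrate_ratio: float  # planted Hypoxia/Normoxia ground-truth ratio


# fixed ground-truth MIDs: Hypoxia M5 citrate is ~12x the Normoxia fraction
_HUH7_MIDS = {
    ("cit459", "Normoxia"): [0.42, 0.05, 0.14, 0.06, 0.30, 0.01, 0.02],
    ("cit459", "Hypoxia"): [0.38, 0.05, 0.16, 0.07, 0.18, 0.12, 0.04],
    ("akg346", "Normoxia"): [0.30, 0.03, 0.05, 0.04, 0.08, 0.50],
    ("akg346", "Hypoxia"): [0.25, 0.03, 0.06, 0.05, 0.09, 0.52],
    ("suc289", "Normoxia"): [0.38, 0.05, 0.13, 0.08, 0.36],
    ("suc289", "Hypoxia"): [0.40, 0.06, 0.15, 0.09, 0.30],
    ("fum287", "Normoxia"): [0.40, 0.04, 0.14, 0.06, 0.36],
    ("fum287", "Hypoxia"): [0.44, 0.05, 0.16, 0.07, 0.28],
    ("mal419", "Normoxia"): [0.42, 0.04, 0.13, 0.06, 0.35],
    ("mal419", "Hypoxia"): [0.46, 0.05, 0.15, 0.07, 0.27],
    ("glu432", "Normoxia"): [0.25, 0.03, 0.06, 0.05, 0.10, 0.51],
    ("glu432", "Hypoxia"): [0.22, 0.03, 0.07, 0.06, 0.11, 0.51],
    ("gln431", "Normoxia"): [0.12, 0.01, 0.02, 0.02, 0.03, 0.80],
    ("gln431", "Hypoxia"): [0.10, 0.01, 0.02, 0.02, 0.03, 0.82],
    ("pyr174", "Normoxia"): [0.88, 0.04, 0.03, 0.05],
    ("pyr174", "Hypoxia"): [0.85, 0.05, 0.04, 0.06],
    ("lac261", "Normoxia"): [0.90, 0.03, 0.03, 0.04],
    ("lac261", "Hypoxia"): [0.86, 0.05, 0.04, 0.05],
    ("nor260", "Normoxia"): [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    ("nor260", "Hypoxia"): [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
}

_HUH7_FRAGMENTS = [
    FragmentSim("cit459", "C20H39O6Si3", 6, "cit_c"),
    FragmentSim("akg346", "C16H31NO3Si2", 5, "akg_c"),
    FragmentSim("suc289", "C12H25O4Si2", 4, "succ_c"),
    FragmentSim("fum287", "C12H23O4Si2", 4, "fum_c"),
    FragmentSim("mal419", "C18H39O5Si3", 4, "mal__L_c"),
    FragmentSim("glu432", "C19H42NO4Si3", 5, "glu__L_c"),
    FragmentSim("gln431", "C19H43N2O3Si3", 5, "gln__L_c"),
    FragmentSim("pyr174", "C6H12NO2Si", 3, "pyr_c"),
    FragmentSim("lac261", "C11H25O3Si2", 3, "lac__L_c"),
    FragmentSim("nor260", "C11H26NO2Si2", 5, ""),  # internal standard, unmapped
]

# raw-count scales; TCA pools drop in the low-oxygen condition
_HUH7_SCALES = {"Normoxia": 2.0e6, "Hypoxia": 1.2e6}


def toy_escher_map(fragments: list[FragmentSim]) -> list:
    """Minimal standard-schema Escher map covering the fixture's BiGG IDs."""
    nodes: dict[str, dict] = {}
    x, y = 600.0, 400.0
    nid = 1
    for frag in fragments:
        if not frag.bigg_id:
            continue
        nodes[str(nid)] = {
            "node_type": "metabolite",
            "bigg_id": frag.bigg_id,
            "name": frag.name,
            "x": x,
            "y": y,
            "label_x": x + 12.0,
            "label_y": y - 12.0,
        }
        nid += 1
        x += 700.0
        if x > 2800.0:
            x, y = 600.0, y + 600.0
    # a midmarker, which metabolite extraction must skip
    nodes[str(nid)] = {"node_type": "midmarker", "x": 100.0, "y": 100.0}
    body = {
        "nodes": nodes,
        "reactions": {},
        "canvas": {"x": 0.0, "y": 0.0, "width": 3600.0, "height": 2400.0},
    }
    header = {
        "map_name": "toy_tca",
        "map_id": "toy_tca_v1",
        "map_description": "synthetic TCA layout for tests",
        "homepage": "",
        "schema": "https://escher.github.io/escher/jsonschema/1-0-0#",
    }
    return [header, body]


def make_huh7_like_fixture(
    seed: int = 42, cv: float = 0.03, n_replicates: int = 3
) -> Huh7Fixture:
    """Two groups (Normoxia/Hypoxia) of TCA + glycolysis fragments with a
    norvaline-like internal standard and the cell counts 638333 / 668750.

    Ground truth plants an M5-citrate Hypoxia/Normoxia MID ratio well above
    6-fold, the qualitative signature of reductive carboxylation."""
    groups = [
        GroupSim("Normoxia", n_replicates, cell_count=638333.0),
        GroupSim("Hypoxia", n_replicates, cell_count=668750.0),
    ]
    abundances = {
        (f.name, g.name): _HUH7_SCALES[g.name] for f in _HUH7_FRAGMENTS for g in groups
    }
    # the spiked standard has identical true abundance in every sample
    for g in groups:
        abundances[("nor260", g.name)] = 5.0e5
    spec = SimulationSpec(
        fragments=_HUH7_FRAGMENTS,
        groups=groups,
        true_mids={k: list(v) for k, v in _HUH7_MIDS.items()},
        abundances=abundances,
        cv=cv,
        seed=seed,
    )
    ratio = (
        _HUH7_MIDS[("cit459", "Hypoxia")][5] / _HUH7_MIDS[("cit459", "Normoxia")][5]
    )
    norm = NormalizationSpec(
        internal_standard="nor260",
        cell_counts={"Normoxia": 638333.0, "Hypoxia": 668750.0},
        reference_group="Normoxia",
    )
    return Huh7Fixture(
        csv_text=simulate_uncorrected(spec),
        map_json=toy_escher_map(_HUH7_FRAGMENTS),
        groups=groups_from_spec(spec),
        normalization=norm,
        spec=spec,
        m5_citrate_ratio=ratio,
    )


def write_fixture(fixture: Huh7Fixture, directory) -> dict[str, str]:
    """Materialize a fixture to ``directory``; returns the file paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": str(directory / "uncorrected.csv"),
        "map": str(directory / "map.json"),
        "groups": str(directory / "groups.json"),
    }
    Path(paths["csv"]).write_text(fixture.csv_text, encoding="utf-8")
    Path(paths["map"]).write_text(json.dumps(fixture.map_json, indent=1), encoding="utf-8")
    groups_doc = {
        "groups": [
            {
                "name": g.name,
                "samples": g.samples,
                "time": g.time,
                "cell_count": g.cell_count,
            }
            for g in fixture.groups
        ]
    }
    Path(paths["groups"]).write_text(json.dumps(groups_doc, indent=1), encoding="utf-8")
    return paths
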