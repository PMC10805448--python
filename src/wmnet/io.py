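"""File formats and run configuration.

Everything is delimited text so artifacts are diffable: 90x90 whitespace
matrices (also the BrainNet Viewer .edge format), subject CSVs, per-subject
streamline TSVs, BrainNet Viewer .node exports, YAML run configuration, and a
JSON reproducibility manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import N_REGIONS, NodeCoordinates
from .cohort import CohortParams, GroupParams, SubjectRecord
from .metrics import HubTable
from .network import ConnectivityMatrix, StreamlineSummary

SUBJECT_COLUMNS = ["subject_id", "group", "age", "gender", "duration", "onset",
                   "verbal_iq", "performance_iq"]
STREAMLINE_COLUMNS = ["region_i", "region_j", "streamline_count", "mean_fa"]


# ---------------------------------------------------------------------------
# matrices (.edge is exactly this format)
# ---------------------------------------------------------------------------

def write_matrix(path, values: np.ndarray | ConnectivityMatrix) -> None:
    if isinstance(values, ConnectivityMatrix):
        values = values.values
    np.savetxt(path, np.asarray(values, float), fmt="%.17g", delimiter="\t")


def read_matrix(path, subject_id: str = "", kind: str | None = None,
                expect_square: bool = True) -> ConnectivityMatrix | np.ndarray:
    """Read a whitespace/tab-delimited matrix.

    Returns a ConnectivityMatrix when ``kind`` is given (inferring FA_bin/FA_wei
    is deliberately not attempted), otherwise the raw array.
    """
    rows: list[list[float]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell") from exc
    if not rows:
        raise ValueError(f"{path.name}: empty matrix file")
    width = len(rows[0])
    for lineno, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ValueError(
                f"{path.name}:{lineno}: expected {width} columns, got {len(r)}")
    values = np.asarray(rows, dtype=float)
    if expect_square and values.shape[0] != values.shape[1]:
        raise ValueError(f"{path.name}: matrix is {values.shape[0]}x{values.shape[1]}, "
                         "expected square")
    if kind is None:
        return values
    return ConnectivityMatrix(subject_id, kind, values)


# ---------------------------------------------------------------------------
# subjects
# ---------------------------------------------------------------------------

def write_subjects(path, records: list[SubjectRecord]) -> None:
    from .cohort import subjects_to_frame

    subjects_to_frame(records).to_csv(path, index=False)


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing column(s): {', '.join(missing)}")
    bad = set(df["group"].unique()) - {"patient", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# streamline summaries
# ---------------------------------------------------------------------------

def write_streamlines(path, streamlines: list[StreamlineSummary]) -> None:
    df = pd.DataFrame([{
        "region_i": s.region_i, "region_j": s.region_j,
        "streamline_count": s.streamline_count, "mean_fa": s.mean_fa,
    } for s in streamlines])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_streamlines(path) -> list[StreamlineSummary]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STREAMLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"streamline table missing column(s): {', '.join(missing)}")
    return [
        StreamlineSummary(int(r.region_i), int(r.region_j),
                          int(r.streamline_count), float(r.mean_fa))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# BrainNet Viewer export
# ---------------------------------------------------------------------------

def export_brainnet_node(path, coords: NodeCoordinates, hubs: HubTable,
                         labels: list[str]) -> None:
    """.node file: x y z color size label; size tracks degree, color marks hubs."""
    if len(labels) != N_REGIONS:
        raise ValueError("need one label per region")
    with open(path, "w") as fh:
        for i in range(N_REGIONS):
            x, y, z = coords.xyz[i]
            color = 2 if hubs.is_hub[i] else 1
            size = hubs.mean_degree[i]
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{color}\t{size:.3f}\t{labels[i]}\n")


export_brainnet_edge = write_matrix


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the output directory."""

    cohort: CohortParams = field(default_factory=CohortParams)
    weight_to_length: str = "reciprocal"
    n_null: int = 100
    swaps_per_edge: int = 10
    fa_threshold: float = 0.2
    min_count: int = 1
    sd_multiplier: float = 1.0
    q_level: float = 0.05
    seed: int = 0
    compute_sigma: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.q_level < 1:
            raise ValueError("q_level must lie in (0, 1)")
        if not 0 <= self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in [0, 1)")


def _cohort_to_dict(p: CohortParams) -> dict:
    d = dataclasses.asdict(p)
    for key in ("affected_regions", "hub_regions", "piq_regions", "viq_regions"):
        d[key] = list(d[key])
    return d


def _cohort_from_dict(d: dict) -> CohortParams:
    d = dict(d)
    for key in ("patients", "controls"):
        if key in d and isinstance(d[key], dict):
            d[key] = GroupParams(**d[key])
    for key in ("affected_regions", "hub_regions", "piq_regions", "viq_regions"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortParams(**d)


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["cohort"] = _cohort_to_dict(cfg.cohort)
    return d


def save_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path=None) -> RunConfig:
    """Load a YAML run configuration; with no path, the shipped default."""
    if path is None:
        resource = importlib.resources.files("wmnet.data").joinpath("default_config.yaml")
        with importlib.resources.as_file(resource) as p:
            raw = yaml.safe_load(p.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    raw = raw or {}
    cohort = _cohort_from_dict(raw.pop("cohort", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"cohort"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(cohort=cohort, **raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, cfg: RunConfig, seed: int, stage: str,
                   artifacts: list[str]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": config_to_dict(cfg),
        "artifacts": sorted(artifacts),
        "versions": {
            "wmnet": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
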