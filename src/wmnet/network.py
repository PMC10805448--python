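"""Construction of FA-weighted and binary structural networks.

Edges come from deterministic-tractography streamline summaries: for each region
pair the number of reconstructed streamlines and the mean fractional anisotropy
(FA) along them.  An edge enters the network when at least ``min_count``
streamlines connect the pair and the mean FA strictly exceeds the FA threshold
(default 0.2, the conventional white-matter cut-off).  The weighted network
(FA_wei) carries mean FA as edge weight; the binary network (FA_bin) carries 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .atlas import N_REGIONS, RegionAtlas

DEFAULT_FA_THRESHOLD = 0.2
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class StreamlineSummary:
    """Streamline bundle between one region pair (i < j)."""

    region_i: int
    region_j: int
    streamline_count: int
    mean_fa: float

    def __post_init__(self) -> None:
        if self.region_i == self.region_j:
            raise ValueError("self-connections are not allowed")
        if not (1 <= self.region_i <= N_REGIONS and 1 <= self.region_j <= N_REGIONS):
            raise ValueError(
                f"region indices must be in 1..{N_REGIONS}: "
                f"({self.region_i}, {self.region_j})"
            )
        if self.region_i > self.region_j:
            raise ValueError("region_i must be < region_j")
        if self.streamline_count < 0:
            raise ValueError("streamline_count must be non-negative")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError(f"mean_fa must be in [0, 1], got {self.mean_fa}")


@dataclass
class ConnectivityMatrix:
    """A 90x90 structural network for one subject.

    ``kind`` is ``"FA_wei"`` (weights are mean FA) or ``"FA_bin"`` (0/1).
    """

    subject_id: str
    kind: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("FA_wei", "FA_bin"):
            raise ValueError(f"kind must be FA_wei or FA_bin, got {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 2:
            raise ValueError(f"matrix must be square (n >= 2), got {v.shape}")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.values, 1)))

    def degrees(self) -> np.ndarray:
        """Binary nodal degree: number of nonzero entries per row."""
        return (self.values != 0).sum(axis=1).astype(int)

    def is_weighted(self) -> bool:
        return self.kind == "FA_wei"


def build_networks(
    streamlines: Iterable[StreamlineSummary],
    atlas: RegionAtlas,
    subject_id: str = "",
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    min_count: int = 1,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Build the (FA_wei, FA_bin) pair from streamline summaries.

    The edge rule is strict: an edge exists iff ``streamline_count >= min_count``
    and ``mean_fa > fa_threshold``.  Bundles at exactly the threshold are dropped.
    Duplicate region pairs are an error, not silently merged.
    """
    if not 0.0 <= fa_threshold < 1.0:
        raise ValueError("fa_threshold must be in [0, 1)")
    n = len(atlas)
    wei = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for s in streamlines:
        if not isinstance(s, StreamlineSummary):
            s = StreamlineSummary(*s)
        key = (s.region_i, s.region_j)
        if key in seen:
            raise ValueError(f"duplicate streamline record for region pair {key}")
        seen.add(key)
        if s.streamline_count >= min_count and s.mean_fa > fa_threshold:
            i, j = s.region_i - 1, s.region_j - 1
            wei[i, j] = wei[j, i] = s.mean_fa
    binary = (wei > 0).astype(float)
    return (
        ConnectivityMatrix(subject_id, "FA_wei", wei),
        ConnectivityMatrix(subject_id, "FA_bin", binary),
    )


def validate_matrix(matrix: ConnectivityMatrix) -> list[str]:
    """Return the list of violated network invariants (empty when valid).

    Checks symmetry (tolerance 1e-9), zero diagonal, and weight range:
    FA_bin entries in {0, 1}; FA_wei nonzero entries in (0.2, 1].
    Never mutates the input.
    """
    v = matrix.values
    if v.shape != (N_REGIONS, N_REGIONS):
        raise ValueError(f"expected a {N_REGIONS}x{N_REGIONS} matrix, got {v.shape}")
    report: list[str] = []
    asym = np.abs(v - v.T).max()
    if asym > SYMMETRY_TOL:
        report.append(f"asymmetric: max |A - A.T| = {asym:.3g}")
    if np.abs(np.diag(v)).max() > 0:
        report.append("nonzero diagonal")
    nz = v[v != 0]
    if matrix.kind == "FA_bin":
        if not np.all(np.isin(nz, [1.0])):
            report.append("FA_bin entries must be 0 or 1")
    else:
        if nz.size and (nz.min() <= DEFAULT_FA_THRESHOLD or nz.max() > 1.0):
            report.append(
                f"FA_wei nonzero weights must lie in ({DEFAULT_FA_THRESHOLD}, 1]: "
                f"range [{nz.min():.3g}, {nz.max():.3g}]"
            )
    return report
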