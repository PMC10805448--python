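"""The 90-region AAL parcellation used as network nodes.

The atlas divides the cerebrum (cerebellum excluded) into 90 regions, 45 per
hemisphere, following the usual AAL convention that odd indices are left-hemisphere
and even indices their right homologues.  Each region carries a lobe label
(central/frontal/temporal/parietal/occipital/limbic/insula/subcortical) and a
cytoarchitectonic class (primary/association/paralimbic/subcortical) used when
reporting hubs.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_REGIONS = 90

LOBES = frozenset(
    {"central", "frontal", "temporal", "parietal", "occipital", "limbic",
     "insula", "subcortical"}
)
CLASSES = frozenset({"primary", "association", "paralimbic", "subcortical"})


@dataclass(frozen=True)
class RegionAtlas:
    """Immutable table of the 90 network nodes.

    Attributes
    ----------
    table : pandas.DataFrame
        Indexed by the 1-based region index, columns
        ``name, abbreviation, hemisphere, lobe, class``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) != N_REGIONS:
            raise ValueError(f"atlas must have exactly {N_REGIONS} regions, got {len(t)}")
        if list(t.index) != list(range(1, N_REGIONS + 1)):
            raise ValueError("atlas index must be 1..90 in order")
        if t["abbreviation"].duplicated().any():
            raise ValueError("duplicate region abbreviations")
        odd = t.index % 2 == 1
        if not ((t.loc[odd, "hemisphere"] == "L").all()
                and (t.loc[~odd, "hemisphere"] == "R").all()):
            raise ValueError("odd indices must be left hemisphere, even indices right")
        bad_lobe = set(t["lobe"]) - LOBES
        if bad_lobe:
            raise ValueError(f"unknown lobe labels: {sorted(bad_lobe)}")
        bad_cls = set(t["class"]) - CLASSES
        if bad_cls:
            raise ValueError(f"unknown class labels: {sorted(bad_cls)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def abbreviations(self) -> list[str]:
        return list(self.table["abbreviation"])

    @property
    def lobes(self) -> pd.Series:
        return self.table["lobe"]

    def index_of(self, abbreviation: str) -> int:
        """1-based region index for an abbreviation such as ``'HIP_L'``."""
        hits = self.table.index[self.table["abbreviation"] == abbreviation]
        if len(hits) == 0:
            raise KeyError(abbreviation)
        return int(hits[0])

    def indices_of(self, abbreviations) -> list[int]:
        return [self.index_of(a) for a in abbreviations]


@dataclass(frozen=True)
class NodeCoordinates:
    """Millimetre (x, y, z) positions of the 90 nodes.

    The shipped coordinate fixture is synthetic: left/right homologues are mirrored
    in x and regions cluster by lobe, which is all the distance-dependent generator
    and the .node export need.
    """

    xyz: np.ndarray = field(repr=False)  # (90, 3)

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (N_REGIONS, 3):
            raise ValueError(f"coordinates must be (90, 3), got {xyz.shape}")
        left, right = xyz[0::2], xyz[1::2]
        if not (np.allclose(left[:, 0], -right[:, 0])
                and np.allclose(left[:, 1:], right[:, 1:])):
            raise ValueError("left/right homologues must be mirrored in x")
        object.__setattr__(self, "xyz", xyz)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (90, 90)."""
        d = self.xyz[:, None, :] - self.xyz[None, :, :]
        return np.sqrt((d ** 2).sum(axis=2))


def _data_path(name: str):
    return importlib.resources.files("wmnet.data").joinpath(name)


def load_aal90() -> RegionAtlas:
    """Load the shipped 90-region AAL atlas fixture."""
    with importlib.resources.as_file(_data_path("aal90_atlas.csv")) as p:
        table = pd.read_csv(p, index_col="index")
    return RegionAtlas(table)


def load_coordinates() -> NodeCoordinates:
    """Load the shipped synthetic node coordinates."""
    with importlib.resources.as_file(_data_path("aal90_coords_synthetic.csv")) as p:
        df = pd.read_csv(p, index_col="index").sort_index()
    return NodeCoordinates(df[["x", "y", "z"]].to_numpy(float))
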