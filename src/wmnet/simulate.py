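"""Synthetic structural-connectome generation.

No generative model is observable from a measured cohort, so the simulator
adopts a distance-dependent, hemisphere/lobe-modular geometric graph as the
population template: an affinity kernel decays exponentially with Euclidean
inter-node distance and is elevated within hemispheres and lobes and for
homotopic (left-right homologue) pairs; after Sinkhorn balancing, each node
connects to its top-k kernel neighbours (Gumbel-jittered), with an elevated
per-node target for a configured set of hub regions so degree-based hub
detection has a stable, anatomically plausible, well-separated target.  This
construction yields small-world topology (clustering well above degree-matched
chance at near-random path length) at realistic sparsity with a tight
background degree distribution.

Edge weights are FA-like: 0.2 plus an exponential excess, so the weight
distribution has appreciable mass just above the FA > 0.2 edge threshold.
That is what lets the planted patient effect act on *topology*: multiplying
affected-region edges by ``fa_attenuation`` (optionally deepening with disease
duration) pushes part of them below threshold, lowering patient degree and
efficiency the way the downstream analysis expects to detect.

Per-subject randomness is spawned deterministically from the cohort seed and
the subject ordinal, so any subject can be regenerated in isolation.
"""
from __future__ import annotations

import numpy as np

from .atlas import N_REGIONS, NodeCoordinates, RegionAtlas
from .cohort import CohortParams, SubjectRecord, generate_clinical_cohort
from .network import ConnectivityMatrix, StreamlineSummary, build_networks

# template model constants (not exposed in CohortParams; the single
# density_calibration knob scales the per-node edge targets)
DISTANCE_SCALE_MM = 40.0      # exponential decay scale of the affinity kernel
INTRA_HEMISPHERE_FACTOR = 1.5
SAME_LOBE_FACTOR = 2.0
HOMOTOPIC_FACTOR = 6.0        # left-right homologue pairs
HUB_DEGREE_RATIO = 2.8        # hub per-node edge target relative to baseline
BASE_TARGET_DEGREE = 8.0      # non-hub per-node edge target at calibration 1
WEIGHT_EXCESS_SHAPE = 2.0     # Gamma shape of the FA excess above 0.2
WEIGHT_EXCESS_SCALE = 0.065   # Gamma scale (mean excess 0.13)
TEMPLATE_JITTER = 0.1         # Gumbel noise scale of neighbour selection
SINKHORN_ITERATIONS = 25      # kernel balancing so no node is over-popular
SUBJECT_NOISE_RATIO = 0.5     # shared (per-subject) FA offset, as a fraction
                              # of edge_noise_sd; gives realistic between-
                              # subject variance in global metrics
MIN_FA = 1e-3


def _affinity_kernel(atlas: RegionAtlas, coords: NodeCoordinates) -> np.ndarray:
    """Pairwise affinity: distance decay with hemisphere/lobe/homotopy structure."""
    d = coords.distances()
    k = np.exp(-d / DISTANCE_SCALE_MM)
    hemi = np.array([1 if h == "L" else 0 for h in atlas.table["hemisphere"]])
    k[hemi[:, None] == hemi[None, :]] *= INTRA_HEMISPHERE_FACTOR
    lobe = atlas.table["lobe"].to_numpy()
    k[lobe[:, None] == lobe[None, :]] *= SAME_LOBE_FACTOR
    idx = np.arange(N_REGIONS)
    homotopic = (idx[:, None] // 2 == idx[None, :] // 2) & (idx[:, None] != idx[None, :])
    k[homotopic] *= HOMOTOPIC_FACTOR
    np.fill_diagonal(k, 0.0)
    # Sinkhorn-balance so no region is globally over-attractive: neighbour
    # choice then reflects relative geometry, and degree excess concentrates
    # on the regions whose per-node targets are deliberately raised
    for _ in range(SINKHORN_ITERATIONS):
        k = k / k.sum(axis=1, keepdims=True)
        k = k / k.sum(axis=0, keepdims=True)
    np.fill_diagonal(k, 0.0)
    return k


def generate_template_network(atlas: RegionAtlas, coords: NodeCoordinates,
                              params: CohortParams | None = None,
                              seed: int | None = None) -> ConnectivityMatrix:
    """Draw the population-template weighted network for one cohort.

    Each node connects to its top-k affinity neighbours (Gumbel-jittered so the
    selection is stochastic but concentrated), with k set per node:
    ``density_calibration * BASE_TARGET_DEGREE`` for ordinary regions and
    ``HUB_DEGREE_RATIO`` times that for configured hub regions.  The union of
    the per-node selections is the template; the kernel's geometry supplies
    clustering and modular structure, the per-node targets keep the degree
    profile tight so hubs separate cleanly from the background.

    Returns a symmetric, zero-diagonal FA_wei matrix with weights in (0.2, 1].
    Raising ``density_calibration`` (with everything else fixed) never removes
    an edge; at its maximum the template is the complete graph.
    """
    p = params or CohortParams()
    if seed is None:
        seed = p.seed
    if coords.xyz.shape[0] != len(atlas):
        raise ValueError("coordinate table must cover all atlas regions")
    rng = np.random.default_rng((seed, 1))
    kernel = _affinity_kernel(atlas, coords)

    targets = np.full(N_REGIONS, p.density_calibration * BASE_TARGET_DEGREE)
    targets[[r - 1 for r in p.hub_regions]] *= HUB_DEGREE_RATIO
    targets = np.minimum(targets, N_REGIONS - 1)
    # fractional targets: floor everywhere, distribute the remainder as single
    # extra picks (largest-remainder, random tie-break) so the density response
    # to the calibration knob is continuous rather than stepping at half-integers
    k_per_node = np.floor(targets).astype(int)
    frac = targets - k_per_node
    n_extra = int(round(frac.sum()))
    if n_extra:
        tie = rng.permutation(N_REGIONS)
        take = np.lexsort((tie, -frac))[:n_extra]
        k_per_node[take] += 1
    k_per_node = np.minimum(k_per_node, N_REGIONS - 1)

    scores = np.log(kernel, where=kernel > 0,
                    out=np.full_like(kernel, -np.inf))
    scores = scores + TEMPLATE_JITTER * rng.gumbel(size=kernel.shape)
    np.fill_diagonal(scores, -np.inf)
    order = np.argsort(scores, axis=1)[:, ::-1]
    adj = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    rows = np.repeat(np.arange(N_REGIONS), k_per_node)
    cols = np.concatenate([order[i, :k] for i, k in enumerate(k_per_node)]) \
        if k_per_node.any() else np.array([], dtype=int)
    adj[rows, cols] = True
    adj |= adj.T  # union-symmetrise

    excess = np.minimum(rng.gamma(WEIGHT_EXCESS_SHAPE, WEIGHT_EXCESS_SCALE,
                                  (N_REGIONS, N_REGIONS)), 0.8)
    excess = np.triu(excess, 1)
    excess = excess + excess.T
    w = np.where(adj, 0.2 + excess, 0.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix("template", "FA_wei", w)


def _subject_multipliers(template: ConnectivityMatrix, subject: SubjectRecord,
                         params: CohortParams) -> np.ndarray:
    """Per-edge FA multiplier encoding the planted clinical effects."""
    n = template.n_nodes
    node_mult = np.ones(n)
    if subject.group == "patient":
        if subject.duration is None:
            raise ValueError("patient record lacks duration")
        att = params.fa_attenuation * max(
            0.0, 1.0 - params.duration_slope * subject.duration)
        for r in params.affected_regions:
            node_mult[r - 1] *= att
    # IQ coupling, z-scored against the subject's own group parameters
    grp = params.patients if subject.group == "patient" else params.controls
    if params.iq_coupling:
        if grp.piq_sd > 0:
            z = (subject.performance_iq - grp.piq_mean) / grp.piq_sd
            for r in params.piq_regions:
                node_mult[r - 1] *= max(0.0, 1.0 + params.iq_coupling * z)
        if grp.viq_sd > 0:
            z = (subject.verbal_iq - grp.viq_mean) / grp.viq_sd
            for r in params.viq_regions:
                node_mult[r - 1] *= max(0.0, 1.0 + params.iq_coupling * z)
    # an edge takes the stronger modulation of its two endpoints
    return np.minimum.outer(node_mult, node_mult)


def generate_subject_streamlines(template: ConnectivityMatrix,
                                 subject: SubjectRecord,
                                 params: CohortParams,
                                 seed: int | None = None,
                                 ordinal: int = 0) -> list[StreamlineSummary]:
    """One streamline-summary record per template edge for one subject.

    mean FA = planted multiplier x template weight + Gaussian jitter, clipped
    to (0, 1]; streamline counts are Poisson with a weight-dependent mean and
    at least 1 (the template edge was, by construction, reconstructed).
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng((seed, 2 + ordinal))
    mult = _subject_multipliers(template, subject, params)
    iu, ju = np.nonzero(np.triu(template.values, 1))
    w = template.values[iu, ju] * mult[iu, ju]
    if params.edge_noise_sd:
        offset = rng.normal(0.0, SUBJECT_NOISE_RATIO * params.edge_noise_sd)
        w = w + offset + rng.normal(0.0, params.edge_noise_sd, w.size)
    fa = np.clip(w, MIN_FA, 1.0)
    counts = 1 + rng.poisson(2.0 + 40.0 * np.maximum(
        template.values[iu, ju] - 0.2, 0.0))
    return [
        StreamlineSummary(int(i + 1), int(j + 1), int(c), float(f))
        for i, j, c, f in zip(iu, ju, counts, fa)
    ]


def simulate_cohort(params: CohortParams | None = None, seed: int | None = None,
                    atlas: RegionAtlas | None = None,
                    coords: NodeCoordinates | None = None):
    """Generate a full cohort: subject records and per-subject streamlines.

    Returns ``(records, streamlines_by_subject, template)`` where
    ``streamlines_by_subject`` maps subject_id to its streamline summaries.
    """
    from .atlas import load_aal90, load_coordinates

    p = params or CohortParams()
    if seed is None:
        seed = p.seed
    atlas = atlas or load_aal90()
    coords = coords or load_coordinates()
    records = generate_clinical_cohort(p, seed)
    template = generate_template_network(atlas, coords, p, seed)
    streamlines = {
        r.subject_id: generate_subject_streamlines(template, r, p, seed, ordinal=k)
        for k, r in enumerate(records)
    }
    return records, streamlines, template


def simulate_networks(params: CohortParams | None = None, seed: int | None = None,
                      atlas: RegionAtlas | None = None,
                      coords: NodeCoordinates | None = None):
    """Convenience: cohort records plus built (FA_wei, FA_bin) matrices."""
    from .atlas import load_aal90

    atlas = atlas or load_aal90()
    records, streamlines, template = simulate_cohort(params, seed, atlas, coords)
    networks = {
        sid: build_networks(sl, atlas, subject_id=sid)
        for sid, sl in streamlines.items()
    }
    return records, networks, template
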