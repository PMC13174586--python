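"""Intra-chain subdomain detection from the PAE structure.

A well-packed domain shows low mutual PAE among its residues; two
domains connected by a flexible linker show high PAE across the
boundary. The detector exploits this with a deterministic density-based
segmentation:

1. an intra-chain residue pair (i, j) with |i − j| > 2 *qualifies* when
   the symmetrized PAE, mean(pae[i,j], pae[j,i]), is at or below
   ``pae_cutoff``;
2. a cut is placed between residues r and r+1 when the density of
   qualifying pairs in the ``boundary_window`` × ``boundary_window``
   square spanning the boundary falls below ``boundary_density``;
3. segments (adjacent or not) whose inter-segment qualifying density
   reaches ``merge_density`` are merged transitively, so discontinuous
   domains come out as interval unions;
4. regions shorter than ``min_length`` are dropped.

Pairwise interface metrics between two detected regions reuse the
inter-chain machinery unchanged, treating each region's residue set as a
pseudo-chain (e.g. to score autoinhibitory intra-chain contacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .interface_metrics import (
    ChainPairMetrics,
    MetricParams,
    compute_actifptm,
    compute_clis,
    compute_ilis,
    compute_ipsae,
    compute_lis,
    identify_lir,
)
from .prediction_io import PredictionRecord
from .structure_io import ContactSet, contacts_between_indices

__all__ = [
    "SubdomainParams",
    "SubdomainPartition",
    "detect_subdomains",
    "subdomain_pair_metrics",
]

_DIAGONAL_EXCLUSION = 2  # |i-j| <= 2 pairs are trivially confident; ignore them


@dataclass(frozen=True)
class SubdomainParams:
    """Detection knobs; all residue indices are chain-local and 0-based."""

    pae_cutoff: float = 12.0
    min_length: int = 20
    boundary_window: int = 10
    boundary_density: float = 0.2
    merge_density: float = 0.5

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.boundary_window < 1:
            raise ValueError("min_length and boundary_window must be >= 1")


@dataclass
class SubdomainPartition:
    """Ordered regions of one chain; each region is a union of half-open
    [start, end) intervals in 0-based chain-local indices."""

    chain_id: str
    regions: list[tuple[tuple[int, int], ...]]
    params_used: SubdomainParams

    def region_indices(self, k: int) -> np.ndarray:
        return np.concatenate(
            [np.arange(s, e) for s, e in self.regions[k]]
        ) if self.regions[k] else np.array([], dtype=int)

    def describe(self) -> list[str]:
        return [
            "+".join(f"{s}-{e - 1}" for s, e in region) for region in self.regions
        ]


def _qualifying_matrix(pae_block: np.ndarray, pae_cutoff: float) -> np.ndarray:
    sym = 0.5 * (pae_block + pae_block.T)
    n = pae_block.shape[0]
    offsets = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return (sym <= pae_cutoff) & (offsets > _DIAGONAL_EXCLUSION)


def _boundary_cuts(qual: np.ndarray, params: SubdomainParams) -> list[int]:
    """Indices r such that a cut falls between r and r+1."""
    n = qual.shape[0]
    w = params.boundary_window
    cuts = []
    for r in range(n - 1):
        i0, i1 = max(0, r - w + 1), r + 1
        j0, j1 = r + 1, min(n, r + 1 + w)
        square = qual[i0:i1, j0:j1]
        if square.size and square.mean() < params.boundary_density:
            cuts.append(r)
    return cuts


def _merge_segments(
    segments: list[tuple[int, int]], qual: np.ndarray, merge_density: float
) -> list[list[tuple[int, int]]]:
    """Union-find over segments on inter-segment qualifying density."""
    parent = list(range(len(segments)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(segments)):
        for b in range(a + 1, len(segments)):
            (s0, e0), (s1, e1) = segments[a], segments[b]
            block = qual[s0:e0, s1:e1]
            if block.size and block.mean() >= merge_density:
                parent[find(a)] = find(b)
    groups: dict[int, list[tuple[int, int]]] = {}
    for k, seg in enumerate(segments):
        groups.setdefault(find(k), []).append(seg)
    # keep chain order by first interval start
    return sorted(groups.values(), key=lambda ivs: ivs[0][0])


def _coalesce(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Fuse abutting intervals so re-merged neighbors read as one span."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return tuple(out)


def detect_subdomains(
    record: PredictionRecord, chain_id: str, params: SubdomainParams = SubdomainParams()
) -> SubdomainPartition:
    """Deterministic PAE-density segmentation of one chain into subdomains."""
    idx = record.structure.chain_indices(chain_id)
    block = record.confidence.pae[np.ix_(idx, idx)]
    qual = _qualifying_matrix(block, params.pae_cutoff)
    n = block.shape[0]
    cuts = _boundary_cuts(qual, params)
    bounds = [0] + [r + 1 for r in cuts] + [n]
    segments = [(s, e) for s, e in zip(bounds[:-1], bounds[1:]) if e > s]
    merged = _merge_segments(segments, qual, params.merge_density)
    regions = [
        _coalesce(ivs)
        for ivs in merged
        if sum(e - s for s, e in ivs) >= params.min_length
    ]
    return SubdomainPartition(chain_id=chain_id, regions=regions, params_used=params)


def subdomain_pair_metrics(
    record: PredictionRecord,
    partition: SubdomainPartition,
    region_i: int,
    region_j: int,
    params: MetricParams = MetricParams(),
) -> ChainPairMetrics:
    """Interface metrics between two detected regions of the same chain.

    Regions are treated as pseudo-chains named ``<chain>[k]``; residue
    sets in the result are global PAE indices, as for real chain pairs.
    """
    if region_i == region_j:
        raise ValueError("region_i and region_j must differ")
    chain_offset = record.structure.chain_indices(partition.chain_id)
    idx_a = chain_offset[partition.region_indices(region_i)]
    idx_b = chain_offset[partition.region_indices(region_j)]
    if np.intersect1d(idx_a, idx_b).size:
        raise AssertionError("partition regions overlap; internal invariant violated")
    pae = record.confidence.pae
    label_a = f"{partition.chain_id}[{region_i}]"
    label_b = f"{partition.chain_id}[{region_j}]"
    contacts = ContactSet(
        chain_a=label_a,
        chain_b=label_b,
        pairs=contacts_between_indices(record.structure, idx_a, idx_b, params.contact_cutoff),
        cutoff_angstrom=params.contact_cutoff,
    )
    lis, pairs = compute_lis(pae, idx_a, idx_b, params)
    clis, cpairs = compute_clis(pae, idx_a, idx_b, contacts, params)
    lir_a, lir_b, clir_a, clir_b = identify_lir(pae, idx_a, idx_b, contacts, params)
    return ChainPairMetrics(
        chain_a=label_a,
        chain_b=label_b,
        lis=lis,
        clis=clis,
        ilis=compute_ilis(lis, clis),
        ipsae=compute_ipsae(pae, idx_a, idx_b, params),
        actifptm=compute_actifptm(pae, idx_a, idx_b, contacts, params),
        iptm_reported=None,
        iptm_is_global=False,
        lir_a=lir_a,
        lir_b=lir_b,
        clir_a=clir_a,
        clir_b=clir_b,
        qualifying_pairs=pairs,
        contact_qualifying_pairs=cpairs,
        contacts=contacts,
    )
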