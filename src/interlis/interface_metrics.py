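"""Per-chain-pair interface confidence metrics from the PAE matrix.

The metrics quantify how confidently a prediction places two chains
relative to each other, using local (per-residue-pair) information rather
than a single global score:

* **LIS** — mean of the linear transform ``(cutoff - PAE) / cutoff`` over
  all directed inter-chain residue pairs with ``PAE <= cutoff``
  (default 12 Å). The transform maps PAE 0 to 1 and PAE >= cutoff to 0.
* **cLIS** — LIS restricted to pairs whose residues are additionally in
  Cβ–Cβ contact (<= 8 Å).
* **iLIS** — geometric mean ``sqrt(LIS * cLIS)``, a single score that is
  zero unless the confident pairs are backed by actual contacts.
* **LIR / cLIR** — the residues participating in at least one qualifying
  (respectively contact-qualifying) pair; the predicted interface.
* **ipSAE** — a TM-score-style statistic: for each residue, TM terms
  ``1 / (1 + (PAE/d0)^2)`` are averaged over its cross-chain partners with
  PAE below a stricter cutoff (default 10 Å, strict inequality), with the
  TM length scale d0 set from the partner count; the pair score is the
  best residue in the best direction.
* **actifpTM** — a pTM-style score evaluated only over contact-defined
  interface residues, with a single d0 from the interface size.

All metrics are pure functions of the PAE matrix, the chain index sets
and the contact set; empty qualifying sets yield exactly 0 so score
matrices are always fully populated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from .structure_io import ContactSet, StructureModel, compute_contacts

if TYPE_CHECKING:  # pragma: no cover
    from .prediction_io import PredictionRecord

__all__ = [
    "MetricParams",
    "ChainPairMetrics",
    "ScoreMatrix",
    "local_score",
    "compute_lis",
    "compute_clis",
    "compute_ilis",
    "identify_lir",
    "compute_ipsae",
    "compute_actifptm",
    "compute_pair_metrics",
    "compute_score_matrix",
    "tm_d0",
]


@dataclass(frozen=True)
class MetricParams:
    """Cutoffs for the interface metrics (all in Å).

    ``pae_cutoff`` gates LIS/cLIS/LIR/cLIR (inclusive), ``contact_cutoff``
    the Cβ contact distance (inclusive), ``ipsae_pae_cutoff`` the ipSAE
    partner selection (strict, mirroring its source convention).
    ``lis_averaging`` selects whether LIS averages over the union of both
    directed blocks (default) or averages the two per-block means.
    """

    pae_cutoff: float = 12.0
    contact_cutoff: float = 8.0
    ipsae_pae_cutoff: float = 10.0
    lis_averaging: str = "union"  # or "per_block"

    def __post_init__(self) -> None:
        if min(self.pae_cutoff, self.contact_cutoff, self.ipsae_pae_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")
        if self.lis_averaging not in ("union", "per_block"):
            raise ValueError(f"unknown lis_averaging {self.lis_averaging!r}")


@dataclass
class ChainPairMetrics:
    """Everything computed for one unordered chain pair."""

    chain_a: str
    chain_b: str
    lis: float
    clis: float
    ilis: float
    ipsae: float
    actifptm: float
    iptm_reported: Optional[float]
    iptm_is_global: bool
    lir_a: frozenset[int]
    lir_b: frozenset[int]
    clir_a: frozenset[int]
    clir_b: frozenset[int]
    qualifying_pairs: frozenset[tuple[int, int]]
    contact_qualifying_pairs: frozenset[tuple[int, int]]
    contacts: ContactSet

    def swapped(self) -> "ChainPairMetrics":
        """The same metrics with the chain roles exchanged."""
        return ChainPairMetrics(
            chain_a=self.chain_b,
            chain_b=self.chain_a,
            lis=self.lis,
            clis=self.clis,
            ilis=self.ilis,
            ipsae=self.ipsae,
            actifptm=self.actifptm,
            iptm_reported=self.iptm_reported,
            iptm_is_global=self.iptm_is_global,
            lir_a=self.lir_b,
            lir_b=self.lir_a,
            clir_a=self.clir_b,
            clir_b=self.clir_a,
            qualifying_pairs=self.qualifying_pairs,
            contact_qualifying_pairs=self.contact_qualifying_pairs,
            contacts=self.contacts.transposed(),
        )


@dataclass
class ScoreMatrix:
    """All-pairs metrics of a multi-subunit complex.

    ``cells`` is keyed by unordered chain pairs in file order; lookup via
    :meth:`cell` is symmetric.
    """

    chain_ids: list[str]
    cells: dict[tuple[str, str], ChainPairMetrics]

    def cell(self, chain_a: str, chain_b: str) -> ChainPairMetrics:
        if (chain_a, chain_b) in self.cells:
            return self.cells[(chain_a, chain_b)]
        if (chain_b, chain_a) in self.cells:
            return self.cells[(chain_b, chain_a)].swapped()
        raise KeyError(f"no cell for chain pair {chain_a!r}, {chain_b!r}")

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.cells.keys())


def local_score(pae_value: float | np.ndarray, pae_cutoff: float) -> float | np.ndarray:
    """Linear local-interaction probability: (cutoff - PAE)/cutoff, floored at 0."""
    arr = np.asarray(pae_value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("PAE values must be non-negative")
    out = np.clip((pae_cutoff - arr) / pae_cutoff, 0.0, 1.0)
    return float(out) if np.isscalar(pae_value) or arr.ndim == 0 else out


def _check_index_sets(pae: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> None:
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("index sets must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("index sets overlap")
    n = pae.shape[0]
    if pae.ndim != 2 or pae.shape[1] != n:
        raise ValueError(f"PAE matrix must be square, got {pae.shape}")
    if idx_a.max() >= n or idx_b.max() >= n or idx_a.min() < 0 or idx_b.min() < 0:
        raise ValueError("index out of PAE bounds")


def _directed_pairs(idx_a: np.ndarray, idx_b: np.ndarray, mask_ab: np.ndarray,
                    mask_ba: np.ndarray) -> frozenset[tuple[int, int]]:
    ia, jb = np.nonzero(mask_ab)
    ib, ja = np.nonzero(mask_ba)
    return frozenset(
        itertools.chain(
            zip(idx_a[ia].tolist(), idx_b[jb].tolist()),
            zip(idx_b[ib].tolist(), idx_a[ja].tolist()),
        )
    )


def compute_lis(
    pae: np.ndarray, idx_a, idx_b, params: MetricParams = MetricParams()
) -> tuple[float, frozenset[tuple[int, int]]]:
    """LIS and the directed qualifying pairs over both off-diagonal blocks."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    _check_index_sets(pae, idx_a, idx_b)
    block_ab = pae[np.ix_(idx_a, idx_b)]
    block_ba = pae[np.ix_(idx_b, idx_a)]
    mask_ab = block_ab <= params.pae_cutoff
    mask_ba = block_ba <= params.pae_cutoff
    pairs = _directed_pairs(idx_a, idx_b, mask_ab, mask_ba)
    if not pairs:
        return 0.0, pairs
    scores_ab = local_score(block_ab[mask_ab], params.pae_cutoff)
    scores_ba = local_score(block_ba[mask_ba], params.pae_cutoff)
    if params.lis_averaging == "per_block":
        means = [b.mean() for b in (scores_ab, scores_ba) if b.size]
        return float(np.mean(means)), pairs
    all_scores = np.concatenate([np.atleast_1d(scores_ab), np.atleast_1d(scores_ba)])
    return float(all_scores.mean()), pairs


def compute_clis(
    pae: np.ndarray, idx_a, idx_b, contacts: ContactSet,
    params: MetricParams = MetricParams(),
) -> tuple[float, frozenset[tuple[int, int]]]:
    """Contact-restricted LIS over qualifying pairs that are also Cβ contacts."""
    _, pairs = compute_lis(pae, idx_a, idx_b, params)
    contact_pairs = frozenset(p for p in pairs if contacts.contains(*p))
    if not contact_pairs:
        return 0.0, contact_pairs
    vals = np.array([local_score(pae[i, j], params.pae_cutoff) for i, j in contact_pairs])
    if params.lis_averaging == "per_block":
        idx_a_set = set(np.asarray(idx_a, dtype=int).tolist())
        per_dir = [
            [local_score(pae[i, j], params.pae_cutoff) for i, j in contact_pairs
             if (i in idx_a_set) == forward]
            for forward in (True, False)
        ]
        means = [np.mean(d) for d in per_dir if d]
        return float(np.mean(means)), contact_pairs
    return float(vals.mean()), contact_pairs


def compute_ilis(lis: float, clis: float) -> float:
    """Integrated LIS: geometric mean of LIS and cLIS."""
    if not (0.0 <= lis <= 1.0 and 0.0 <= clis <= 1.0):
        raise ValueError(f"LIS/cLIS must lie in [0,1], got {lis}, {clis}")
    return math.sqrt(lis * clis)


def identify_lir(
    pae: np.ndarray, idx_a, idx_b, contacts: ContactSet,
    params: MetricParams = MetricParams(),
) -> tuple[frozenset[int], frozenset[int], frozenset[int], frozenset[int]]:
    """LIR and cLIR residue sets (global indices) for both chains."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    _, pairs = compute_lis(pae, idx_a, idx_b, params)
    _, cpairs = compute_clis(pae, idx_a, idx_b, contacts, params)
    a_set, b_set = set(idx_a.tolist()), set(idx_b.tolist())

    def split(pp: frozenset[tuple[int, int]]) -> tuple[frozenset[int], frozenset[int]]:
        members = {i for p in pp for i in p}
        return frozenset(members & a_set), frozenset(members & b_set)

    lir_a, lir_b = split(pairs)
    clir_a, clir_b = split(cpairs)
    return lir_a, lir_b, clir_a, clir_b


def tm_d0(n: int) -> float:
    """TM-score normalization length for n scored residues, clamped to >= 1."""
    return max(1.0, 1.24 * (max(n, 16) - 15) ** (1.0 / 3.0) - 1.8)


def compute_ipsae(
    pae: np.ndarray, idx_a, idx_b, params: MetricParams = MetricParams()
) -> float:
    """ipSAE: best per-residue mean TM term over sub-cutoff partners, both directions."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    _check_index_sets(pae, idx_a, idx_b)

    def directed(src: np.ndarray, dst: np.ndarray) -> float:
        block = pae[np.ix_(src, dst)]
        qual = block < params.ipsae_pae_cutoff
        best = 0.0
        for row, mask in zip(block, qual):
            n_i = int(mask.sum())
            if n_i == 0:
                continue
            d0 = tm_d0(n_i)
            score = float(np.mean(1.0 / (1.0 + (row[mask] / d0) ** 2)))
            best = max(best, score)
        return best

    return max(directed(idx_a, idx_b), directed(idx_b, idx_a))


def compute_actifptm(
    pae: np.ndarray, idx_a, idx_b, contacts: ContactSet,
    params: MetricParams = MetricParams(),
) -> float:
    """actifpTM: pTM-style score over the contact-defined interface residues."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    _check_index_sets(pae, idx_a, idx_b)
    a_set, b_set = set(idx_a.tolist()), set(idx_b.tolist())
    members = {i for p in contacts.pairs for i in p}
    iface_a = sorted(members & a_set)
    iface_b = sorted(members & b_set)
    n = len(iface_a) + len(iface_b)
    if n == 0:
        return 0.0
    d0 = tm_d0(n)
    best = 0.0
    for src, dst in ((iface_a, iface_b), (iface_b, iface_a)):
        for i in src:
            terms = 1.0 / (1.0 + (pae[i, dst] / d0) ** 2)
            best = max(best, float(terms.mean()))
    return best


def compute_pair_metrics(
    record: "PredictionRecord", chain_a: str, chain_b: str,
    params: MetricParams = MetricParams(),
) -> ChainPairMetrics:
    """All interface metrics for one chain pair of a prediction."""
    model = record.structure
    pae = record.confidence.pae
    idx_a = model.chain_indices(chain_a)
    idx_b = model.chain_indices(chain_b)
    contacts = compute_contacts(model, chain_a, chain_b, params.contact_cutoff)
    lis, pairs = compute_lis(pae, idx_a, idx_b, params)
    clis, cpairs = compute_clis(pae, idx_a, idx_b, contacts, params)
    ilis = compute_ilis(lis, clis)
    lir_a, lir_b, clir_a, clir_b = identify_lir(pae, idx_a, idx_b, contacts, params)
    ipsae = compute_ipsae(pae, idx_a, idx_b, params)
    actifptm = compute_actifptm(pae, idx_a, idx_b, contacts, params)
    iptm, is_global = record.confidence.iptm_for_pair(chain_a, chain_b)
    return ChainPairMetrics(
        chain_a=chain_a,
        chain_b=chain_b,
        lis=lis,
        clis=clis,
        ilis=ilis,
        ipsae=ipsae,
        actifptm=actifptm,
        iptm_reported=iptm,
        iptm_is_global=is_global,
        lir_a=lir_a,
        lir_b=lir_b,
        clir_a=clir_a,
        clir_b=clir_b,
        qualifying_pairs=pairs,
        contact_qualifying_pairs=cpairs,
        contacts=contacts,
    )


def compute_score_matrix(
    record: "PredictionRecord", params: MetricParams = MetricParams()
) -> ScoreMatrix:
    """Metrics for every unordered chain pair, chains in file order."""
    chain_ids = record.structure.chain_ids
    if len(chain_ids) < 2:
        raise ValueError(
            "score matrix needs at least 2 chains; for single-chain records "
            "use the subdomains module"
        )
    cells = {
        (a, b): compute_pair_metrics(record, a, b, params)
        for a, b in itertools.combinations(chain_ids, 2)
    }
    return ScoreMatrix(chain_ids=chain_ids, cells=cells)
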