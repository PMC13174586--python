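"""Per-residue intra-chain confidence profiles.

Two profile kinds are supported: the residue-level intra-chain LIS
(how confidently a residue is placed relative to the rest of its own
chain, computed from the residue's PAE row) and pLDDT. Profiles from
several models of the same job can be aggregated into a mean ± sample
standard deviation envelope, and a dimer-derived profile can be
subtracted from a monomer-derived one to locate residues that gain or
lose folding confidence upon dimerization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConsistencyError
from .interface_metrics import MetricParams, local_score
from .prediction_io import PredictionRecord

__all__ = [
    "ResidueProfile",
    "ProfileEnsemble",
    "intra_chain_lis_profile",
    "plddt_profile",
    "aggregate_profiles",
    "compare_profiles",
]


@dataclass
class ResidueProfile:
    chain_id: str
    values: np.ndarray
    kind: str  # "intra_lis" | "plddt"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("intra_lis", "plddt"):
            raise ValueError(f"unknown profile kind {self.kind!r}")


@dataclass
class ProfileEnsemble:
    per_model: dict[str, ResidueProfile]
    mean: np.ndarray
    sd: np.ndarray


def intra_chain_lis_profile(
    record: PredictionRecord, chain_id: str, params: MetricParams = MetricParams()
) -> ResidueProfile:
    """Per-residue intra-chain LIS from each residue's PAE row.

    Value i = mean of local_score(pae[i, j]) over same-chain partners j != i
    with pae[i, j] <= pae_cutoff; 0 when no partner qualifies. Rows (not
    the symmetrized matrix) are used — rows are what PAE plots display.
    """
    idx = record.structure.chain_indices(chain_id)
    block = record.confidence.pae[np.ix_(idx, idx)]
    n = len(idx)
    values = np.zeros(n)
    for i in range(n):
        row = np.delete(block[i], i)
        qual = row <= params.pae_cutoff
        if qual.any():
            values[i] = float(np.mean(local_score(row[qual], params.pae_cutoff)))
    return ResidueProfile(chain_id=chain_id, values=values, kind="intra_lis")


def plddt_profile(record: PredictionRecord, chain_id: str) -> ResidueProfile:
    idx = record.structure.chain_indices(chain_id)
    return ResidueProfile(chain_id=chain_id, values=record.confidence.plddt[idx], kind="plddt")


def profile_for(record: PredictionRecord, chain_id: str, kind: str,
                params: MetricParams = MetricParams()) -> ResidueProfile:
    if kind == "intra_lis":
        return intra_chain_lis_profile(record, chain_id, params)
    if kind == "plddt":
        return plddt_profile(record, chain_id)
    raise ValueError(f"unknown profile kind {kind!r}")


def aggregate_profiles(
    records: Sequence[PredictionRecord], chain_id: str, kind: str = "intra_lis",
    params: MetricParams = MetricParams(),
) -> ProfileEnsemble:
    """Position-wise mean and sample (n−1) standard deviation across models.

    A single model yields an all-zero SD vector rather than NaN.
    """
    if not records:
        raise ValueError("need at least one record")
    profiles = {r.model_name: profile_for(r, chain_id, kind, params) for r in records}
    lengths = {p.values.size for p in profiles.values()}
    if len(lengths) != 1:
        raise ConsistencyError(f"models disagree on chain {chain_id} length: {sorted(lengths)}")
    stack = np.vstack([profiles[name].values for name in sorted(profiles)])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    return ProfileEnsemble(per_model=profiles, mean=mean, sd=sd)


def compare_profiles(dimer_profile: ResidueProfile, monomer_profile: ResidueProfile) -> np.ndarray:
    """delta = dimer − monomer, positive where confidence is gained on dimerization.

    No alignment is attempted: the profiles must already share length and
    kind (database monomer/dimer predictions share sequence numbering).
    """
    if dimer_profile.kind != monomer_profile.kind:
        raise ValueError(
            f"profile kinds differ: {dimer_profile.kind} vs {monomer_profile.kind}"
        )
    if dimer_profile.values.size != monomer_profile.values.size:
        raise ValueError(
            f"profile lengths differ: {dimer_profile.values.size} vs "
            f"{monomer_profile.values.size}"
        )
    return dimer_profile.values - monomer_profile.values
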