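import numpy as np
import pytest

from interlis.fixtures import (
    FixtureSpec,
    PlantedInterface,
    make_complex_fixture,
    make_monomer_fixture,
)
from interlis.prediction_io import ConfidenceData, PredictionRecord
from interlis.structure_io import ChainRecord, ResidueRecord, StructureModel

PAE_CEILING = 31.75


def build_model(coords_by_chain: dict[str, np.ndarray]) -> StructureModel:
    """StructureModel straight from coordinates, bypassing file parsing."""
    chains = []
    gidx = 0
    for chain_id, coords in coords_by_chain.items():
        residues = []
        for i, xyz in enumerate(coords):
            residues.append(
                ResidueRecord(
                    author_seq_num=i + 1,
                    residue_name="ALA",
                    rep_coord=tuple(float(v) for v in xyz),
                    rep_atom="CB",
                    global_index=gidx,
                )
            )
            gidx += 1
        chains.append(ChainRecord(chain_id=chain_id, residues=residues))
    return StructureModel(model_id="1", chains=chains, source_format="mmcif")


def random_record(
    rng: np.random.Generator, n_chains: int = 2, n_per_chain: int = 40
) -> PredictionRecord:
    """Random coordinates (some in contact) and random asymmetric PAE."""
    coords = {
        chr(ord("A") + k): rng.normal(0.0, 6.0, size=(n_per_chain, 3))
        for k in range(n_chains)
    }
    model = build_model(coords)
    n = model.n_residues
    pae = rng.uniform(0.0, PAE_CEILING, size=(n, n))
    np.fill_diagonal(pae, 0.0)
    plddt = np.round(rng.uniform(30.0, 99.0, size=n), 2)
    return PredictionRecord(
        job_id="random",
        model_name="model_0",
        platform="af3",
        structure=model,
        confidence=ConfidenceData(pae=pae, plddt=plddt),
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Two chains, one fully-in-contact 5x5 interface block at PAE 4."""
    spec = FixtureSpec(
        n_chains=2,
        residues_per_chain=30,
        interface_pairs=(PlantedInterface("A", (0, 5), "B", (0, 5), 4.0, True),),
        seed=11,
    )
    records, truth = make_complex_fixture(spec)
    return records[0], truth, spec


@pytest.fixture(scope="session")
def mixed_fixture():
    """A contact interface plus a confident-but-non-contact block."""
    spec = FixtureSpec(
        n_chains=2,
        residues_per_chain=30,
        interface_pairs=(
            PlantedInterface("A", (0, 5), "B", (0, 5), 4.0, True),
            PlantedInterface("A", (10, 13), "B", (10, 13), 10.0, False),
        ),
        seed=12,
    )
    records, truth = make_complex_fixture(spec)
    return records[0], truth, spec


@pytest.fixture(scope="session")
def monomer_fixture():
    record, truth = make_monomer_fixture(
        contact_patch=((10, 15), (100, 105), 4.0)
    )
    return record, truth
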