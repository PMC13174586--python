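"""Synthetic prediction bundles with known ground truth.

Every other module is exercised against bundles built here: poly-alanine
chains with planted interface patches, a planted PAE matrix, and planted
pLDDT, wrapped in any of the six supported platform dialects. Geometry
is deliberately minimal — chains sit on ideal-helix lanes 40 Å apart
(rise 1.5 Å, 100°/residue), and each planted *in-contact* patch is
re-placed as two tight parallel residue rows 3 Å apart whose every
cross-pair lies within 7 Å, while non-contact material stays ≥ 15 Å
separated. Realistic error statistics are a non-goal; the fixtures are
structural and format stand-ins with closed-form expected metrics.

Planted pLDDT is quantized to 2 decimals and coordinates to 3 decimals,
the precision the PDB text format carries, so every dialect round-trips
losslessly.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np

from .errors import GenerationError
from .interface_metrics import MetricParams
from .prediction_io import ConfidenceData, PredictionBundle, PredictionRecord
from .structure_io import StructureModel, parse_structure_details

__all__ = [
    "PlantedInterface",
    "FixtureSpec",
    "FixtureTruth",
    "make_complex_fixture",
    "make_monomer_fixture",
    "write_dialect",
]

PAE_CEILING = 31.75  # common PAE encoding ceiling; jittered values are capped here
_LANE_SPACING = 40.0
_PATCH_OFFSET = 3.0
_PATCH_Z0 = 100.0
_PATCH_Z_STEP = 30.0
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)


@dataclass(frozen=True)
class PlantedInterface:
    """One planted PAE block between two chain-local residue ranges.

    Ranges are half-open ``[start, end)``. When ``in_contact`` the two
    ranges are additionally placed within Cβ contact distance.
    """

    chain_a: str
    range_a: tuple[int, int]
    chain_b: str
    range_b: tuple[int, int]
    pae_value: float
    in_contact: bool = True


@dataclass(frozen=True)
class FixtureSpec:
    n_chains: int = 2
    residues_per_chain: int = 30
    interface_pairs: tuple[PlantedInterface, ...] = ()
    background_pae: float = 28.0
    plddt_profile: Union[float, Sequence[float]] = 90.0
    seed: int = 0
    n_models: int = 1
    model_jitter_sd: float = 0.0
    job_id: str = "fixture"

    def chain_ids(self) -> list[str]:
        if self.n_chains > 26:
            raise GenerationError("fixtures support at most 26 chains (A-Z)")
        return [chr(ord("A") + k) for k in range(self.n_chains)]


@dataclass
class FixtureTruth:
    """Closed-form expectations derived from the spec alone.

    ``metrics[(a, b)] = (lis, clis, ilis)``; residue sets are global PAE
    indices. Only chain pairs with at least one planted block appear.
    """

    metrics: dict[tuple[str, str], tuple[float, float, float]]
    lir: dict[tuple[str, str], tuple[frozenset, frozenset, frozenset, frozenset]]
    contacts: dict[tuple[str, str], frozenset]
    partition: Optional[list[tuple[tuple[int, int], ...]]] = None


# --- geometry ---------------------------------------------------------------

def _helix_coords(chain_index: int, i: int) -> tuple[np.ndarray, np.ndarray]:
    """(CA, CB) base positions of residue i on chain lane chain_index."""
    theta = _HELIX_TURN * i
    y0 = _LANE_SPACING * chain_index
    ca = np.array([_HELIX_RISE * i, y0 + 2.3 * math.cos(theta), 2.3 * math.sin(theta)])
    cb = np.array([_HELIX_RISE * i, y0 + 3.3 * math.cos(theta), 3.3 * math.sin(theta)])
    return ca, cb


def _patch_positions(length: int, x0: float, y: float, z: float) -> list[np.ndarray]:
    span = min(6.0, _HELIX_RISE * max(length - 1, 0))
    if length == 1:
        return [np.array([x0, y, z])]
    return [np.array([x0 + span * k / (length - 1), y, z]) for k in range(length)]


def _build_coordinates(spec: FixtureSpec) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Per chain, per residue (CA, CB) coordinates with patches re-placed."""
    chain_ids = spec.chain_ids()
    coords = {
        cid: [_helix_coords(k, i) for i in range(spec.residues_per_chain)]
        for k, cid in enumerate(chain_ids)
    }
    claimed: set[tuple[str, int]] = set()
    contact_patches = [p for p in spec.interface_pairs if p.in_contact]
    for p_idx, patch in enumerate(contact_patches):
        for cid, (s, e) in ((patch.chain_a, patch.range_a), (patch.chain_b, patch.range_b)):
            if not (0 <= s < e <= spec.residues_per_chain):
                raise GenerationError(f"planted range {s}-{e} outside chain {cid}")
            overlap = {(cid, i) for i in range(s, e)} & claimed
            if overlap:
                raise GenerationError(
                    f"residues {sorted(overlap)} claimed by two contact patches; "
                    "geometry infeasible"
                )
            claimed.update((cid, i) for i in range(s, e))
        lane_a = ord(patch.chain_a) - ord("A")
        z = _PATCH_Z0 + _PATCH_Z_STEP * p_idx
        y = _LANE_SPACING * lane_a + 12.0
        x0 = _HELIX_RISE * patch.range_a[0]
        for (cid, (s, e)), dy in (
            ((patch.chain_a, patch.range_a), 0.0),
            ((patch.chain_b, patch.range_b), _PATCH_OFFSET),
        ):
            for k, cb in enumerate(_patch_positions(e - s, x0, y + dy, z)):
                ca = cb + np.array([0.40, 0.60, 0.40])
                coords[cid][s + k] = (ca, cb)
    return coords


def _coords_to_structure(
    coords: dict[str, list[tuple[np.ndarray, np.ndarray]]],
    plddt: np.ndarray,
    name: str = "fixture",
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    gidx = 0
    for cid, residues in coords.items():
        chain = gemmi.Chain(cid)
        for i, (ca, cb) in enumerate(residues):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            for atom_name, pos in (("CA", ca), ("CB", cb)):
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*np.round(pos, 3))
                atom.occ = 1.0
                atom.b_iso = float(plddt[gidx])
                res.add_atom(atom)
            chain.add_residue(res)
            gidx += 1
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


# --- confidence planting ----------------------------------------------------

def _global_range(spec: FixtureSpec, chain_id: str, rng: tuple[int, int]) -> np.ndarray:
    offset = spec.chain_ids().index(chain_id) * spec.residues_per_chain
    return np.arange(offset + rng[0], offset + rng[1])


def _plant_pae(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_chains * spec.residues_per_chain
    pae = np.full((n, n), float(spec.background_pae))
    np.fill_diagonal(pae, 0.0)
    for patch in spec.interface_pairs:
        ga = _global_range(spec, patch.chain_a, patch.range_a)
        gb = _global_range(spec, patch.chain_b, patch.range_b)
        pae[np.ix_(ga, gb)] = patch.pae_value
        pae[np.ix_(gb, ga)] = patch.pae_value
    return pae


def _plant_plddt(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_chains * spec.residues_per_chain
    if np.isscalar(spec.plddt_profile):
        vec = np.full(n, float(spec.plddt_profile))
    else:
        vec = np.asarray(spec.plddt_profile, dtype=float)
        if vec.shape != (n,):
            raise GenerationError(f"plddt_profile length {vec.size} != {n} residues")
    return np.round(vec, 2)


def _derive_truth(spec: FixtureSpec, params: MetricParams) -> FixtureTruth:
    if spec.background_pae <= params.pae_cutoff:
        raise GenerationError(
            "closed-form truth requires background_pae above the PAE cutoff"
        )
    by_pair: dict[tuple[str, str], list[PlantedInterface]] = {}
    for patch in spec.interface_pairs:
        key = (patch.chain_a, patch.chain_b)
        by_pair.setdefault(key, []).append(patch)
    metrics, lir, contacts = {}, {}, {}
    for (a, b), patches in by_pair.items():
        lis_num = lis_den = clis_num = clis_den = 0.0
        lir_a: set[int] = set()
        lir_b: set[int] = set()
        clir_a: set[int] = set()
        clir_b: set[int] = set()
        pair_contacts: set[tuple[int, int]] = set()
        for p in patches:
            ga = _global_range(spec, a, p.range_a)
            gb = _global_range(spec, b, p.range_b)
            if p.in_contact:
                pair_contacts.update((i, j) for i in ga for j in gb)
            if p.pae_value <= params.pae_cutoff:
                w = 2.0 * ga.size * gb.size  # both directed blocks
                s = (params.pae_cutoff - p.pae_value) / params.pae_cutoff
                lis_num += w * s
                lis_den += w
                lir_a.update(ga.tolist())
                lir_b.update(gb.tolist())
                if p.in_contact:
                    clis_num += w * s
                    clis_den += w
                    clir_a.update(ga.tolist())
                    clir_b.update(gb.tolist())
        lis = lis_num / lis_den if lis_den else 0.0
        clis = clis_num / clis_den if clis_den else 0.0
        metrics[(a, b)] = (lis, clis, math.sqrt(lis * clis))
        lir[(a, b)] = (
            frozenset(lir_a), frozenset(lir_b), frozenset(clir_a), frozenset(clir_b)
        )
        contacts[(a, b)] = frozenset(pair_contacts)
    return FixtureTruth(metrics=metrics, lir=lir, contacts=contacts)


# --- record assembly --------------------------------------------------------

def _records_from_parts(
    spec_like_job: str,
    cif_text: str,
    pae: np.ndarray,
    plddt: np.ndarray,
    n_models: int,
    jitter_sd: float,
    seed: int,
    platform: str = "af3",
) -> list[PredictionRecord]:
    rng = np.random.default_rng(seed)
    records = []
    for m in range(n_models):
        pae_m = pae
        if m > 0 and jitter_sd > 0:
            noise = rng.normal(0.0, jitter_sd, size=pae.shape)
            pae_m = np.clip(pae + noise, 0.0, PAE_CEILING)
            np.fill_diagonal(pae_m, 0.0)
        structure, _, _ = parse_structure_details(cif_text, "mmcif")
        records.append(
            PredictionRecord(
                job_id=spec_like_job,
                model_name=f"model_{m}",
                platform=platform,
                structure=structure,
                confidence=ConfidenceData(pae=pae_m, plddt=plddt),
            )
        )
    return records


def make_complex_fixture(
    spec: FixtureSpec, params: MetricParams = MetricParams()
) -> tuple[list[PredictionRecord], FixtureTruth]:
    """Build one multi-chain fixture job and its closed-form truth.

    Model 0 carries the exact planted PAE; with ``n_models > 1`` the
    remaining models get seeded Gaussian jitter clipped to
    [0, 31.75], so the truth applies verbatim to model 0 only.
    """
    coords = _build_coordinates(spec)
    plddt = _plant_plddt(spec)
    pae = _plant_pae(spec)
    st = _coords_to_structure(coords, plddt, name=spec.job_id)
    cif_text = st.make_mmcif_document().as_string()
    records = _records_from_parts(
        spec.job_id, cif_text, pae, plddt, spec.n_models, spec.model_jitter_sd, spec.seed
    )
    return records, _derive_truth(spec, params)


def make_monomer_fixture(
    n_residues: int = 120,
    domains: tuple[tuple[int, int], ...] = ((0, 60), (60, 120)),
    domain_pae: float = 3.0,
    background_pae: float = 28.0,
    contact_patch: Optional[tuple[tuple[int, int], tuple[int, int], float]] = None,
    plddt: float = 90.0,
    seed: int = 0,
    job_id: str = "monomer",
) -> tuple[PredictionRecord, FixtureTruth]:
    """Single chain with low-PAE domains joined by high-PAE linker material.

    ``contact_patch = (range_i, range_j, pae_value)`` optionally plants
    an inter-domain contact (e.g. an autoinhibitory interaction): both
    ranges are re-placed within Cβ contact distance and the cross PAE is
    set to ``pae_value``. The expected partition is the domain list.
    """
    for s, e in domains:
        if not (0 <= s < e <= n_residues):
            raise GenerationError(f"domain {s}-{e} outside chain of {n_residues}")
    coords = {"A": [_helix_coords(0, i) for i in range(n_residues)]}
    if contact_patch is not None:
        (s0, e0), (s1, e1), _ = contact_patch
        if set(range(s0, e0)) & set(range(s1, e1)):
            raise GenerationError("contact patch ranges overlap; geometry infeasible")
        x0 = _HELIX_RISE * s0
        for (s, e), dy in (((s0, e0), 0.0), ((s1, e1), _PATCH_OFFSET)):
            for k, cb in enumerate(_patch_positions(e - s, x0, 12.0 + dy, _PATCH_Z0)):
                coords["A"][s + k] = (cb + np.array([0.40, 0.60, 0.40]), cb)
    n = n_residues
    pae = np.full((n, n), float(background_pae))
    for s, e in domains:
        pae[s:e, s:e] = domain_pae
    if contact_patch is not None:
        (s0, e0), (s1, e1), patch_pae = contact_patch
        pae[s0:e0, s1:e1] = patch_pae
        pae[s1:e1, s0:e0] = patch_pae
    np.fill_diagonal(pae, 0.0)
    plddt_vec = np.round(np.full(n, float(plddt)), 2)
    st = _coords_to_structure(coords, plddt_vec, name=job_id)
    cif_text = st.make_mmcif_document().as_string()
    record = _records_from_parts(job_id, cif_text, pae, plddt_vec, 1, 0.0, seed)[0]
    truth = FixtureTruth(
        metrics={}, lir={}, contacts={}, partition=[((s, e),) for s, e in domains]
    )
    if contact_patch is not None:
        (s0, e0), (s1, e1), patch_pae = contact_patch
        truth.contacts[("A[0]", "A[1]")] = frozenset(
            (i, j) for i in range(s0, e0) for j in range(s1, e1)
        )
        truth.lir[("A[0]", "A[1]")] = (
            frozenset(range(s0, e0)), frozenset(range(s1, e1)),
            frozenset(range(s0, e0)), frozenset(range(s1, e1)),
        )
    return record, truth


# --- dialect writers --------------------------------------------------------

def _structure_texts(record: PredictionRecord) -> tuple[str, str]:
    """(mmCIF, PDB) serializations rebuilt from the record's structure."""
    coords = {}
    plddt = record.confidence.plddt
    for chain in record.structure.chains:
        entries = []
        for r in chain.residues:
            cb = np.asarray(r.rep_coord)
            if r.rep_atom == "CB":
                entries.append((cb + np.array([0.40, 0.60, 0.40]), cb))
            else:  # CA-only residue: emit just the CA (glycine-like)
                entries.append((cb, None))
        coords[chain.chain_id] = entries
    st = gemmi.Structure()
    st.name = record.job_id
    model = gemmi.Model("1")
    gidx = 0
    for chain_rec in record.structure.chains:
        chain = gemmi.Chain(chain_rec.chain_id)
        for res_rec, (ca, cb) in zip(chain_rec.residues, coords[chain_rec.chain_id]):
            res = gemmi.Residue()
            res.name = res_rec.residue_name
            res.seqid = gemmi.SeqId(res_rec.author_seq_num, " ")
            atoms = [("CA", ca)] + ([("CB", cb)] if cb is not None else [])
            for atom_name, pos in atoms:
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*np.round(np.asarray(pos), 3))
                atom.occ = 1.0
                atom.b_iso = float(plddt[gidx])
                res.add_atom(atom)
            chain.add_residue(res)
            gidx += 1
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_mmcif_document().as_string(), st.make_pdb_string()


def _atom_counts(record: PredictionRecord) -> list[int]:
    return [
        2 if r.rep_atom == "CB" else 1
        for c in record.structure.chains
        for r in c.residues
    ]


def _pair_iptm_matrix(record: PredictionRecord) -> Optional[list[list[float]]]:
    cp = record.confidence.chain_pair_iptm
    if not cp:
        return None
    ids = record.structure.chain_ids
    mat = [[0.0] * len(ids) for _ in ids]
    for (a, b), v in cp.items():
        i, j = ids.index(a), ids.index(b)
        mat[i][j] = mat[j][i] = v
    return mat


def _json_bytes(obj) -> bytes:
    return json.dumps(obj, sort_keys=True).encode()


def _npz_bytes(**arrays) -> bytes:
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    return buf.getvalue()


def _write_af3(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    for i, rec in enumerate(records):
        base = f"fold_{rec.job_id}"
        cif, _ = _structure_texts(rec)
        out[f"{base}_model_{i}.cif"] = cif.encode()
        counts = _atom_counts(rec)
        atom_plddts = np.repeat(rec.confidence.plddt, counts)
        full = {
            "atom_plddts": atom_plddts.tolist(),
            "pae": rec.confidence.pae.tolist(),
            "token_chain_ids": [
                c.chain_id for c in rec.structure.chains for _ in c.residues
            ],
            "token_res_ids": [
                r.author_seq_num for c in rec.structure.chains for r in c.residues
            ],
        }
        out[f"{base}_full_data_{i}.json"] = _json_bytes(full)
        summary = {"ptm": 0.5}
        if rec.confidence.iptm_reported is not None:
            summary["iptm"] = rec.confidence.iptm_reported
        if rec.confidence.ranking_score is not None:
            summary["ranking_score"] = rec.confidence.ranking_score
        mat = _pair_iptm_matrix(rec)
        if mat is not None:
            summary["chain_pair_iptm"] = mat
        out[f"{base}_summary_confidences_{i}.json"] = _json_bytes(summary)
    return out


def _write_colabfold(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    for i, rec in enumerate(records):
        tag = f"rank_{i + 1:03d}_alphafold2_multimer_v3_model_{i + 1}_seed_000"
        _, pdb = _structure_texts(rec)
        out[f"{rec.job_id}_unrelaxed_{tag}.pdb"] = pdb.encode()
        scores = {
            "max_pae": PAE_CEILING,
            "pae": rec.confidence.pae.tolist(),
            "plddt": rec.confidence.plddt.tolist(),
            "ptm": 0.5,
        }
        if rec.confidence.iptm_reported is not None:
            scores["iptm"] = rec.confidence.iptm_reported
        out[f"{rec.job_id}_scores_{tag}.json"] = _json_bytes(scores)
    return out


def _write_afm(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    order = []
    iptm = {}
    iptm_ptm = {}
    folder = f"{records[0].job_id}/"
    for i, rec in enumerate(records):
        model = f"model_{i + 1}_multimer_v3_pred_0"
        order.append(model)
        _, pdb = _structure_texts(rec)
        out[f"{folder}unrelaxed_{model}.pdb"] = pdb.encode()
        out[f"{folder}pae_{model}.json"] = _json_bytes(
            [
                {
                    "predicted_aligned_error": rec.confidence.pae.tolist(),
                    "max_predicted_aligned_error": PAE_CEILING,
                }
            ]
        )
        if rec.confidence.iptm_reported is not None:
            iptm[model] = rec.confidence.iptm_reported
            iptm_ptm[model] = rec.confidence.iptm_reported
    out[f"{folder}ranking_debug.json"] = _json_bytes(
        {"iptm": iptm, "iptm+ptm": iptm_ptm, "order": order}
    )
    return out


def _write_boltz(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    for i, rec in enumerate(records):
        folder = f"predictions/{rec.job_id}/"
        cif, _ = _structure_texts(rec)
        out[f"{folder}{rec.job_id}_model_{i}.cif"] = cif.encode()
        out[f"{folder}pae_{rec.job_id}_model_{i}.npz"] = _npz_bytes(
            pae=rec.confidence.pae
        )
        out[f"{folder}plddt_{rec.job_id}_model_{i}.npz"] = _npz_bytes(
            plddt=rec.confidence.plddt / 100.0
        )
        conf: dict = {"confidence_score": 0.5}
        if rec.confidence.iptm_reported is not None:
            conf["iptm"] = rec.confidence.iptm_reported
        if rec.confidence.chain_pair_iptm:
            nested: dict[str, dict[str, float]] = {}
            for (a, b), v in rec.confidence.chain_pair_iptm.items():
                nested.setdefault(a, {})[b] = v
                nested.setdefault(b, {})[a] = v
            conf["pair_chains_iptm"] = nested
        out[f"{folder}confidence_{rec.job_id}_model_{i}.json"] = _json_bytes(conf)
    return out


def _write_chai(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    for i, rec in enumerate(records):
        folder = f"{rec.job_id}/"
        cif, _ = _structure_texts(rec)
        out[f"{folder}pred.model_idx_{i}.cif"] = cif.encode()
        arrays = {
            "pae": rec.confidence.pae,
            "plddt": rec.confidence.plddt / 100.0,
            "aggregate_score": np.array(0.5),
        }
        if rec.confidence.iptm_reported is not None:
            arrays["iptm"] = np.array(rec.confidence.iptm_reported)
        mat = _pair_iptm_matrix(rec)
        if mat is not None:
            arrays["per_chain_pair_iptm"] = np.asarray(mat)
        out[f"{folder}scores.model_idx_{i}.npz"] = _npz_bytes(**arrays)
    return out


def _write_openfold3(records: list[PredictionRecord]) -> dict[str, bytes]:
    out = {}
    for i, rec in enumerate(records):
        base = f"{rec.job_id}_of3_model_{i}"
        cif, _ = _structure_texts(rec)
        out[f"{base}.cif"] = cif.encode()
        conf = {
            "pae": rec.confidence.pae.tolist(),
            "plddt": rec.confidence.plddt.tolist(),
            "ptm": 0.5,
        }
        if rec.confidence.iptm_reported is not None:
            conf["iptm"] = rec.confidence.iptm_reported
        out[f"{base}_confidences.json"] = _json_bytes(conf)
    return out


_WRITERS = {
    "af3": _write_af3,
    "colabfold": _write_colabfold,
    "afm": _write_afm,
    "boltz": _write_boltz,
    "chai": _write_chai,
    "openfold3": _write_openfold3,
}


def write_dialect(
    records: list[PredictionRecord], platform: str, out: Union[str, Path]
) -> list[str]:
    """Serialize fixture records in one platform's file layout.

    ``out`` is a directory, or a ZIP archive when it ends in ``.zip``.
    Returns the entry names written. Records may span several jobs (each
    job is written with its own file prefix in the same tree).
    """
    if platform not in _WRITERS:
        raise ValueError(f"unsupported platform tag {platform!r}")
    by_job: dict[str, list[PredictionRecord]] = {}
    for rec in records:
        by_job.setdefault(rec.job_id, []).append(rec)
    entries: dict[str, bytes] = {}
    for job in sorted(by_job):
        entries.update(_WRITERS[platform](by_job[job]))
    out = Path(out)
    if out.suffix == ".zip":
        out.parent.mkdir(parents=True, exist_ok=True)
        buf = io.BytesIO()
        with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in sorted(entries):
                info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
                zf.writestr(info, entries[name])
        out.write_bytes(buf.getvalue())
    else:
        out.mkdir(parents=True, exist_ok=True)
        for name, data in entries.items():
            path = out / name
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_bytes(data)
    return sorted(entries)
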