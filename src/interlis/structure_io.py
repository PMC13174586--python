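"""Coordinate parsing and residue-level contact geometry.

Model coordinate files (mmCIF or PDB) are parsed with :mod:`gemmi` and
reduced to the representation the interface metrics need: per residue, a
single representative interaction coordinate — the Cβ atom, falling back
to Cα for glycine or residues whose Cβ is missing. Residue pairs whose
representative atoms lie within a distance cutoff (default 8 Å) are
"in contact"; contacts feed the contact-restricted metrics (cLIS, cLIR,
actifpTM).

Residues carry two indices: the author sequence number (what ChimeraX and
PyMOL selections address) and a 0-based ``global_index`` over the whole
model in file chain order, which aligns with the rows/columns of the PAE
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import gemmi
import numpy as np

from .errors import ParseError

__all__ = [
    "ResidueRecord",
    "ChainRecord",
    "StructureModel",
    "ContactSet",
    "parse_structure",
    "parse_all_models",
    "compute_contacts",
    "contacts_between_indices",
]


@dataclass(frozen=True)
class ResidueRecord:
    """One polymer residue with its representative interaction coordinate."""

    author_seq_num: int
    residue_name: str
    rep_coord: tuple[float, float, float]
    rep_atom: Literal["CB", "CA"]
    global_index: int


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[ResidueRecord]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def author_seq_nums(self) -> list[int]:
        return [r.author_seq_num for r in self.residues]


@dataclass
class StructureModel:
    """Chains -> residues -> representative coordinates for one model."""

    model_id: str
    chains: list[ChainRecord]
    source_format: Literal["mmcif", "pdb"]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ParseError(f"duplicate chain identifiers in model: {ids}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model (has {self.chain_ids})")

    def chain_indices(self, chain_id: str) -> np.ndarray:
        """Global PAE-row indices of one chain, in residue order."""
        return np.array([r.global_index for r in self.chain(chain_id).residues], dtype=int)

    def rep_coords(self) -> np.ndarray:
        """(N, 3) array of representative coordinates ordered by global_index."""
        out = np.empty((self.n_residues, 3), dtype=float)
        for c in self.chains:
            for r in c.residues:
                out[r.global_index] = r.rep_coord
        return out


@dataclass
class ContactSet:
    """Undirected inter-chain residue contacts at a distance cutoff.

    Pairs are stored as ``(global_index_a, global_index_b)`` with the first
    element on ``chain_a``.
    """

    chain_a: str
    chain_b: str
    pairs: frozenset[tuple[int, int]]
    cutoff_angstrom: float = 8.0

    def contains(self, i: int, j: int) -> bool:
        """Membership irrespective of orientation."""
        return (i, j) in self.pairs or (j, i) in self.pairs

    def transposed(self) -> "ContactSet":
        return ContactSet(
            chain_a=self.chain_b,
            chain_b=self.chain_a,
            pairs=frozenset((j, i) for i, j in self.pairs),
            cutoff_angstrom=self.cutoff_angstrom,
        )


_REP_PRIMARY = "CB"
_REP_FALLBACK = "CA"


def _residue_rep(res: gemmi.Residue) -> Optional[tuple[tuple[float, float, float], str]]:
    cb = res.find_atom(_REP_PRIMARY, "*")
    if cb is not None and cb.element.name == "C":
        return (cb.pos.x, cb.pos.y, cb.pos.z), "CB"
    ca = res.find_atom(_REP_FALLBACK, "*")
    if ca is not None:
        return (ca.pos.x, ca.pos.y, ca.pos.z), "CA"
    return None


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info and info.is_amino_acid())


def _read_gemmi_structure(raw: bytes | str, format_hint: Optional[str]) -> tuple[gemmi.Structure, str]:
    text = raw.decode() if isinstance(raw, (bytes, bytearray)) else raw
    fmt = format_hint
    if fmt is None:
        head = text.lstrip()[:4000]
        fmt = "mmcif" if (head.startswith("data_") or "_atom_site." in head) else "pdb"
    if fmt not in ("mmcif", "pdb"):
        raise ValueError(f"format_hint must be 'mmcif' or 'pdb', got {fmt!r}")
    try:
        if fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {fmt} document: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keep first-listed altloc
    st.remove_ligands_and_waters()
    return st, fmt


def _model_from_gemmi(
    model: gemmi.Model, model_id: str, fmt: str
) -> tuple[StructureModel, np.ndarray, list[int]]:
    chains: list[ChainRecord] = []
    bfactors: list[float] = []
    atom_counts: list[int] = []
    gidx = 0
    for ch in model:
        residues: list[ResidueRecord] = []
        for res in ch:
            if not _is_amino_acid(res):
                continue
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ParseError(
                    f"insertion code {res.seqid.icode!r} at {ch.name}/{res.seqid.num}: "
                    "prediction outputs are expected to use plain sequential numbering"
                )
            rep = _residue_rep(res)
            if rep is None:
                raise ParseError(
                    f"residue {ch.name}/{res.seqid.num} ({res.name}) has neither CB nor CA"
                )
            coord, rep_atom = rep
            residues.append(
                ResidueRecord(
                    author_seq_num=res.seqid.num,
                    residue_name=res.name,
                    rep_coord=coord,
                    rep_atom=rep_atom,  # type: ignore[arg-type]
                    global_index=gidx,
                )
            )
            bfactors.append(float(np.mean([a.b_iso for a in res])))
            atom_counts.append(len(res))
            gidx += 1
        if residues:
            nums = [r.author_seq_num for r in residues]
            if nums != sorted(nums):
                raise ParseError(f"chain {ch.name}: residues not in ascending author order")
            chains.append(ChainRecord(chain_id=ch.name, residues=residues))
    if not chains:
        raise ParseError("document contains no polymer (amino-acid) chains")
    sm = StructureModel(model_id=model_id, chains=chains, source_format=fmt)  # type: ignore[arg-type]
    return sm, np.asarray(bfactors, dtype=float), atom_counts


def parse_all_models(raw: bytes | str, format_hint: Optional[str] = None) -> list[StructureModel]:
    """Parse every MODEL in a coordinate document (usually one)."""
    st, fmt = _read_gemmi_structure(raw, format_hint)
    if len(st) == 0:
        raise ParseError("document contains no models")
    return [_model_from_gemmi(m, str(m.num), fmt)[0] for m in st]


def parse_structure_details(
    raw: bytes | str, format_hint: Optional[str] = None
) -> tuple[StructureModel, np.ndarray, list[int]]:
    """First model plus per-residue mean B-factor and per-residue atom count.

    Prediction platforms commonly store pLDDT in the B-factor column;
    loaders use the B-factor vector (rounded to the 2 decimals the PDB
    text format carries) and the atom counts (to collapse per-atom pLDDT
    lists onto residues).
    """
    st, fmt = _read_gemmi_structure(raw, format_hint)
    if len(st) == 0:
        raise ParseError("document contains no models")
    return _model_from_gemmi(st[0], str(st[0].num), fmt)


def parse_structure(raw: bytes | str, format_hint: Optional[str] = None) -> StructureModel:
    """Parse a coordinate document into a :class:`StructureModel`.

    Heteroatoms, waters and ligands are dropped; only amino-acid polymer
    residues are kept. For multi-MODEL PDB files this returns the first
    model (see :func:`parse_all_models`).
    """
    return parse_all_models(raw, format_hint)[0]


def contacts_between_indices(
    model: StructureModel,
    idx_a: Sequence[int] | np.ndarray,
    idx_b: Sequence[int] | np.ndarray,
    cutoff: float = 8.0,
) -> frozenset[tuple[int, int]]:
    """All pairs (i in idx_a, j in idx_b) with rep-coord distance <= cutoff."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    coords = model.rep_coords()
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    ii, jj = np.nonzero(dist <= cutoff)
    return frozenset(zip(idx_a[ii].tolist(), idx_b[jj].tolist()))


def compute_contacts(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 8.0
) -> ContactSet:
    """Inter-chain Cβ (Cα fallback) contacts at an inclusive distance cutoff."""
    if chain_a == chain_b:
        raise ValueError("chain_a and chain_b must differ; use contacts_between_indices "
                         "for intra-chain region contacts")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    pairs = contacts_between_indices(
        model, model.chain_indices(chain_a), model.chain_indices(chain_b), cutoff
    )
    return ContactSet(chain_a=chain_a, chain_b=chain_b, pairs=pairs, cutoff_angstrom=cutoff)
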