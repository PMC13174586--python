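"""Visualization script generation and tabular export.

Generates deterministic ChimeraX (``.cxc``) and PyMOL (``.pml``) command
scripts that reproduce the interface color scheme — cLIR residues in the
chain's base color, LIR-only residues in a lightened shade, everything
else gray — plus CSV tables of all computed metrics and residue
assignments and JSON contact-map data (linear edge list, or circular
layout with per-chain arc spans).

Scripts address residues by author sequence number, which is what both
viewers' selection syntax uses; ranges are compressed (``12-18,25``).
Output text is a pure function of its inputs so repeated exports are
byte-identical.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .interface_metrics import ChainPairMetrics, MetricParams, ScoreMatrix
from .prediction_io import PredictionRecord
from .residue_profiles import intra_chain_lis_profile

__all__ = [
    "ColorScheme",
    "ScriptSpec",
    "build_script_spec",
    "render_chimerax",
    "render_pymol",
    "export_metrics_csv",
    "export_contact_map",
]

# 12 distinct hues, assigned by chain file order and cycled beyond 12.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e", "#8c564b",
    "#e377c2", "#17becf", "#bcbd22", "#7f7f7f", "#aec7e8", "#98df8a",
)


@dataclass(frozen=True)
class ColorScheme:
    """How residues are painted in generated scripts."""

    mode: str = "lir_clir"  # "lir_clir" | "chain" | "plddt"
    palette: tuple[str, ...] = DEFAULT_PALETTE
    light_blend: float = 0.5
    noninteracting_color: str = "#808080"
    plddt_min: float = 50.0
    lir_padding: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("lir_clir", "chain", "plddt"):
            raise ValueError(f"unknown color mode {self.mode!r}")
        if not 0.0 <= self.light_blend <= 1.0:
            raise ValueError("light_blend must lie in [0, 1]")

    def base_color(self, chain_index: int) -> str:
        return self.palette[chain_index % len(self.palette)]

    def light_color(self, chain_index: int) -> str:
        return _blend_toward_white(self.base_color(chain_index), self.light_blend)


@dataclass
class ChainSelections:
    """Author-numbered residue sets of one chain, precedence-resolved."""

    chain_id: str
    clir: tuple[int, ...]
    lir_only: tuple[int, ...]
    noninteracting: tuple[int, ...]
    shown_range: tuple[int, ...]  # padded LIR region (author numbers)


@dataclass
class ScriptSpec:
    structure_path: str
    chains: list[ChainSelections]
    scheme: ColorScheme
    show_only_lir_region: bool = True


def _blend_toward_white(hex_color: str, t: float) -> str:
    r, g, b = (int(hex_color[i : i + 2], 16) for i in (1, 3, 5))
    mix = tuple(round(v + (255 - v) * t) for v in (r, g, b))
    return "#{:02x}{:02x}{:02x}".format(*mix)


def _compress_ranges(nums: Sequence[int]) -> str:
    """``[12,13,14,18] -> "12-14,18"`` for viewer selection strings."""
    if not nums:
        return ""
    nums = sorted(set(nums))
    parts = []
    start = prev = nums[0]
    for n in nums[1:] + [None]:  # type: ignore[list-item]
        if n is not None and n == prev + 1:
            prev = n
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if n is not None:
            start = prev = n
    return ",".join(parts)


def _pair_cells(metrics: Union[ScoreMatrix, ChainPairMetrics]) -> list[ChainPairMetrics]:
    if isinstance(metrics, ScoreMatrix):
        return [metrics.cells[p] for p in metrics.pairs()]
    return [metrics]


def build_script_spec(
    record: PredictionRecord,
    metrics: Union[ScoreMatrix, ChainPairMetrics],
    scheme: ColorScheme = ColorScheme(),
    structure_path: str = "model.cif",
    show_only_lir_region: bool = True,
) -> ScriptSpec:
    """Resolve per-chain LIR/cLIR selections with clir > lir > gray precedence."""
    model = record.structure
    lir_by_chain: dict[str, set[int]] = {c: set() for c in model.chain_ids}
    clir_by_chain: dict[str, set[int]] = {c: set() for c in model.chain_ids}
    for cell in _pair_cells(metrics):
        for chain_id, lir, clir in (
            (cell.chain_a, cell.lir_a, cell.clir_a),
            (cell.chain_b, cell.lir_b, cell.clir_b),
        ):
            if chain_id not in lir_by_chain:
                raise ConsistencyError(
                    f"metrics refer to chain {chain_id!r} absent from the record"
                )
            lir_by_chain[chain_id] |= set(lir)
            clir_by_chain[chain_id] |= set(clir)
    all_indices = {i for s in lir_by_chain.values() for i in s}
    if all_indices and max(all_indices) >= model.n_residues:
        raise ConsistencyError("metrics index residues beyond the record's size")

    chains: list[ChainSelections] = []
    for chain in model.chains:
        by_gidx = {r.global_index: r.author_seq_num for r in chain.residues}
        clir = sorted(by_gidx[i] for i in clir_by_chain[chain.chain_id])
        lir_all = sorted(by_gidx[i] for i in lir_by_chain[chain.chain_id])
        lir_only = sorted(set(lir_all) - set(clir))
        noninter = sorted(set(by_gidx.values()) - set(lir_all))
        shown: tuple[int, ...] = ()
        if lir_all:
            lo = min(lir_all) - scheme.lir_padding
            hi = max(lir_all) + scheme.lir_padding
            shown = tuple(n for n in by_gidx.values() if lo <= n <= hi)
        chains.append(
            ChainSelections(
                chain_id=chain.chain_id,
                clir=tuple(clir),
                lir_only=tuple(lir_only),
                noninteracting=tuple(noninter),
                shown_range=shown,
            )
        )
    return ScriptSpec(
        structure_path=structure_path,
        chains=chains,
        scheme=scheme,
        show_only_lir_region=show_only_lir_region,
    )


def render_chimerax(spec: ScriptSpec) -> str:
    """ChimeraX .cxc command script implementing the spec's color classes."""
    scheme = spec.scheme
    lines = [
        f"open {spec.structure_path}",
        "hide atoms",
        "show cartoon",
        f"color {scheme.noninteracting_color}",
    ]
    any_lir = any(c.clir or c.lir_only for c in spec.chains)
    for k, ch in enumerate(spec.chains):
        sel = f"/{ch.chain_id}"
        if ch.lir_only:
            lines.append(
                f"color {sel}:{_compress_ranges(ch.lir_only)} {scheme.light_color(k)}"
            )
        if ch.clir:
            lines.append(
                f"color {sel}:{_compress_ranges(ch.clir)} {scheme.base_color(k)}"
            )
    if spec.show_only_lir_region and any_lir:
        for ch in spec.chains:
            hidden = sorted(
                set(ch.clir) | set(ch.lir_only) | set(ch.noninteracting)
            )
            hidden = [n for n in hidden if n not in set(ch.shown_range)]
            if hidden:
                lines.append(f"hide /{ch.chain_id}:{_compress_ranges(hidden)} cartoon")
    lines.append("view")
    return "\n".join(lines) + "\n"


def render_pymol(spec: ScriptSpec) -> str:
    """PyMOL .pml script with the same selection semantics as the .cxc output."""
    scheme = spec.scheme
    lines = [
        f"load {spec.structure_path}, model",
        "hide everything, model",
        "show cartoon, model",
        f"color {_pymol_color(scheme.noninteracting_color)}, model",
    ]
    any_lir = any(c.clir or c.lir_only for c in spec.chains)
    for k, ch in enumerate(spec.chains):
        if ch.lir_only:
            name = f"{ch.chain_id}_lir"
            lines.append(
                f"select {name}, model and chain {ch.chain_id} and resi "
                f"{_pymol_resi(ch.lir_only)}"
            )
            lines.append(f"color {_pymol_color(scheme.light_color(k))}, {name}")
        if ch.clir:
            name = f"{ch.chain_id}_clir"
            lines.append(
                f"select {name}, model and chain {ch.chain_id} and resi "
                f"{_pymol_resi(ch.clir)}"
            )
            lines.append(f"color {_pymol_color(scheme.base_color(k))}, {name}")
    if spec.show_only_lir_region and any_lir:
        for ch in spec.chains:
            if ch.shown_range:
                lines.append(
                    f"hide cartoon, model and chain {ch.chain_id} and not resi "
                    f"{_pymol_resi(ch.shown_range)}"
                )
            else:
                lines.append(f"hide cartoon, model and chain {ch.chain_id}")
    lines.append("deselect")
    lines.append("zoom visible")
    return "\n".join(lines) + "\n"


def _pymol_color(hex_color: str) -> str:
    return "0x" + hex_color.lstrip("#")


def _pymol_resi(nums: Sequence[int]) -> str:
    return _compress_ranges(nums).replace(",", "+")


def export_metrics_csv(
    analyses: Sequence[tuple[PredictionRecord, Union[ScoreMatrix, ChainPairMetrics]]],
    params: MetricParams = MetricParams(),
) -> tuple[str, str]:
    """Pair-level and residue-level CSV tables for all analyzed models.

    Returns ``(pair_csv, residue_csv)`` as RFC 4180 text with 6-decimal
    fixed-point numeric formatting.
    """
    pair_rows = []
    res_rows = []
    for record, metrics in analyses:
        model = record.structure
        intra = {
            c.chain_id: intra_chain_lis_profile(record, c.chain_id, params).values
            for c in model.chains
        }
        for cell in _pair_cells(metrics):
            pair_rows.append(
                {
                    "job_id": record.job_id,
                    "model_name": record.model_name,
                    "chain_a": cell.chain_a,
                    "chain_b": cell.chain_b,
                    "lis": cell.lis,
                    "clis": cell.clis,
                    "ilis": cell.ilis,
                    "ipsae": cell.ipsae,
                    "actifptm": cell.actifptm,
                    "iptm_reported": cell.iptm_reported,
                    "n_lir_a": len(cell.lir_a),
                    "n_lir_b": len(cell.lir_b),
                    "n_clir_a": len(cell.clir_a),
                    "n_clir_b": len(cell.clir_b),
                    "n_contact_pairs": len(cell.contacts.pairs),
                }
            )
            for chain_id, partner, lir, clir in (
                (cell.chain_a, cell.chain_b, cell.lir_a, cell.clir_a),
                (cell.chain_b, cell.chain_a, cell.lir_b, cell.clir_b),
            ):
                try:
                    chain = model.chain(chain_id)
                except KeyError:
                    continue  # pseudo-chain (subdomain) rows have no chain record
                values = intra[chain_id]
                for pos, res in enumerate(chain.residues):
                    res_rows.append(
                        {
                            "job_id": record.job_id,
                            "model_name": record.model_name,
                            "chain": chain_id,
                            "author_seq_num": res.author_seq_num,
                            "residue_name": res.residue_name,
                            "partner_chain": partner,
                            "is_lir": res.global_index in lir,
                            "is_clir": res.global_index in clir,
                            "plddt": record.confidence.plddt[res.global_index],
                            "intra_lis": values[pos],
                        }
                    )
    pair_df = pd.DataFrame(pair_rows)
    res_df = pd.DataFrame(res_rows)
    return (
        pair_df.to_csv(index=False, float_format="%.6f", lineterminator="\r\n"),
        res_df.to_csv(index=False, float_format="%.6f", lineterminator="\r\n"),
    )


def export_contact_map(
    record: PredictionRecord,
    metrics: Union[ScoreMatrix, ChainPairMetrics],
    layout: str = "linear",
) -> str:
    """JSON contact-map data: cLIR contact edges, plus arc spans if circular.

    Edges are the undirected contact-qualifying residue pairs, reported
    with chain ids and author residue numbers. The circular layout adds
    per-chain arc spans as cumulative residue offsets so a plotting tool
    can place each chain on a circle segment.
    """
    if layout not in ("linear", "circular"):
        raise ValueError(f"layout must be 'linear' or 'circular', got {layout!r}")
    model = record.structure
    author = {
        r.global_index: (c.chain_id, r.author_seq_num)
        for c in model.chains
        for r in c.residues
    }
    edges = set()
    for cell in _pair_cells(metrics):
        for i, j in cell.contact_qualifying_pairs:
            edges.add((min(i, j), max(i, j)))
    edge_list = [
        {
            "chain_a": author[i][0],
            "resnum_a": author[i][1],
            "chain_b": author[j][0],
            "resnum_b": author[j][1],
        }
        for i, j in sorted(edges)
    ]
    doc: dict = {"layout": layout, "edges": edge_list}
    if layout == "circular":
        spans = []
        offset = 0
        for c in model.chains:
            spans.append({"chain": c.chain_id, "start": offset, "length": len(c)})
            offset += len(c)
        doc["arcs"] = spans
        doc["total_residues"] = offset
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"
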