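"""Platform detection and normalization of prediction bundles.

Structure-prediction tools write their coordinates and confidence data in
mutually incompatible layouts. This module detects the originating
platform from the file names inside a folder or ZIP archive, reads that
dialect, and normalizes everything into :class:`PredictionRecord`
objects: a parsed structure plus an N×N PAE matrix in Å, a per-residue
pLDDT vector on the [0, 100] scale, and the platform-reported ipTM
(scalar or per-chain-pair) when available.

Supported dialects and their signatures:

========== =======================================================================
platform    signature (any entry matching)
========== =======================================================================
af3         ``*_full_data_N.json`` together with ``*_model_N.cif``
colabfold   ``*_scores_rank_NNN_*.json`` (PAE/pLDDT JSON next to the PDB)
afm         ``ranking_debug.json`` plus ``pae_model_*.json`` sidecars; the binary
            result pickles are never executed — a JSON sidecar with
            ``predicted_aligned_error`` is expected instead
boltz       ``predictions/`` tree with ``pae_*.npz`` / ``plddt_*.npz`` per model
chai        ``scores.model_idx_N.npz`` next to ``pred.model_idx_N.cif``
openfold3   ``*_of3_model_N_confidences.json`` next to the matching ``.cif``
========== =======================================================================

Detection is a pure function of the entry names; when two signatures are
present the load fails loudly rather than guessing, and a
``platform_override`` bypasses detection entirely. pLDDT stored on the
[0, 1] scale (Boltz, Chai) is rescaled to [0, 100].
"""

from __future__ import annotations

import io
import json
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousPlatformError,
    ConsistencyError,
    FormatError,
    ParseError,
    UnknownPlatformError,
)
from .structure_io import StructureModel, parse_structure_details

__all__ = [
    "ConfidenceData",
    "PredictionRecord",
    "PredictionBundle",
    "PLATFORMS",
    "detect_platform",
    "load_bundle",
    "list_models",
]

PLATFORMS = ("afm", "af3", "colabfold", "boltz", "chai", "openfold3")


@dataclass
class ConfidenceData:
    """Normalized confidence block of one model.

    ``pae[i, j]`` is the expected position error (Å) of residue j when
    the prediction is aligned on residue i; the matrix is generally
    asymmetric. ``plddt`` is per-residue on [0, 100].
    """

    pae: np.ndarray
    plddt: np.ndarray
    iptm_reported: Optional[float] = None
    chain_pair_iptm: Optional[dict[tuple[str, str], float]] = None
    ranking_score: Optional[float] = None

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ConsistencyError(f"PAE matrix must be square, got shape {self.pae.shape}")
        if np.isnan(self.pae).any() or (self.pae < 0).any():
            raise ConsistencyError("PAE matrix contains NaN or negative entries")
        if self.plddt.shape != (self.pae.shape[0],):
            raise ConsistencyError(
                f"pLDDT length {self.plddt.shape} does not match PAE dimension {self.pae.shape[0]}"
            )
        if (self.plddt < 0).any() or (self.plddt > 100).any():
            raise ConsistencyError("pLDDT values outside [0, 100]")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]

    def iptm_for_pair(self, chain_a: str, chain_b: str) -> tuple[Optional[float], bool]:
        """Reported ipTM for a chain pair; second element flags a global scalar."""
        if self.chain_pair_iptm is not None:
            for key in ((chain_a, chain_b), (chain_b, chain_a)):
                if key in self.chain_pair_iptm:
                    return self.chain_pair_iptm[key], False
        if self.iptm_reported is not None:
            return self.iptm_reported, True
        return None, False


@dataclass
class PredictionRecord:
    """One model of one prediction job, normalized across platforms."""

    job_id: str
    model_name: str
    platform: str
    structure: StructureModel
    confidence: ConfidenceData

    def __post_init__(self) -> None:
        if self.structure.n_residues != self.confidence.n_residues:
            raise ConsistencyError(
                f"structure has {self.structure.n_residues} residues but PAE is "
                f"{self.confidence.n_residues}x{self.confidence.n_residues}"
            )


@dataclass
class PredictionBundle:
    """All jobs found in one uploaded archive/folder."""

    jobs: dict[str, list[PredictionRecord]] = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return sum(len(v) for v in self.jobs.values())

    def all_records(self) -> list[PredictionRecord]:
        return [r for job in sorted(self.jobs) for r in self.jobs[job]]


# --- entry collection -------------------------------------------------------

def _entries_from_source(source) -> dict[str, bytes]:
    """Map posix-relative path -> bytes for a dir, ZIP path, or ZIP bytes."""
    if isinstance(source, (bytes, bytearray)):
        data = bytes(source)
        if not zipfile.is_zipfile(io.BytesIO(data)):
            raise FormatError("byte input is not a ZIP archive")
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            return {n: zf.read(n) for n in zf.namelist() if not n.endswith("/")}
    path = Path(source)
    if not path.exists():
        raise FormatError(f"input path does not exist: {path}")
    if path.is_dir():
        return {
            p.relative_to(path).as_posix(): p.read_bytes()
            for p in sorted(path.rglob("*"))
            if p.is_file()
        }
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            return {n: zf.read(n) for n in zf.namelist() if not n.endswith("/")}
    raise FormatError(f"input is neither a directory nor a ZIP archive: {path}")


# --- platform detection -----------------------------------------------------

_SIGNATURES: dict[str, list[str]] = {
    "af3": [r"_full_data_\d+\.json$", r"_model_\d+\.cif$"],
    "colabfold": [r"_scores_rank_\d+.*\.json$"],
    "afm": [r"(^|/)ranking_debug\.json$"],
    "boltz": [r"(^|/)pae_.*\.npz$"],
    "chai": [r"(^|/)scores\.model_idx_\d+\.npz$"],
    "openfold3": [r"_of3_model_\d+_confidences\.json$"],
}


def detect_platform(entry_names: list[str]) -> tuple[str, str]:
    """Detect the originating platform from file names alone.

    Returns ``(platform, rationale)``; ``("unknown", ...)`` when no
    signature matches. Raises :class:`AmbiguousPlatformError` when two
    platforms' signatures are both present.
    """
    if not entry_names:
        raise ValueError("entry_names must be non-empty")
    matched: dict[str, list[str]] = {}
    for platform, patterns in _SIGNATURES.items():
        hits = []
        for pat in patterns:
            hit = next((n for n in sorted(entry_names) if re.search(pat, n)), None)
            if hit is None:
                break
            hits.append(hit)
        else:
            matched[platform] = hits
    if len(matched) > 1:
        raise AmbiguousPlatformError(
            "entry names match several platform signatures: "
            + "; ".join(f"{p} (e.g. {h[0]})" for p, h in sorted(matched.items()))
        )
    if not matched:
        tried = ", ".join(f"{p}: {pats[0]}" for p, pats in _SIGNATURES.items())
        return "unknown", f"no signature matched; tried {tried}"
    platform, hits = matched.popitem()
    return platform, f"matched {', '.join(hits)}"


# --- shared helpers ---------------------------------------------------------

def _json(entries: dict[str, bytes], name: str):
    try:
        return json.loads(entries[name].decode())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{name}: invalid JSON ({exc})") from exc


def _npz(entries: dict[str, bytes], name: str) -> dict[str, np.ndarray]:
    with np.load(io.BytesIO(entries[name])) as z:
        return {k: z[k] for k in z.files}


def _parse_model(entries: dict[str, bytes], name: str, fmt: Optional[str] = None):
    try:
        return parse_structure_details(entries[name], fmt)
    except ParseError as exc:
        raise ParseError(f"{name}: {exc}") from exc


def _plddt_0_100(plddt: np.ndarray) -> np.ndarray:
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size and plddt.max() <= 1.0 + 1e-12:
        plddt = plddt * 100.0
    return plddt


def _pair_iptm_from_matrix(mat, chain_ids: list[str]) -> dict[tuple[str, str], float]:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (len(chain_ids), len(chain_ids)):
        raise ConsistencyError(
            f"chain-pair ipTM matrix shape {mat.shape} does not match "
            f"{len(chain_ids)} chains"
        )
    out = {}
    for i, a in enumerate(chain_ids):
        for j, b in enumerate(chain_ids):
            if i < j:
                out[(a, b)] = float(mat[i, j])
    return out


def _bfactor_plddt(bfac: np.ndarray) -> np.ndarray:
    # B-factor columns carry 2 decimals in text formats; restore that grid.
    return np.round(bfac, 2)


# --- dialect loaders --------------------------------------------------------

def _load_af3(entries: dict[str, bytes]) -> PredictionBundle:
    jobs: dict[str, list[PredictionRecord]] = {}
    pattern = re.compile(r"(?P<prefix>.*?)(?P<job>[^/]+)_full_data_(?P<i>\d+)\.json$")
    groups: dict[tuple[str, str], list[int]] = {}
    for n in sorted(entries):
        m = pattern.match(n)
        if m:
            groups.setdefault((m["prefix"], m["job"]), []).append(int(m["i"]))
    if not groups:
        raise FormatError("no *_full_data_N.json entries found for af3 input")
    for (prefix, job), indices in sorted(groups.items()):
        records = []
        for i in sorted(indices):
            base = f"{prefix}{job}"
            cif_name = f"{base}_model_{i}.cif"
            if cif_name not in entries:
                raise FormatError(f"af3 job {job}: missing {cif_name}")
            structure, _, atom_counts = _parse_model(entries, cif_name, "mmcif")
            full = _json(entries, f"{base}_full_data_{i}.json")
            pae = np.asarray(full["pae"], dtype=float)
            atom_plddts = np.asarray(full["atom_plddts"], dtype=float)
            if atom_plddts.size != sum(atom_counts):
                raise ConsistencyError(
                    f"af3 job {job} model {i}: {atom_plddts.size} atom pLDDTs for "
                    f"{sum(atom_counts)} atoms"
                )
            splits = np.cumsum(atom_counts)[:-1]
            plddt = np.array([seg.mean() for seg in np.split(atom_plddts, splits)])
            iptm = ranking = None
            pair_iptm = None
            summary_name = f"{base}_summary_confidences_{i}.json"
            if summary_name in entries:
                summary = _json(entries, summary_name)
                iptm = summary.get("iptm")
                ranking = summary.get("ranking_score")
                if summary.get("chain_pair_iptm") is not None:
                    pair_iptm = _pair_iptm_from_matrix(
                        summary["chain_pair_iptm"], structure.chain_ids
                    )
            conf = ConfidenceData(
                pae=pae,
                plddt=plddt,
                iptm_reported=iptm,
                chain_pair_iptm=pair_iptm,
                ranking_score=ranking,
            )
            records.append(
                PredictionRecord(job, f"model_{i}", "af3", structure, conf)
            )
        # rank by the platform's ranking score when every model has one
        if all(r.confidence.ranking_score is not None for r in records):
            records.sort(key=lambda r: (-r.confidence.ranking_score, r.model_name))
        jobs[job] = records
    return PredictionBundle(jobs=jobs)


def _load_colabfold(entries: dict[str, bytes]) -> PredictionBundle:
    pattern = re.compile(r"(?P<job>[^/]+?)_scores_(?P<model>rank_\d+.*?)\.json$")
    jobs: dict[str, list[PredictionRecord]] = {}
    for n in sorted(entries):
        m = pattern.search(n)
        if not m:
            continue
        pdb_name = n.replace("_scores_", "_unrelaxed_")[: -len(".json")] + ".pdb"
        if pdb_name not in entries:
            raise FormatError(f"colabfold scores {n}: missing coordinates {pdb_name}")
        structure, bfac, _ = _parse_model(entries, pdb_name, "pdb")
        scores = _json(entries, n)
        pae = np.asarray(scores["pae"], dtype=float)
        plddt = (
            np.asarray(scores["plddt"], dtype=float)
            if "plddt" in scores
            else _bfactor_plddt(bfac)
        )
        conf = ConfidenceData(
            pae=pae,
            plddt=_plddt_0_100(plddt),
            iptm_reported=scores.get("iptm"),
            ranking_score=scores.get("iptm"),
        )
        jobs.setdefault(m["job"], []).append(
            PredictionRecord(m["job"], m["model"], "colabfold", structure, conf)
        )
    if not jobs:
        raise FormatError("no *_scores_rank_*.json entries found for colabfold input")
    for records in jobs.values():
        records.sort(key=lambda r: r.model_name)
    return PredictionBundle(jobs=jobs)


def _load_afm(entries: dict[str, bytes]) -> PredictionBundle:
    ranking_names = [
        n for n in sorted(entries) if re.search(r"(^|/)ranking_debug\.json$", n)
    ]
    if not ranking_names:
        raise FormatError("afm input lacks ranking_debug.json")
    jobs: dict[str, list[PredictionRecord]] = {}
    for ranking_name in ranking_names:
        folder = ranking_name[: -len("ranking_debug.json")]
        ranking = _json(entries, ranking_name)
        order = ranking.get("order") or []
        iptm_map = ranking.get("iptm") or {}
        job = folder.rstrip("/").split("/")[-1] if folder.strip("/") else "afm_job"
        pae_pattern = re.compile(re.escape(folder) + r"pae_(?P<model>model_.+?)\.json$")
        models = sorted(m["model"] for n in entries if (m := pae_pattern.match(n)))
        if not models:
            raise FormatError("afm input lacks pae_model_*.json sidecars "
                              "(binary result pickles are not read)")
        if order:
            known = [m for m in order if m in models]
            models = known + [m for m in models if m not in known]
        records = []
        for model in models:
            pdb_name = f"{folder}unrelaxed_{model}.pdb"
            if pdb_name not in entries:
                raise FormatError(f"afm model {model}: missing {pdb_name}")
            structure, bfac, _ = _parse_model(entries, pdb_name, "pdb")
            payload = _json(entries, f"{folder}pae_{model}.json")
            if isinstance(payload, list):
                payload = payload[0]
            pae = np.asarray(payload["predicted_aligned_error"], dtype=float)
            conf = ConfidenceData(
                pae=pae,
                plddt=_bfactor_plddt(bfac),
                iptm_reported=iptm_map.get(model),
                ranking_score=(ranking.get("iptm+ptm") or {}).get(model),
            )
            records.append(PredictionRecord(job, model, "afm", structure, conf))
        jobs[job] = records
    return PredictionBundle(jobs=jobs)


def _load_boltz(entries: dict[str, bytes]) -> PredictionBundle:
    pattern = re.compile(r"(^|.*/)predictions/(?P<job>[^/]+)/pae_(?P=job)_model_(?P<i>\d+)\.npz$")
    jobs: dict[str, list[PredictionRecord]] = {}
    for n in sorted(entries):
        m = pattern.match(n)
        if not m:
            continue
        job, i = m["job"], int(m["i"])
        folder = n[: -len(f"pae_{job}_model_{i}.npz")]
        cif_name = f"{folder}{job}_model_{i}.cif"
        if cif_name not in entries:
            raise FormatError(f"boltz job {job}: missing {cif_name}")
        structure, bfac, _ = _parse_model(entries, cif_name, "mmcif")
        pae = np.asarray(_npz(entries, n)["pae"], dtype=float)
        plddt_name = f"{folder}plddt_{job}_model_{i}.npz"
        if plddt_name in entries:
            plddt = _plddt_0_100(_npz(entries, plddt_name)["plddt"])
        else:
            plddt = _bfactor_plddt(bfac)
        iptm = pair_iptm = None
        conf_name = f"{folder}confidence_{job}_model_{i}.json"
        if conf_name in entries:
            cj = _json(entries, conf_name)
            iptm = cj.get("iptm")
            nested = cj.get("pair_chains_iptm")
            if nested:
                pair_iptm = {
                    (a, b): float(v)
                    for a, row in nested.items()
                    for b, v in row.items()
                    if a < b
                }
        conf = ConfidenceData(
            pae=pae, plddt=plddt, iptm_reported=iptm, chain_pair_iptm=pair_iptm
        )
        jobs.setdefault(job, []).append(
            PredictionRecord(job, f"model_{i}", "boltz", structure, conf)
        )
    if not jobs:
        raise FormatError("no predictions/<job>/pae_*.npz entries found for boltz input")
    return PredictionBundle(jobs=jobs)


def _load_chai(entries: dict[str, bytes]) -> PredictionBundle:
    pattern = re.compile(r"(?P<folder>^|.*/)scores\.model_idx_(?P<i>\d+)\.npz$")
    jobs: dict[str, list[PredictionRecord]] = {}
    for n in sorted(entries):
        m = pattern.match(n)
        if not m:
            continue
        folder, i = m["folder"], int(m["i"])
        job = folder.rstrip("/").split("/")[-1] if folder.strip("/") else "chai_job"
        cif_name = f"{folder}pred.model_idx_{i}.cif"
        if cif_name not in entries:
            raise FormatError(f"chai model_idx_{i}: missing {cif_name}")
        structure, _, _ = _parse_model(entries, cif_name, "mmcif")
        scores = _npz(entries, n)
        pae = np.asarray(scores["pae"], dtype=float)
        if pae.ndim == 3:  # some writers keep a leading batch axis
            pae = pae[0]
        pair_iptm = None
        if "per_chain_pair_iptm" in scores:
            pair_iptm = _pair_iptm_from_matrix(
                np.squeeze(scores["per_chain_pair_iptm"]), structure.chain_ids
            )
        conf = ConfidenceData(
            pae=pae,
            plddt=_plddt_0_100(np.ravel(scores["plddt"])),
            iptm_reported=float(scores["iptm"]) if "iptm" in scores else None,
            ranking_score=float(scores["aggregate_score"])
            if "aggregate_score" in scores
            else None,
            chain_pair_iptm=pair_iptm,
        )
        jobs.setdefault(job, []).append(
            PredictionRecord(job, f"model_idx_{i}", "chai", structure, conf)
        )
    if not jobs:
        raise FormatError("no scores.model_idx_*.npz entries found for chai input")
    return PredictionBundle(jobs=jobs)


def _load_openfold3(entries: dict[str, bytes]) -> PredictionBundle:
    pattern = re.compile(r"(?P<prefix>.*?)(?P<job>[^/]+)_of3_model_(?P<i>\d+)_confidences\.json$")
    jobs: dict[str, list[PredictionRecord]] = {}
    for n in sorted(entries):
        m = pattern.match(n)
        if not m:
            continue
        job, i = m["job"], int(m["i"])
        cif_name = f"{m['prefix']}{job}_of3_model_{i}.cif"
        if cif_name not in entries:
            raise FormatError(f"openfold3 job {job}: missing {cif_name}")
        structure, _, _ = _parse_model(entries, cif_name, "mmcif")
        cj = _json(entries, n)
        conf = ConfidenceData(
            pae=np.asarray(cj["pae"], dtype=float),
            plddt=_plddt_0_100(np.asarray(cj["plddt"], dtype=float)),
            iptm_reported=cj.get("iptm"),
            ranking_score=cj.get("ranking_score"),
        )
        jobs.setdefault(job, []).append(
            PredictionRecord(job, f"model_{i}", "openfold3", structure, conf)
        )
    if not jobs:
        raise FormatError("no *_of3_model_N_confidences.json entries found")
    return PredictionBundle(jobs=jobs)


_LOADERS = {
    "af3": _load_af3,
    "colabfold": _load_colabfold,
    "afm": _load_afm,
    "boltz": _load_boltz,
    "chai": _load_chai,
    "openfold3": _load_openfold3,
}


def load_bundle(source, platform_override: Optional[str] = None) -> PredictionBundle:
    """Load a prediction bundle from a directory, ZIP path, or ZIP bytes.

    The platform is auto-detected from entry names unless
    ``platform_override`` names one of :data:`PLATFORMS`.
    """
    entries = _entries_from_source(source)
    if not entries:
        raise FormatError("input contains no files")
    if platform_override is not None:
        if platform_override not in _LOADERS:
            raise ValueError(f"unknown platform {platform_override!r}; expected one of {PLATFORMS}")
        platform = platform_override
    else:
        platform, rationale = detect_platform(list(entries))
        if platform == "unknown":
            raise UnknownPlatformError(
                f"could not detect prediction platform: {rationale}"
            )
    return _LOADERS[platform](entries)


def list_models(bundle: PredictionBundle) -> pd.DataFrame:
    """One row per model: job, model, platform, size, chains, reported ipTM."""
    rows = []
    for job in sorted(bundle.jobs):
        for rec in bundle.jobs[job]:
            rows.append(
                {
                    "job_id": rec.job_id,
                    "model_name": rec.model_name,
                    "platform": rec.platform,
                    "n_residues": rec.structure.n_residues,
                    "chain_ids": ",".join(rec.structure.chain_ids),
                    "iptm_reported": rec.confidence.iptm_reported,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "job_id", "model_name", "platform", "n_residues", "chain_ids", "iptm_reported",
        ],
    )
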