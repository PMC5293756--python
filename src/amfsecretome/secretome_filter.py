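"""Secretome filtering: signal peptide, topology, targeting, size, duplicates.

A protein is called secreted when it (i) carries an N-terminal signal
peptide, (ii) has no transmembrane segment outside the signal peptide,
(iii) carries no mitochondrial targeting presequence, and (iv) its mature
chain (after signal-peptide cleavage) is at least 15 residues long.  No
upper size limit is applied, and proteins whose mature sequences are exact
duplicates of an already retained protein are discarded.

The filter chain is the contract; the individual predictors are pluggable.
Predictions from external tools (SignalP / TMHMM / Phobius / TargetP) can be
supplied as a TSV override table; when none is given, built-in
hydropathy-based heuristics are used so the pipeline runs fully offline:

* signal peptide — a hydrophobic h-region (window mean Kyte–Doolittle
  hydropathy above a threshold) near the N-terminus followed by a cleavage
  site obeying the (-3,-1) small-residue rule;
* transmembrane segment — a long high-hydropathy window outside the signal
  peptide;
* mitochondrial presequence — an arginine-rich, acidic-residue-free
  N-terminus.

These heuristics are deliberately simple stand-ins calibrated against the
synthetic-data generator; they do not reproduce the external tools' scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog_merge import MergedCatalog, ProteinRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "FilterParams",
    "SignalPrediction",
    "TopologyPrediction",
    "TargetingPrediction",
    "SecretomeEntry",
    "predict_signal_peptide",
    "predict_tm_segments",
    "predict_mito_targeting",
    "read_prediction_table",
    "apply_secretome_filter",
]

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale (kcal-free index units).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

#: Small residues admitted at the (-3) and (-1) positions of a cleavage site.
SMALL_RESIDUES = frozenset("AGSCTV")


@dataclass
class FilterParams:
    """Thresholds for the filter chain and its built-in heuristic predictors.

    ``min_mature_len`` (15 aa) is the biological retention threshold; the
    remaining values calibrate the hydropathy stand-ins: the signal peptide is
    searched within the first ``sp_search_window`` residues as an
    ``h_region_window``-long stretch of mean hydropathy ≥ ``h_region_kd_min``,
    transmembrane helices as ``tm_window``-long stretches of mean hydropathy
    ≥ ``tm_kd_min``, and a mitochondrial presequence as ≥ ``mito_min_R``
    arginines with no D/E among the first ``mito_nterm_len`` residues.
    """

    min_mature_len: int = 15
    sp_search_window: int = 45
    h_region_window: int = 8
    h_region_kd_min: float = 2.0
    tm_kd_min: float = 1.8
    tm_window: int = 19
    mito_nterm_len: int = 25
    mito_min_R: int = 3
    h_region_max_start: int = 35  # 1-based latest allowed h-region start

    def __post_init__(self) -> None:
        for name in (
            "min_mature_len", "sp_search_window", "h_region_window",
            "h_region_kd_min", "tm_kd_min", "tm_window",
            "mito_nterm_len", "mito_min_R", "h_region_max_start",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"FilterParams.{name} must be positive")


@dataclass
class SignalPrediction:
    has_sp: bool
    cleavage_pos: int | None = None  # 1-based index of the LAST signal-peptide residue
    score: float = 0.0


@dataclass
class TopologyPrediction:
    tm_segments: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)


@dataclass
class TargetingPrediction:
    compartment: str  # "secretory" | "mitochondrial" | "other"


@dataclass
class SecretomeEntry:
    """A retained secreted protein with its mature sequence and annotations."""

    protein: ProteinRecord
    mature_sequence: str
    signal: SignalPrediction
    features: dict = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.protein.id


def _hydropathy(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])


def predict_signal_peptide(seq: str, params: FilterParams | None = None) -> SignalPrediction:
    """Heuristic signal-peptide call: hydrophobic h-region plus (-3,-1) rule.

    The first ``h_region_window`` stretch (starting no later than position
    ``h_region_max_start``, 1-based) with mean hydropathy ≥
    ``h_region_kd_min`` is taken as the h-region; the cleavage site is the
    smallest downstream position ``c`` (within ``sp_search_window``) whose
    residues at ``c`` and ``c-2`` are both small (A, G, S, C, T or V).
    ``cleavage_pos`` is the 1-based index of the last signal-peptide residue;
    the mature protein starts at ``cleavage_pos + 1``.
    """
    params = params or FilterParams()
    seq = seq.upper()
    if len(seq) < 5:
        return SignalPrediction(False)
    window = seq[: params.sp_search_window]
    kd = _hydropathy(window)
    w = params.h_region_window
    if len(kd) < w:
        return SignalPrediction(False)
    means = np.convolve(kd, np.ones(w) / w, mode="valid")
    max_start = min(len(means), params.h_region_max_start)  # 0-based start < this
    hits = np.nonzero(means[:max_start] >= params.h_region_kd_min)[0]
    if hits.size == 0:
        return SignalPrediction(False)
    h_start = int(hits[0])
    h_end = h_start + w  # 0-based position just past the h-region
    for c in range(max(h_end + 1, 2), min(len(seq) - 1, params.sp_search_window)):
        if seq[c] in SMALL_RESIDUES and seq[c - 2] in SMALL_RESIDUES:
            return SignalPrediction(True, cleavage_pos=c + 1, score=float(means[h_start]))
    return SignalPrediction(False)


def predict_tm_segments(
    seq: str,
    sp: SignalPrediction | None = None,
    params: FilterParams | None = None,
) -> TopologyPrediction:
    """Sliding-window transmembrane-helix call, discounting the signal peptide.

    All ``tm_window``-long windows with mean hydropathy ≥ ``tm_kd_min`` are
    merged into segments; segments lying entirely within the predicted signal
    peptide (segment end ≤ ``cleavage_pos``) are discounted so a signal
    peptide is not mistaken for a membrane anchor.
    """
    params = params or FilterParams()
    seq = seq.upper()
    w = params.tm_window
    if len(seq) < w:
        return TopologyPrediction([])
    kd = _hydropathy(seq)
    means = np.convolve(kd, np.ones(w) / w, mode="valid")
    covered = np.zeros(len(seq), dtype=bool)
    for start in np.nonzero(means >= params.tm_kd_min)[0]:
        covered[start : start + w] = True
    segments: list[tuple[int, int]] = []
    pos = 0
    while pos < len(seq):
        if covered[pos]:
            end = pos
            while end + 1 < len(seq) and covered[end + 1]:
                end += 1
            segments.append((pos + 1, end + 1))  # 1-based inclusive
            pos = end + 1
        else:
            pos += 1
    cleave = sp.cleavage_pos if (sp is not None and sp.has_sp) else 0
    segments = [s for s in segments if s[1] > cleave]
    return TopologyPrediction(segments)


def predict_mito_targeting(seq: str, params: FilterParams | None = None,
                           sp: SignalPrediction | None = None) -> TargetingPrediction:
    """Arginine-rich, D/E-free N-terminus ⇒ mitochondrial presequence."""
    params = params or FilterParams()
    nterm = seq.upper()[: params.mito_nterm_len]
    if nterm.count("R") >= params.mito_min_R and not set(nterm) & {"D", "E"}:
        return TargetingPrediction("mitochondrial")
    if sp is not None and sp.has_sp:
        return TargetingPrediction("secretory")
    return TargetingPrediction("other")


def read_prediction_table(path: str | Path) -> pd.DataFrame:
    """Read an external-predictor override TSV.

    Columns: ``protein_id  has_sp  cleavage_pos  tm_count  targeting`` and an
    optional boolean ``gpi`` column (GPI-anchored proteins are not considered
    truly secreted and are excluded when the column is present).
    """
    tbl = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "has_sp", "cleavage_pos", "tm_count", "targeting"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"prediction table misses columns {sorted(missing)}")
    return tbl.set_index("protein_id")


def _predict_builtin(record: ProteinRecord, params: FilterParams):
    sp = predict_signal_peptide(record.aa_sequence, params)
    topo = predict_tm_segments(record.aa_sequence, sp, params)
    targ = predict_mito_targeting(record.aa_sequence, params, sp)
    return sp, topo, targ, False


def _predict_from_table(record: ProteinRecord, table: pd.DataFrame):
    row = table.loc[record.id]
    has_sp = bool(row["has_sp"])
    cleave = int(row["cleavage_pos"]) if has_sp else None
    sp = SignalPrediction(has_sp, cleave)
    n_tm = int(row["tm_count"])
    topo = TopologyPrediction([(0, 0)] * n_tm if n_tm else [])
    targ = TargetingPrediction(str(row["targeting"]))
    gpi = bool(row["gpi"]) if "gpi" in table.columns else False
    return sp, topo, targ, gpi


def apply_secretome_filter(
    catalog: MergedCatalog | Iterable[ProteinRecord] | Mapping[str, ProteinRecord],
    predictions: pd.DataFrame | str | Path | None = None,
    params: FilterParams | None = None,
) -> list[SecretomeEntry]:
    """Run the full secretome decision chain over a protein catalog.

    Retains a protein iff it has a signal peptide, zero transmembrane
    segments, a non-mitochondrial targeting call, no GPI anchor (override
    table only) and a mature length of at least ``params.min_mature_len``.
    Exact duplicate mature sequences are collapsed (first id kept).  When an
    override table is given it must cover every catalog id; ids in the table
    absent from the catalog only produce a warning.
    """
    params = params or FilterParams()
    if isinstance(catalog, Mapping):
        records: Sequence[ProteinRecord] = list(catalog.values())
    elif isinstance(catalog, MergedCatalog):
        records = list(catalog.records)
    else:
        records = list(catalog)

    table: pd.DataFrame | None = None
    if predictions is not None:
        table = predictions if isinstance(predictions, pd.DataFrame) else read_prediction_table(predictions)
        ids = {r.id for r in records}
        missing = ids - set(table.index)
        if missing:
            raise ValueError(
                f"prediction table misses {len(missing)} catalog ids "
                f"(e.g. {sorted(missing)[:3]})"
            )
        unknown = set(table.index) - ids
        if unknown:
            warnings.warn(
                f"prediction table covers {len(unknown)} unknown ids "
                f"(e.g. {sorted(unknown)[:3]})",
                stacklevel=2,
            )

    retained: list[SecretomeEntry] = []
    seen_mature: dict[str, str] = {}
    for rec in records:
        if table is not None:
            sp, topo, targ, gpi = _predict_from_table(rec, table)
        else:
            sp, topo, targ, gpi = _predict_builtin(rec, params)
        if not sp.has_sp or topo.tm_count > 0 or targ.compartment == "mitochondrial" or gpi:
            continue
        mature = rec.aa_sequence[sp.cleavage_pos:]
        if len(mature) < params.min_mature_len:
            continue
        if mature in seen_mature:
            logger.info("duplicate mature sequence: %s == %s", rec.id, seen_mature[mature])
            continue
        seen_mature[mature] = rec.id
        retained.append(SecretomeEntry(rec, mature, sp))
    return retained
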