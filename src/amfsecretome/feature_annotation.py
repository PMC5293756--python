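"""Effector-candidate feature annotation of secreted proteins.

Secreted proteins are annotated with the sequence features commonly used to
shortlist fungal effector candidates:

* SCR status — small cysteine-rich proteins (< 200 aa, ≥ 2 cysteines, ≥ 3%
  cysteine content of the mature chain);
* nuclear localization signals (basic-residue-rich windows, or an external
  override table);
* tandem repeat arrays, and their KEX2 class — repeat units carrying a
  conserved [KR]R dipeptide are putatively processed by the Golgi KEX2
  protease into secreted peptides;
* occurrences of a catalog of degenerate motifs described in effectors of
  filamentous plant pathogens (RxLR, [YFW]xC, CRN LFLAK, ...), with
  presence/absence enrichment of the secretome against non-secreted
  proteins and a positional summary;
* paralog tribes (single-linkage clusters by local alignment) and PFAM
  domain enrichment from externally supplied annotations.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparative_sets import local_align, shared_kmer_prefilter, _components
from .differential_expression import bh_fdr
from .secretome_filter import SecretomeEntry

__all__ = [
    "ScrResult",
    "RepeatAnnotation",
    "MotifHit",
    "EnrichmentRow",
    "DEFAULT_MOTIF_CATALOG",
    "MotifPatternError",
    "classify_scr",
    "detect_nls",
    "find_tandem_repeats",
    "classify_rcp_kex2",
    "compile_motif",
    "scan_motif_catalog",
    "motif_enrichment",
    "positional_summary",
    "cluster_tribes",
    "pfam_enrichment",
]

KEX2_SITE = re.compile(r"[KR]R")

#: Known motifs reported in effectors of eukaryotic filamentous plant
#: pathogens, in the degenerate-pattern grammar (``x`` = any residue,
#: ``xN`` = N wildcards, ``[..]`` = alternatives).
DEFAULT_MOTIF_CATALOG: dict[str, str] = {
    "LIxAR": "[LI]xAR",
    "RKC-C-H": "[RK]Cx2Cx12H",
    "RxLx": "RxLx",
    "RxLR": "RxLR",
    "YFWxC": "[YFW]xC",
    "YxSLRK": "YxSL[RK]",
    "WYFCxTYxSTYL": "[WYF]CxTYxSTYL",
    "SGPCKRP": "[SG]PC[KR]P",
    "GIFYxR": "G[IFY][ALST]R",
    "CHxC": "CHxC",
    "FYMRHYVAEYPRCM": "[FY][MR][HY]V[AE]Y[PR]CM",
    "CLAKTWLHM": "CL[AK][TW]LHM",
    "WIHGNWE": "[WI][HG]N[WE]",
    "KECxD": "KECxD",
    "RSIDELD": "RSIDELD",
    "IGYRxVA": "IGYRxVx4A",
    "KAWVIP": "K[AV]W[VI]P",
    "QMLLIP": "Q[ML]LIP",
    "LFLAK": "LFLAK",
}


class MotifPatternError(ValueError):
    """A motif pattern is not valid in the degenerate-pattern grammar."""


@dataclass(frozen=True)
class ScrResult:
    is_scr: bool
    length: int
    cys_count: int
    cys_fraction: float


@dataclass
class RepeatAnnotation:
    """A maximal tandem repeat array on a mature sequence (1-based span)."""

    unit_consensus: str
    unit_length: int
    copy_number: int
    span: tuple[int, int]
    mean_unit_identity: float
    kex2_cleavable: bool


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    pattern: str
    position: int  # 1-based first occurrence start on the mature sequence
    count: int


@dataclass(frozen=True)
class EnrichmentRow:
    feature_id: str
    k_fg: int
    n_fg: int
    k_bg: int
    n_bg: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def _mature(entry: "SecretomeEntry | str") -> str:
    return entry if isinstance(entry, str) else entry.mature_sequence


def classify_scr(entry: "SecretomeEntry | str") -> ScrResult:
    """Small cysteine-rich call: < 200 aa, ≥ 2 Cys, Cys fraction ≥ 3%.

    The length bound is strict (a 200-residue protein is not small); the
    cysteine count and fraction bounds are inclusive.  Applied to the mature
    sequence — the secreted moiety is the biological unit.
    """
    seq = _mature(entry).upper()
    length = len(seq)
    cys = seq.count("C")
    frac = cys / length if length else 0.0
    is_scr = length < 200 and cys >= 2 and frac >= 0.03 - 1e-12
    return ScrResult(is_scr, length, cys, frac)


def detect_nls(
    entry: "SecretomeEntry | str",
    override: Mapping[str, bool] | None = None,
    *,
    window: int = 7,
    min_basic: int = 6,
) -> list[int]:
    """Basic-residue NLS heuristic: 1-based starts of windows with ≥ 6/7 K/R.

    When an ``override`` mapping (protein id → has NLS) covers the entry, it
    wins over the heuristic (an external NLS predictor's table).
    """
    if override is not None and not isinstance(entry, str) and entry.id in override:
        return [1] if override[entry.id] else []
    seq = _mature(entry).upper()
    basic = np.frombuffer(seq.encode(), dtype=np.uint8)
    isb = (basic == ord("K")) | (basic == ord("R"))
    if len(seq) < window:
        return []
    counts = np.convolve(isb.astype(int), np.ones(window, dtype=int), mode="valid")
    starts = np.nonzero(counts >= min_basic)[0]
    # report maximal non-adjacent hits: keep starts not directly continuing a hit
    hits = [int(s) + 1 for i, s in enumerate(starts) if i == 0 or starts[i - 1] != s - 1]
    return hits


def _adjacent_identities(arr: np.ndarray, unit: int) -> np.ndarray:
    """identity[i] between arr[i:i+unit] and arr[i+unit:i+2*unit] for all i."""
    if len(arr) < 2 * unit:
        return np.empty(0)
    eq = (arr[:-unit] == arr[unit:]).astype(float)
    kernel = np.ones(unit) / unit
    return np.convolve(eq, kernel, mode="valid")


def find_tandem_repeats(
    seq: str,
    min_unit: int = 3,
    max_unit: int = 100,
    min_copies: int = 3,
    min_identity: float = 0.7,
) -> list[RepeatAnnotation]:
    """Detect maximal tandem repeat arrays by lag correlation.

    For every candidate unit length *L*, adjacent-unit identities are scored
    along the sequence; runs of at least ``min_copies`` consecutive units
    whose adjacent identities all reach ``min_identity`` are reported.
    Overlapping calls are resolved to the largest array
    (``copy_number × unit_length``), ties to the smaller unit length.
    """
    seq = seq.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    candidates: list[RepeatAnnotation] = []
    for L in range(min_unit, min(max_unit, n // min_copies) + 1):
        ident = _adjacent_identities(arr, L)
        if ident.size == 0:
            continue
        ok = ident >= min_identity - 1e-12
        i = 0
        while i < len(ok):
            if not ok[i]:
                i += 1
                continue
            # count consecutive whole-unit steps i, i+L, i+2L, ...
            start = i
            steps = 0
            j = i
            while j < len(ok) and ok[j]:
                steps += 1
                j += L
            copies = steps + 1
            if copies >= min_copies and not _smaller_period(
                arr[start : start + copies * L], min_unit, min_identity
            ):
                span = (start + 1, start + copies * L)
                units = [seq[start + k * L : start + (k + 1) * L] for k in range(copies)]
                adj = [ident[start + k * L] for k in range(copies - 1)]
                candidates.append(
                    RepeatAnnotation(
                        unit_consensus=_consensus(units),
                        unit_length=L,
                        copy_number=copies,
                        span=span,
                        mean_unit_identity=float(np.mean(adj)),
                        kex2_cleavable=_kex2_conserved(units),
                    )
                )
            # next maximal start for this L: skip starts inside this run's phase
            i += 1
    # greedy overlap resolution: biggest array first, smaller unit on ties,
    # then the cleanest phase (highest adjacent-unit identity)
    candidates.sort(
        key=lambda r: (
            -r.copy_number * r.unit_length,
            r.unit_length,
            -r.mean_unit_identity,
            r.span[0],
        )
    )
    chosen: list[RepeatAnnotation] = []
    taken = np.zeros(n, dtype=bool)
    for cand in candidates:
        s, e = cand.span[0] - 1, cand.span[1]
        if not taken[s:e].any():
            chosen.append(cand)
            taken[s:e] = True
    chosen.sort(key=lambda r: r.span[0])
    return chosen


def _smaller_period(region: np.ndarray, min_unit: int, min_identity: float) -> bool:
    """True when the array region is explained by a period below min_unit.

    Guards against calling e.g. a homopolymer a unit-3 repeat: the true unit
    length there is 1, below the minimum reportable unit.
    """
    for p in range(1, min_unit):
        if len(region) < 2 * p:
            continue
        ident = float(np.mean(region[:-p] == region[p:]))
        if ident >= min_identity - 1e-12:
            return True
    return False


def _consensus(units: Sequence[str]) -> str:
    cols = zip(*units)
    return "".join(max(set(col), key=lambda c: (col.count(c), c)) for col in cols)


def _kex2_conserved(units: Sequence[str]) -> bool:
    """[KR]R at one conserved unit offset in at least copy_number − 1 units."""
    L = len(units[0])
    need = len(units) - 1
    for off in range(L - 1):
        hits = sum(1 for u in units if u[off] in "KR" and u[off + 1] == "R")
        if hits >= need:
            return True
    return False


def classify_rcp_kex2(
    seq: str, repeats: Sequence[RepeatAnnotation] | None = None
) -> str:
    """Repeat-containing-protein class: cleavable_rcp | non_cleavable_rcp | not_rcp."""
    if repeats is None:
        repeats = find_tandem_repeats(seq)
    if not repeats:
        return "not_rcp"
    return "cleavable_rcp" if any(r.kex2_cleavable for r in repeats) else "non_cleavable_rcp"


_TOKEN = re.compile(r"(\[[A-Z]+\])|(x\d*)|([A-Z])")


def compile_motif(pattern: str) -> re.Pattern:
    """Compile a degenerate motif pattern into an overlapping-match regex.

    Grammar: an uppercase letter matches itself, ``x`` any residue, ``xN``
    exactly N arbitrary residues, ``[..]`` any of the bracketed residues.
    """
    out = []
    pos = 0
    for m in _TOKEN.finditer(pattern):
        if m.start() != pos:
            raise MotifPatternError(f"malformed motif pattern {pattern!r} at offset {pos}")
        pos = m.end()
        cls, wild, lit = m.groups()
        if cls:
            out.append(cls)
        elif wild:
            n = wild[1:]
            out.append("." if not n else f".{{{int(n)}}}")
        else:
            out.append(lit)
    if pos != len(pattern) or not out:
        raise MotifPatternError(f"malformed motif pattern {pattern!r} at offset {pos}")
    return re.compile(f"(?=({''.join(out)}))")


def scan_motif_catalog(
    seq: str, catalog: Mapping[str, str] | None = None
) -> list[MotifHit]:
    """Report all (possibly overlapping) catalog-motif occurrences in a sequence.

    Returns one :class:`MotifHit` per motif with at least one occurrence;
    ``position`` is the 1-based start of the first occurrence, ``count`` the
    total number of occurrences.
    """
    catalog = DEFAULT_MOTIF_CATALOG if catalog is None else catalog
    seq = seq.upper()
    hits: list[MotifHit] = []
    for motif_id, pattern in catalog.items():
        rx = compile_motif(pattern)
        positions = [m.start() + 1 for m in rx.finditer(seq)]
        if positions:
            hits.append(MotifHit(motif_id, pattern, positions[0], len(positions)))
    return hits


def _hypergeom_enrichment(counts: list[tuple[str, int, int, int, int]]) -> list[EnrichmentRow]:
    rows = []
    for fid, k_fg, n_fg, k_bg, n_bg in counts:
        if n_fg <= 0 or n_bg <= 0:
            raise ValueError("zero-size foreground or background set")
        # one-sided over-representation: P(X >= k_fg) drawing n_fg from the pool
        p = float(stats.hypergeom.sf(k_fg - 1, n_fg + n_bg, k_fg + k_bg, n_fg))
        a, b = k_fg, n_fg - k_fg
        c, d = k_bg, n_bg - k_bg
        if b == 0 or c == 0:
            odds = float("inf") if a > 0 and d > 0 else (1.0 if a == 0 and c == 0 else float("nan"))
        else:
            odds = (a * d) / (b * c)
        rows.append(EnrichmentRow(fid, k_fg, n_fg, k_bg, n_bg, odds, min(p, 1.0)))
    qs = bh_fdr([r.p for r in rows]) if rows else []
    return [
        EnrichmentRow(r.feature_id, r.k_fg, r.n_fg, r.k_bg, r.n_bg, r.odds_ratio, r.p, q)
        for r, q in zip(rows, qs)
    ]


def motif_enrichment(
    fg_presence: Mapping[str, int],
    n_fg: int,
    bg_presence: Mapping[str, int],
    n_bg: int,
) -> list[EnrichmentRow]:
    """Per-motif one-sided hypergeometric enrichment of the secretome.

    ``fg_presence``/``bg_presence`` count proteins carrying each motif in
    the foreground (secretome) and background (non-secreted) sets; p-values
    are BH-corrected across motifs.
    """
    motifs = sorted(set(fg_presence) | set(bg_presence))
    counts = [
        (m, int(fg_presence.get(m, 0)), n_fg, int(bg_presence.get(m, 0)), n_bg)
        for m in motifs
    ]
    return _hypergeom_enrichment(counts)


def positional_summary(first_positions: Sequence[int]) -> dict[str, float]:
    """Quartile summary of first-hit positions relative to the mature start."""
    if len(first_positions) == 0:
        return {"n": 0, "q1": float("nan"), "median": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(first_positions, [25, 50, 75])
    return {"n": len(first_positions), "q1": float(q1), "median": float(med), "q3": float(q3)}


def cluster_tribes(
    entries: Sequence["SecretomeEntry"],
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
    *,
    prefilter: bool = True,
) -> dict[str, str]:
    """Single-linkage paralog tribes of secreted proteins.

    Two proteins are linked when their local alignment reaches
    ``min_identity`` over at least ``min_coverage`` of the longer sequence;
    tribes are the connected components.  Singletons get the label
    ``unique``; tribes are numbered deterministically by their smallest
    member id.  Returns ``{protein_id: tribe_label}``.
    """
    if not entries:
        raise ValueError("cluster_tribes requires at least one entry")
    seqs = {e.id: e.mature_sequence for e in entries}
    ids = sorted(seqs)
    pairs = list(itertools.combinations(ids, 2))
    if prefilter:
        pairs = shared_kmer_prefilter(seqs, pairs)
    edges = []
    for a, b in pairs:
        hit = local_align(seqs[a], seqs[b], query_id=a, subject_id=b)
        longer = max(len(seqs[a]), len(seqs[b]))
        aligned = hit.aln_length
        if hit.identity >= min_identity and aligned >= min_coverage * longer:
            edges.append((a, b))
    assignment: dict[str, str] = {}
    counter = 0
    for comp in _components(ids, edges):
        if len(comp) == 1:
            assignment[comp[0]] = "unique"
        else:
            counter += 1
            for member in comp:
                assignment[member] = f"tribe_{counter:03d}"
    return assignment


def pfam_enrichment(
    secretome_annotations: Mapping[str, Iterable[str]],
    repertoire_annotations: Mapping[str, Iterable[str]],
) -> list[EnrichmentRow]:
    """Hypergeometric PFAM-domain enrichment of the secretome vs the repertoire.

    Annotations map protein ids to their PFAM domain ids.  The secretome
    must be a subset of the repertoire; the background for each domain is
    the whole repertoire (secretome included), so a domain present in every
    protein is never called enriched.
    """
    missing = set(secretome_annotations) - set(repertoire_annotations)
    if missing:
        raise ValueError(f"secretome ids absent from repertoire: {sorted(missing)[:3]}")
    n_all = len(repertoire_annotations)
    n_sec = len(secretome_annotations)
    dom_all: dict[str, int] = {}
    dom_sec: dict[str, int] = {}
    for pid, doms in repertoire_annotations.items():
        for d in set(doms):
            dom_all[d] = dom_all.get(d, 0) + 1
    for pid, doms in secretome_annotations.items():
        for d in set(doms):
            dom_sec[d] = dom_sec.get(d, 0) + 1
    rows = []
    for d in sorted(dom_all):
        k = dom_sec.get(d, 0)
        K = dom_all[d]
        if n_sec <= 0 or n_all <= 0:
            raise ValueError("zero-size secretome or repertoire")
        p = float(stats.hypergeom.sf(k - 1, n_all, K, n_sec))
        not_sec = n_all - n_sec
        a, b = k, n_sec - k
        c, dd = K - k, not_sec - (K - k)
        odds = (a * dd) / (b * c) if b and c else (float("inf") if a and dd else float("nan"))
        rows.append(EnrichmentRow(d, k, n_sec, K - k, not_sec, odds, min(p, 1.0)))
    qs = bh_fdr([r.p for r in rows]) if rows else []
    return [
        EnrichmentRow(r.feature_id, r.k_fg, r.n_fg, r.k_bg, r.n_bg, r.odds_ratio, r.p, q)
        for r, q in zip(rows, qs)
    ]


def annotate_entry(
    entry: "SecretomeEntry",
    *,
    motif_catalog: Mapping[str, str] | None = None,
    nls_override: Mapping[str, bool] | None = None,
) -> "SecretomeEntry":
    """Populate ``entry.features`` with SCR, NLS, repeat, KEX2 and motif calls."""
    seq = entry.mature_sequence
    repeats = find_tandem_repeats(seq) if len(seq) >= 9 else []
    entry.features.update(
        scr=classify_scr(entry),
        nls_hits=detect_nls(entry, nls_override),
        repeats=repeats,
        rcp_class=classify_rcp_kex2(seq, repeats),
        motif_hits=scan_motif_catalog(seq, motif_catalog),
    )
    return entry
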