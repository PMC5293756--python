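"""Cross-condition set algebra and cross-species sequence grouping.

Given per-comparison differential-expression calls, genes are classified
into multi-host expression categories (up in all hosts, host-specific, up in
extraradical mycelium, up after plant-signal treatment), Venn region counts
and the host-specificity ratio (fraction of the in-planta up-regulated pool
up-regulated in exactly one host) are computed, and up-regulated secreted
proteins of two species are grouped into a core secretome by Smith–Waterman
local alignment with Karlin–Altschul e-values — a desk-scale, exact
replacement for a BLASTP screen (results can differ from heuristic BLAST
near thresholds; an externally computed hit table can be imported instead).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

__all__ = [
    "AlignmentHit",
    "OrthologGroup",
    "SetClassification",
    "local_align",
    "classify_patterns",
    "venn_counts",
    "host_specificity_ratio",
    "round_half_up",
    "cross_species_groups",
    "collapse_isoforms",
    "shared_kmer_prefilter",
    "hits_to_table",
]

#: Karlin–Altschul gapped constants for BLOSUM62 with gap open 11 / extend 1.
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

_BLOSUM62 = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment hit between two sequences."""

    query_id: str
    subject_id: str
    score: int  # raw Smith–Waterman score
    bit_score: float
    identity: float  # identical columns / alignment length
    aln_length: int
    e_value: float
    query_coverage: float = 0.0  # aligned query residues / query length
    subject_coverage: float = 0.0


@dataclass
class OrthologGroup:
    group_id: str
    members: list[str]
    linking_hits: list[AlignmentHit] = field(default_factory=list)


@dataclass
class SetClassification:
    """Multi-condition expression category of one gene.

    The raw up/down label sets are always retained; ``category`` is the
    derived host-centric class.
    """

    gene_id: str
    up_in: frozenset[str]
    down_in: frozenset[str]
    category: str  # common_all_hosts | host_specific:<h> | shared_subset:<h+h> | erm_up | signal_up | none


def _nt_matrix(match: int = 2, mismatch: int = -3) -> balign.SubstitutionMatrix:
    alph = bseq.NucleotideSequence.unambiguous_alphabet()
    n = len(alph)
    mat = np.full((n, n), mismatch, dtype=np.int32)
    np.fill_diagonal(mat, match)
    return balign.SubstitutionMatrix(alph, alph, mat)


def local_align(
    seq_a: str,
    seq_b: str,
    *,
    matrix: balign.SubstitutionMatrix | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "a",
    subject_id: str = "b",
    nucleotide: bool = False,
    karlin_lambda: float = KARLIN_LAMBDA,
    karlin_k: float = KARLIN_K,
) -> AlignmentHit:
    """Optimal Smith–Waterman local alignment with affine gaps.

    A gap of length *k* costs ``gap_open + (k - 1) * gap_extend``.  The raw
    score ``S`` is converted to a bit score ``S' = (λS − ln K) / ln 2`` and an
    e-value ``E = m·n·2^(−S')`` with the (configurable) gapped
    Karlin–Altschul constants for BLOSUM62-11/1.  Identity is counted over
    aligned columns (gapped columns count against identity).
    """
    if not seq_a or not seq_b:
        raise ValueError("local_align requires non-empty sequences")
    if nucleotide:
        matrix = matrix or _nt_matrix()
        sa, sb = bseq.NucleotideSequence(seq_a.upper()), bseq.NucleotideSequence(seq_b.upper())
    else:
        matrix = matrix or _BLOSUM62
        sa, sb = bseq.ProteinSequence(seq_a.upper()), bseq.ProteinSequence(seq_b.upper())
    alns = balign.align_optimal(
        sa, sb, matrix, gap_penalty=(-gap_open, -gap_extend), local=True, max_number=1
    )
    aln = alns[0]
    score = int(aln.score)
    m, n = len(seq_a), len(seq_b)
    if score <= 0 or len(aln.trace) == 0:
        return AlignmentHit(query_id, subject_id, 0, 0.0, 0.0, 0, float(m) * n, 0.0, 0.0)
    trace = aln.trace
    cols = len(trace)
    both = (trace[:, 0] != -1) & (trace[:, 1] != -1)
    codes_a = np.asarray(sa.code)
    codes_b = np.asarray(sb.code)
    ident = int(np.sum(codes_a[trace[both, 0]] == codes_b[trace[both, 1]]))
    bit = (karlin_lambda * score - math.log(karlin_k)) / math.log(2)
    e_value = m * n * 2.0 ** (-bit)
    return AlignmentHit(
        query_id,
        subject_id,
        score,
        bit,
        ident / cols,
        cols,
        e_value,
        query_coverage=int(np.sum(trace[:, 0] != -1)) / m,
        subject_coverage=int(np.sum(trace[:, 1] != -1)) / n,
    )


def shared_kmer_prefilter(
    seqs: Mapping[str, str], pairs: Iterable[tuple[str, str]], k: int = 5
) -> list[tuple[str, str]]:
    """Keep only pairs sharing at least one exact k-mer (BLAST-like seeding).

    A cheap screen before all-vs-all Smith–Waterman; unrelated random
    proteins rarely share a 5-mer while homologs above ~30% identity over a
    meaningful span essentially always do.
    """
    kmers = {
        sid: {s[i : i + k] for i in range(len(s) - k + 1)} for sid, s in seqs.items()
    }
    return [(a, b) for a, b in pairs if kmers[a] & kmers[b]]


def _components(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> list[list[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for n in parent:
        groups.setdefault(find(n), []).append(n)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


# ---------------------------------------------------------------------------
# expression-pattern set algebra
# ---------------------------------------------------------------------------

def classify_patterns(
    calls: Mapping[str, pd.DataFrame],
    design,
) -> list[SetClassification]:
    """Derive per-gene multi-condition categories from per-comparison calls.

    ``calls`` maps each comparison label of the design to that comparison's
    expression-result table (columns ``gene_id`` and ``call``).  Categories,
    in priority order: up in every host comparison → ``common_all_hosts``;
    up in exactly one host → ``host_specific:<host>``; up in several but not
    all hosts → ``shared_subset:<h1+h2>``; otherwise up in an ERM comparison
    → ``erm_up``; otherwise up after a plant-signal treatment → ``signal_up``;
    otherwise ``none``.  The raw label sets are kept alongside, so a gene can
    be counted in several pools (in-planta, ERM, signal) at once.
    """
    missing = [c.label for c in design.comparisons if c.label not in calls]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    host_labels = set(design.host_labels)
    erm_labels = set(getattr(design, "erm_labels", set()))
    signal_labels = set(getattr(design, "signal_labels", set()))

    gene_ids: list[str] = []
    seen: set[str] = set()
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for label, tbl in calls.items():
        for gid, call in zip(tbl["gene_id"], tbl["call"]):
            if gid not in seen:
                seen.add(gid)
                gene_ids.append(gid)
            if call == "up":
                up.setdefault(gid, set()).add(label)
            elif call == "down":
                down.setdefault(gid, set()).add(label)

    out: list[SetClassification] = []
    for gid in gene_ids:
        u = frozenset(up.get(gid, set()))
        d = frozenset(down.get(gid, set()))
        hosts_up = u & host_labels
        if host_labels and hosts_up == host_labels:
            cat = "common_all_hosts"
        elif len(hosts_up) == 1:
            cat = f"host_specific:{next(iter(hosts_up))}"
        elif len(hosts_up) > 1:
            cat = "shared_subset:" + "+".join(sorted(hosts_up))
        elif u & erm_labels:
            cat = "erm_up"
        elif u & signal_labels:
            cat = "signal_up"
        else:
            cat = "none"
        out.append(SetClassification(gid, u, d, cat))
    return out


def venn_counts(
    classifications: Sequence[SetClassification],
    labels: Iterable[str],
    *,
    direction: str = "up",
) -> dict[frozenset[str], int]:
    """Count genes per region of the label power set (non-empty regions).

    The regions partition the pool of genes carrying at least one of
    ``labels``; the sum over regions equals the pool size.
    """
    labels = frozenset(labels)
    counts: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(labels) + 1)
        for sub in itertools.combinations(sorted(labels), r)
    }
    for c in classifications:
        member = (c.up_in if direction == "up" else c.down_in) & labels
        if member:
            counts[frozenset(member)] += 1
    assert sum(counts.values()) == sum(
        1 for c in classifications
        if (c.up_in if direction == "up" else c.down_in) & labels
    )
    return counts


def host_specificity_ratio(
    region_counts: Mapping[frozenset[str], int] | Mapping[tuple, int],
    host_labels: Iterable[str],
) -> float:
    """Percentage of the in-planta up-pool up-regulated in exactly one host.

    Returns full precision; use :func:`round_half_up` for the integer
    rendering used in reports.  Raises on an empty pool.
    """
    hosts = frozenset(host_labels)
    single = total = 0
    for region, n in region_counts.items():
        overlap = frozenset(region) & hosts
        if overlap:
            total += n
            if len(overlap) == 1:
                single += n
    if total == 0:
        raise ValueError("empty in-planta up-pool: host-specificity undefined")
    return 100.0 * single / total


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero (matching conventional report rendering)."""
    factor = 10.0 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# cross-species grouping
# ---------------------------------------------------------------------------

def _entry_seqs(entries) -> dict[str, str]:
    out = {}
    for e in entries:
        seq = getattr(e, "mature_sequence", None) or getattr(e, "aa_sequence", None) or str(e[1])
        eid = getattr(e, "id", None) or str(e[0])
        out[eid] = seq
    return out


def cross_species_groups(
    entries_a,
    entries_b,
    e_threshold: float = 1e-5,
    *,
    prefilter: bool = False,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[OrthologGroup]:
    """Group up-regulated secreted proteins of two species by homology.

    All pairwise Smith–Waterman hits (cross-species and within-species, so
    paralogs can join one sequence group) with e-value below ``e_threshold``
    form a graph; the sequence groups are its connected components that
    contain at least one member of each species.  ``prefilter`` enables the
    shared-k-mer seed screen for large inputs; it can miss marginal homologs
    and is off by default because the up-regulated pools are small.
    """
    seqs_a, seqs_b = _entry_seqs(entries_a), _entry_seqs(entries_b)
    if not seqs_a or not seqs_b:
        raise ValueError("both entry sets must be non-empty")
    seqs = {**seqs_a, **seqs_b}
    ids = sorted(seqs)
    pairs = list(itertools.combinations(ids, 2))
    if prefilter:
        pairs = shared_kmer_prefilter(seqs, pairs)
    hits: list[AlignmentHit] = []
    for a, b in pairs:
        hit = local_align(seqs[a], seqs[b], gap_open=gap_open, gap_extend=gap_extend,
                          query_id=a, subject_id=b)
        if hit.e_value < e_threshold:
            hits.append(hit)
    edges = [(h.query_id, h.subject_id) for h in hits]
    groups = []
    counter = 0
    for comp in _components(ids, edges):
        in_a = any(m in seqs_a for m in comp)
        in_b = any(m in seqs_b for m in comp)
        if in_a and in_b:
            counter += 1
            linking = [h for h in hits if h.query_id in comp and h.subject_id in comp]
            groups.append(OrthologGroup(f"G{counter:02d}", comp, linking))
    return groups


def collapse_isoforms(
    transcripts: Mapping[str, str],
    min_identity: float = 0.97,
    min_query_coverage: float = 0.50,
    min_subject_coverage: float = 0.10,
    *,
    prefilter: bool = True,
) -> tuple[list[str], dict[str, str]]:
    """Collapse near-identical nucleotide transcripts into representatives.

    Two transcripts are linked when a local alignment reaches identity >
    ``min_identity`` with coverage > ``min_query_coverage`` of one sequence
    and > ``min_subject_coverage`` of the other; clusters are single-linkage
    and the longest member represents each cluster.  Returns the
    representative ids and an ``{id: representative}`` map.
    """
    ids = sorted(transcripts)
    pairs = list(itertools.combinations(ids, 2))
    if prefilter:
        pairs = shared_kmer_prefilter(transcripts, pairs, k=11)
    edges = []
    for a, b in pairs:
        hit = local_align(transcripts[a], transcripts[b], nucleotide=True,
                          gap_open=5, gap_extend=2, query_id=a, subject_id=b)
        if hit.aln_length == 0:
            continue
        cov_hi = max(hit.query_coverage, hit.subject_coverage)
        cov_lo = min(hit.query_coverage, hit.subject_coverage)
        if hit.identity > min_identity and cov_hi > min_query_coverage and cov_lo > min_subject_coverage:
            edges.append((a, b))
    reps: list[str] = []
    isoform_map: dict[str, str] = {}
    for comp in _components(ids, edges):
        rep = max(comp, key=lambda i: (len(transcripts[i]), i))
        reps.append(rep)
        for member in comp:
            isoform_map[member] = rep
    return sorted(reps), isoform_map


def hits_to_table(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    """Render hits in a BLAST-tabular-like 12-column layout."""
    rows = [
        {
            "query_id": h.query_id, "subject_id": h.subject_id,
            "pct_identity": 100.0 * h.identity, "aln_length": h.aln_length,
            "mismatches": pd.NA, "gap_opens": pd.NA,
            "q_start": pd.NA, "q_end": pd.NA, "s_start": pd.NA, "s_end": pd.NA,
            "e_value": h.e_value, "bit_score": h.bit_score,
        }
        for h in hits
    ]
    return pd.DataFrame(rows)
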