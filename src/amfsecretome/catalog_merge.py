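"""Consensus gene-catalog merging from two independent assemblies.

Two draft assemblies of the same organism rarely agree on gene models: each
contains genes the other misses, and a single locus may be represented as one
complete ORF in one assembly but as several fragments in the other.  Given a
cross-mapping table between the two catalogs (e.g. derived from a spliced
aligner run), :func:`resolve_consensus` arbitrates every locus into one of
five classes:

* genes unique to catalog A or to catalog B are kept as-is;
* when several catalog-A fragments map onto one catalog-B gene, the complete
  B gene supersedes the fragments (and symmetrically for fragmented B genes);
* for one-to-one matches the catalog-A representative is kept, unless only
  the B definition is supported by RNA-seq evidence.

ORFs lacking a start or a stop codon are discarded after arbitration, and
exact duplicate protein sequences are collapsed with provenance retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "CrossMapRow",
    "MergedCatalog",
    "CatalogError",
    "load_catalog",
    "read_crossmap",
    "validate_orf",
    "resolve_consensus",
    "write_merged",
]

_VALID_FLAGS = {"one_to_one", "query_fragmented", "target_fragmented"}
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class CatalogError(ValueError):
    """Malformed catalog, cross-map, or inconsistent locus assignment."""


@dataclass
class ProteinRecord:
    """A single protein-coding gene model from one source catalog."""

    id: str
    species: str
    aa_sequence: str
    source_catalog: str = "A"  # "A", "B" or "merged"
    has_start: bool = True
    has_stop: bool = True
    rnaseq_supported: bool = True

    def __post_init__(self) -> None:
        self.aa_sequence = self.aa_sequence.upper().rstrip("*")
        if len(self.aa_sequence) < 1:
            raise CatalogError(f"empty sequence for record {self.id!r}")
        bad = set(self.aa_sequence) - _AA_ALPHABET
        if bad:
            raise CatalogError(
                f"record {self.id!r} contains non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class CrossMapRow:
    """One mapping between a catalog-A gene (query) and a catalog-B gene (target)."""

    query_id: str
    target_id: str
    coverage: float
    identity: float
    fragment_flag: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise CatalogError(
                f"coverage/identity outside [0,1] for {self.query_id}->{self.target_id}"
            )
        if self.fragment_flag not in _VALID_FLAGS:
            raise CatalogError(
                f"unknown fragment_flag {self.fragment_flag!r} "
                f"for {self.query_id}->{self.target_id}"
            )


@dataclass
class MergedCatalog:
    """Arbitrated non-redundant catalog with per-gene class labels.

    ``class_labels`` maps every retained id to one of ``A_only``, ``B_only``,
    ``B_replaces_fragmented_A``, ``A_representative_of_pair``,
    ``A_replaces_fragmented_B``.  ``dropped`` maps every non-retained input id
    to the reason it was removed, so retained + dropped partition the input.
    """

    records: list[ProteinRecord]
    class_labels: dict[str, str]
    provenance: dict[str, list[str]]
    dropped: dict[str, str] = field(default_factory=dict)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_catalog(
    fasta_path: str | Path,
    flags_table: str | Path | None = None,
    *,
    species: str = "",
    source_catalog: str = "A",
) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into an ordered ``{id: ProteinRecord}`` mapping.

    ``flags_table`` is an optional TSV with columns ``protein_id``,
    ``has_start``, ``has_stop``, ``rnaseq_supported``; all flags default to
    true when absent.  Duplicate FASTA ids raise :class:`CatalogError`.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    flags: dict[str, dict] = {}
    if flags_table is not None:
        tbl = pd.read_csv(flags_table, sep="\t", dtype={"protein_id": str})
        for row in tbl.itertuples(index=False):
            flags[row.protein_id] = {
                "has_start": bool(getattr(row, "has_start", True)),
                "has_stop": bool(getattr(row, "has_stop", True)),
                "rnaseq_supported": bool(getattr(row, "rnaseq_supported", True)),
            }
    records: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if not entry.id or len(entry.seq) == 0:
            raise CatalogError(f"malformed FASTA entry {entry.id!r} in {fasta_path}")
        if entry.id in records:
            raise CatalogError(f"duplicate id {entry.id!r} in {fasta_path}")
        records[entry.id] = ProteinRecord(
            id=entry.id,
            species=species,
            aa_sequence=str(entry.seq),
            source_catalog=source_catalog,
            **flags.get(entry.id, {}),
        )
    return records


def read_crossmap(tsv_path: str | Path) -> list[CrossMapRow]:
    """Read a cross-map TSV (`query_id target_id coverage identity fragment_flag`)."""
    tbl = pd.read_csv(tsv_path, sep="\t", dtype={"query_id": str, "target_id": str})
    return [
        CrossMapRow(r.query_id, r.target_id, float(r.coverage), float(r.identity), r.fragment_flag)
        for r in tbl.itertuples(index=False)
    ]


def validate_orf(record: ProteinRecord) -> bool:
    """Keep an ORF only when it carries both a start and a stop codon."""
    return record.has_start and record.has_stop


def _check_flag_consistency(crossmap: Iterable[CrossMapRow]) -> None:
    by_query: dict[str, set[str]] = {}
    by_target: dict[str, set[str]] = {}
    for row in crossmap:
        by_query.setdefault(row.query_id, set()).add(row.fragment_flag)
        by_target.setdefault(row.target_id, set()).add(row.fragment_flag)
    for gid, flags in list(by_query.items()) + list(by_target.items()):
        if len(flags) > 1:
            raise CatalogError(
                f"gene {gid!r} participates in contradictory fragment flags: {sorted(flags)}"
            )


def _pick_winner(
    default: ProteinRecord, losers: list[ProteinRecord]
) -> tuple[ProteinRecord, str]:
    """RNA-seq support overrides the default winner; length breaks dead ties.

    Returns the winning record and a short note ("" when the default stood).
    """
    if default.rnaseq_supported:
        return default, ""
    supported = [r for r in losers if r.rnaseq_supported]
    if supported:
        winner = max(supported, key=lambda r: (len(r), r.id))
        return winner, f"rnaseq_support_over_{default.id}"
    # neither definition supported: keep the longest ORF overall
    pool = [default, *losers]
    winner = max(pool, key=lambda r: (len(r), r.id))
    if winner is default:
        return default, ""
    return winner, f"longer_orf_over_{default.id}"


def resolve_consensus(
    cat_a: Mapping[str, ProteinRecord],
    cat_b: Mapping[str, ProteinRecord],
    crossmap: Iterable[CrossMapRow],
) -> MergedCatalog:
    """Arbitrate two catalogs of the same organism into one consensus catalog.

    Every input gene ends up either retained (with a class label) or in
    ``dropped`` with a reason; the split is invariant to cross-map row order.
    """
    crossmap = sorted(crossmap, key=lambda r: (r.query_id, r.target_id))
    for row in crossmap:
        if row.query_id not in cat_a:
            raise CatalogError(f"cross-map query id {row.query_id!r} not in catalog A")
        if row.target_id not in cat_b:
            raise CatalogError(f"cross-map target id {row.target_id!r} not in catalog B")
    _check_flag_consistency(crossmap)

    mapped_a = {r.query_id for r in crossmap}
    mapped_b = {r.target_id for r in crossmap}

    selected: list[tuple[ProteinRecord, str, list[str]]] = []  # record, label, sources
    dropped: dict[str, str] = {}

    for aid in cat_a:
        if aid not in mapped_a:
            selected.append((cat_a[aid], "A_only", [aid]))
    for bid in cat_b:
        if bid not in mapped_b:
            selected.append((cat_b[bid], "B_only", [bid]))

    # class-C analog: several catalog-A fragments covered by one B gene
    frag_a_rows = [r for r in crossmap if r.fragment_flag == "query_fragmented"]
    by_b: dict[str, list[CrossMapRow]] = {}
    for row in frag_a_rows:
        by_b.setdefault(row.target_id, []).append(row)
    for bid in sorted(by_b):
        frags = [cat_a[r.query_id] for r in by_b[bid]]
        winner, note = _pick_winner(cat_b[bid], frags)
        label = "B_replaces_fragmented_A" if winner.id == bid else "A_replaces_fragmented_B"
        sources = sorted({bid, *(f.id for f in frags)})
        selected.append((winner, label, sources))
        for rec in (cat_b[bid], *frags):
            if rec.id != winner.id:
                dropped[rec.id] = f"superseded_by_{winner.id}" + (f" ({note})" if note else "")

    # class-E analog: several catalog-B fragments covered by one A gene
    frag_b_rows = [r for r in crossmap if r.fragment_flag == "target_fragmented"]
    by_a: dict[str, list[CrossMapRow]] = {}
    for row in frag_b_rows:
        by_a.setdefault(row.query_id, []).append(row)
    for aid in sorted(by_a):
        frags = [cat_b[r.target_id] for r in by_a[aid]]
        winner, note = _pick_winner(cat_a[aid], frags)
        label = "A_replaces_fragmented_B" if winner.id == aid else "B_replaces_fragmented_A"
        sources = sorted({aid, *(f.id for f in frags)})
        selected.append((winner, label, sources))
        for rec in (cat_a[aid], *frags):
            if rec.id != winner.id:
                dropped[rec.id] = f"superseded_by_{winner.id}" + (f" ({note})" if note else "")

    # class-D analog: one-to-one pairs, catalog-A representative preferred
    pair_rows = [r for r in crossmap if r.fragment_flag == "one_to_one"]
    by_a_pair: dict[str, list[CrossMapRow]] = {}
    for row in pair_rows:
        by_a_pair.setdefault(row.query_id, []).append(row)
    for aid in sorted(by_a_pair):
        partners = [cat_b[r.target_id] for r in by_a_pair[aid]]
        winner, note = _pick_winner(cat_a[aid], partners)
        # the label marks the locus class; the RNA-seq rule may put the B
        # definition forward as the pair's representative
        label = "A_representative_of_pair"
        sources = sorted({aid, *(p.id for p in partners)})
        selected.append((winner, label, sources))
        for rec in (cat_a[aid], *partners):
            if rec.id != winner.id:
                dropped[rec.id] = f"superseded_by_{winner.id}" + (f" ({note})" if note else "")

    # ORF validation after arbitration
    validated: list[tuple[ProteinRecord, str, list[str]]] = []
    for rec, label, sources in selected:
        if validate_orf(rec):
            validated.append((rec, label, sources))
        else:
            dropped[rec.id] = "missing_start_or_stop"

    # exact duplicate removal on the full amino-acid sequence
    records: list[ProteinRecord] = []
    class_labels: dict[str, str] = {}
    provenance: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for rec, label, sources in sorted(validated, key=lambda t: (t[0].source_catalog, t[0].id)):
        key = rec.aa_sequence.upper()
        if key in seen:
            keeper = seen[key]
            dropped[rec.id] = f"duplicate_of_{keeper}"
            provenance[keeper] = sorted(set(provenance[keeper]) | set(sources))
            continue
        seen[key] = rec.id
        records.append(rec)
        class_labels[rec.id] = label
        provenance[rec.id] = sources

    return MergedCatalog(records, class_labels, provenance, dropped)


def write_merged(merged: MergedCatalog, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the merged catalog as FASTA plus a class-label sidecar TSV."""
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    sidecar = out_prefix.with_suffix(".classes.tsv")
    with open(fasta, "w") as fh:
        for rec in merged.records:
            fh.write(f">{rec.id}\n{rec.aa_sequence}\n")
    rows = [
        {
            "protein_id": rec.id,
            "class_label": merged.class_labels[rec.id],
            "sources": ",".join(merged.provenance[rec.id]),
        }
        for rec in merged.records
    ]
    pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)
    return fasta, sidecar
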