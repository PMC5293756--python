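"""Seeded synthetic study generator with known ground truth.

Emulates the inputs of a two-species comparative secretome study so the
whole pipeline can be exercised and validated offline:

* species 1 is represented by two partially overlapping assembly catalogs
  (A and B) plus a cross-mapping table, with planted unique genes,
  one-to-one pairs, fragmented gene pairs, RNA-seq-unsupported definitions
  and exact duplicates — the arbitration ground truth is known;
* species 2 is a single catalog (a transcriptome-assembly analog);
* planted protein features: signal peptides with known cleavage sites
  (n/h/c architecture compatible with the filter heuristics),
  transmembrane helices, mitochondrial presequences, small cysteine-rich
  proteins, nuclear localization signals, tandem repeat arrays with or
  without conserved KEX2 [KR]R sites, effector-catalog motifs, and
  cross-species homolog families mutated to a target identity;
* triplicate count matrices over pre-symbiotic and symbiotic conditions
  (germinating spores as reference, GR24, root exudates, intraradical
  mycelium per host, extraradical mycelium) with planted common-up,
  host-specific-up, ERM-up and signal-responsive fold changes under
  beta-binomial noise.

Truth labels are kept consistent with the emitted sequences by
construction: planted-negative proteins are rejection-sampled until the
built-in predictors do not fire on them (see docs/methods.md), so the
planted secretome is exactly the set of proteins the filter chain is
expected to retain.

Everything is driven by one :class:`numpy.random.Generator`; the same seed
reproduces the study byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog_merge import CrossMapRow, ProteinRecord
from .differential_expression import Comparison, ComparisonDesign, CountMatrix
from .secretome_filter import (
    FilterParams,
    predict_mito_targeting,
    predict_signal_peptide,
    predict_tm_segments,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_proteomes",
    "generate_counts",
    "generate_crossmap_fixture",
    "default_design",
    "write_study",
]

#: Average natural residue frequencies (Swiss-Prot-like), used as the default
#: background composition.  A uniform alphabet would make cysteine 5% of all
#: residues (voiding the small-cysteine-rich definition) and inflate
#: hydropathy false calls, so natural composition is the default.
NATURAL_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

_PLANTED_MOTIFS: dict[str, str] = {
    # motif id -> a concrete instantiation template; lowercase x drawn randomly
    "RSIDELD": "RSIDELD",
    "KECxD": "KECxD",
    "YxSLRK": "YxSLR",
    "LFLAK": "LFLAK",
    "WIHGNWE": "WHNW",
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Counts emulate triplicate libraries over the condition panel of a
    two-species mycorrhizal expression study; ``phi`` is the squared
    biological coefficient of variation of the per-gene proportion across
    replicates (Var(p) = φ·π²), the standard RNA-seq meaning of a
    dispersion of 0.05.
    """

    seed: int = 0
    n_genes: int = 3000  # per species
    fraction_secreted: float = 0.10
    # feature rates among planted secreted proteins
    scr_rate: float = 0.30
    nls_rate: float = 0.10
    rcp_rate: float = 0.10
    rcp_kex2_fraction: float = 0.5
    motif_rate: float = 0.15
    # rates among planted non-secreted proteins
    tm_rate: float = 0.10
    mito_rate: float = 0.05
    motif_bg_rate: float = 0.03
    # catalog structure (species 1)
    a_only_rate: float = 0.20
    b_only_rate: float = 0.10
    fragment_rate: float = 0.05  # split evenly between A- and B-fragmented loci
    unsupported_rate: float = 0.02  # one-to-one loci where only B is RNA-seq supported
    duplicate_rate: float = 0.02
    # cross-species homology
    n_homolog_families: int = 20
    homolog_identity: float = 0.60
    # sequence lengths
    length_log_median: float = 350.0
    length_log_sigma: float = 0.4
    # expression design
    conditions: tuple[str, ...] = (
        "reference", "GR24", "exudates", "IRM_Mt", "IRM_Bd", "IRM_Lc", "ERM",
    )
    species2_conditions: tuple[str, ...] = (
        "reference", "GR24", "exudates", "IRM_Mt", "IRM_Bd", "ERM",
    )
    replicates: int = 3
    library_size_mean: int = 1_000_000
    library_size_sigma: float = 0.1
    phi: float = 0.005
    noise_model: str = "beta_binomial"  # or "negative_binomial"
    de_fold_change: float = 8.0
    n_common_up: int = 40
    n_host_specific_up: int = 10  # per host
    n_erm_up: int = 15
    n_signal_up: int = 15
    baseline_pi_range: tuple[float, float] = (5e-6, 5e-4)
    de_baseline_pi_range: tuple[float, float] = (2e-4, 1e-3)
    composition: Mapping[str, float] = field(default_factory=lambda: dict(NATURAL_COMPOSITION))
    filter_params: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        for name in ("fraction_secreted", "scr_rate", "nls_rate", "rcp_rate",
                     "motif_rate", "tm_rate", "mito_rate", "a_only_rate",
                     "b_only_rate", "fragment_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"GeneratorConfig.{name} must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tm_rate + self.mito_rate > 1.0:
            raise ValueError("tm_rate + mito_rate exceed the non-secreted fraction")
        if self.a_only_rate + self.b_only_rate + self.fragment_rate > 1.0:
            raise ValueError("catalog-structure rates exceed 1")


@dataclass
class SyntheticTruth:
    """Planted feature labels and expression design, consistent with the data."""

    features: pd.DataFrame  # indexed by protein id
    consensus_ids: dict[int, list[str]]  # species -> expected merged catalog ids
    de_sets: dict[int, dict[str, str]]  # species -> gene id -> set name
    true_fc: dict[int, pd.DataFrame]  # species -> genes x conditions fold multipliers
    baseline_pi: dict[int, pd.Series]  # species -> per-gene baseline proportion


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    catalog_a: dict[str, ProteinRecord]
    catalog_b: dict[str, ProteinRecord]
    crossmap: list[CrossMapRow]
    species2_catalog: dict[str, ProteinRecord]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------

def _residues(rng: np.random.Generator, n: int, comp: Mapping[str, float]) -> str:
    letters = np.array(sorted(comp))
    probs = np.array([comp[l] for l in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def _signal_peptide(rng: np.random.Generator) -> str:
    """n/h/c signal peptide with a deterministic (-3,-1) cleavage site.

    The h-region uses {L, I, F} only (none of which are small residues), and
    the c-region 'QNAQA' admits exactly one small-small dipeptide, so the
    cleavage position equals the peptide length by construction.
    """
    n_region = "M" + _residues(rng, rng.integers(2, 5), {"K": .3, "N": .3, "Q": .2, "T": .2})
    h_len = int(rng.integers(8, 13))
    h_region = "".join(rng.choice(["L", "I", "F"], size=h_len))
    return n_region + h_region + "QNAQA"


def _mito_presequence(rng: np.random.Generator) -> str:
    """Arginine-rich, D/E-free N-terminal presequence (25 residues)."""
    pool = {"R": 0.25, "L": 0.25, "S": 0.15, "T": 0.1, "A": 0.15, "F": 0.1}
    while True:
        seq = "M" + _residues(rng, 24, pool)
        if seq.count("R") >= 4:
            return seq


def _tm_helix(rng: np.random.Generator) -> str:
    return "".join(rng.choice(["L", "I", "V", "F"], size=21))


def _plant(seq: str, insert: str, pos: int) -> str:
    """Overwrite (not insert) residues so lengths stay fixed."""
    return seq[:pos] + insert + seq[pos + len(insert):]


def _instantiate_motif(rng: np.random.Generator, template: str,
                       comp: Mapping[str, float]) -> str:
    return "".join(_residues(rng, 1, comp) if c == "x" else c for c in template)


def _repeat_array(rng: np.random.Generator, comp: Mapping[str, float],
                  kex2: bool) -> str:
    """Tandem array of 4–7 units (8–15 aa) mutated at 10% between copies."""
    unit_len = int(rng.integers(8, 16))
    copies = int(rng.integers(4, 8))
    unit = list(_residues(rng, unit_len, comp))
    if kex2:
        unit[0] = str(rng.choice(["K", "R"]))
        unit[1] = "R"
    alphabet = sorted(comp)
    while True:
        parts = []
        for _ in range(copies):
            u = list(unit)
            for i in range(2 if kex2 else 0, unit_len):
                if rng.random() < 0.10:
                    u[i] = str(rng.choice(alphabet))
            if not kex2 and len(u) > 1:
                # keep the array free of a conserved [KR]R signature
                if u[0] in "KR" and u[1] == "R":
                    u[1] = "A"
            parts.append("".join(u))
        arr = "".join(parts)
        from .feature_annotation import find_tandem_repeats, classify_rcp_kex2
        calls = find_tandem_repeats(arr)
        if calls and classify_rcp_kex2(arr, calls) == (
            "cleavable_rcp" if kex2 else "non_cleavable_rcp"
        ):
            return arr


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float,
                        comp: Mapping[str, float]) -> str:
    out = list(seq)
    alphabet = sorted(comp)
    for i, c in enumerate(out):
        if rng.random() > identity:
            choices = [a for a in alphabet if a != c]
            out[i] = str(rng.choice(choices))
    return "".join(out)


# ---------------------------------------------------------------------------
# per-protein construction
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    return max(60, int(rng.lognormal(np.log(cfg.length_log_median), cfg.length_log_sigma)))


def _passes_as_secreted(seq: str, cleavage: int, params: FilterParams) -> bool:
    sp = predict_signal_peptide(seq, params)
    if not sp.has_sp or abs(sp.cleavage_pos - cleavage) > 1:
        return False
    if predict_tm_segments(seq, sp, params).tm_count:
        return False
    return predict_mito_targeting(seq, params, sp).compartment != "mitochondrial"


def _looks_secreted(seq: str, params: FilterParams) -> bool:
    sp = predict_signal_peptide(seq, params)
    if not sp.has_sp:
        return False
    if predict_tm_segments(seq, sp, params).tm_count:
        return False
    if predict_mito_targeting(seq, params, sp).compartment == "mitochondrial":
        return False
    return len(seq) - sp.cleavage_pos >= params.min_mature_len


def _build_secreted(rng, cfg, *, scr: bool, nls: bool, rcp: str, motif: str | None):
    """Returns (sequence, cleavage_pos, motif_id).  rcp in {'', 'kex2', 'plain'}."""
    params = cfg.filter_params
    while True:
        sp = _signal_peptide(rng)
        cleavage = len(sp)
        if scr:
            mat_len = int(rng.integers(60, 190))
        else:
            mat_len = max(params.min_mature_len, _draw_length(rng, cfg) - cleavage)
        mature = _residues(rng, mat_len, cfg.composition)
        if scr:
            # plant cysteines up to >= 4% of the mature length (and >= 3)
            target = max(3, int(np.ceil(0.04 * mat_len)))
            pos = rng.choice(mat_len, size=target, replace=False)
            mature = "".join("C" if i in set(pos.tolist()) else c for i, c in enumerate(mature))
        if rcp:
            arr = _repeat_array(rng, cfg.composition, kex2=(rcp == "kex2"))
            if len(arr) + 10 < mat_len:
                mature = _plant(mature, arr, int(rng.integers(5, mat_len - len(arr) - 2)))
        if nls and mat_len > 45:
            nls_seq = "".join(rng.choice(["K", "R"], size=7))
            mature = _plant(mature, nls_seq, int(rng.integers(30, mat_len - 8)))
        if motif is not None and mat_len > 40:
            ins = _instantiate_motif(rng, _PLANTED_MOTIFS[motif], cfg.composition)
            mature = _plant(mature, ins, int(rng.integers(10, mat_len - len(ins) - 1)))
        seq = sp + mature
        if _passes_as_secreted(seq, cleavage, params):
            return seq, cleavage, (motif if motif is not None and mat_len > 40 else None)


def _build_background(rng, cfg, *, tm: bool, mito: bool, motif: str | None):
    """A planted-negative protein; rejection-sampled so no predictor fires."""
    params = cfg.filter_params
    length = _draw_length(rng, cfg)
    while True:
        if mito:
            seq = _mito_presequence(rng) + _residues(rng, length - 25, cfg.composition)
            if predict_mito_targeting(seq, params).compartment != "mitochondrial":
                continue
        elif tm:
            sp = _signal_peptide(rng)
            body = _residues(rng, max(60, length - len(sp)), cfg.composition)
            helix_pos = int(rng.integers(20, len(body) - 25))
            body = _plant(body, _tm_helix(rng), helix_pos)
            seq = sp + body
            spp = predict_signal_peptide(seq, params)
            if not (spp.has_sp and predict_tm_segments(seq, spp, params).tm_count > 0):
                continue
        else:
            seq = "M" + _residues(rng, length - 1, cfg.composition)
            if _looks_secreted(seq, params):
                continue
            if predict_mito_targeting(seq, params).compartment == "mitochondrial":
                continue
        if motif is not None:
            ins = _instantiate_motif(rng, _PLANTED_MOTIFS[motif], cfg.composition)
            pos = int(rng.integers(50, len(seq) - len(ins) - 1))
            cand = _plant(seq, ins, pos)
            if not mito and not tm and _looks_secreted(cand, params):
                continue
            seq = cand
        return seq


# ---------------------------------------------------------------------------
# study assembly
# ---------------------------------------------------------------------------

def _plan_features(rng, cfg, n: int) -> list[dict]:
    """Assign exact planted feature counts to n gene slots."""
    n_secreted = round(cfg.fraction_secreted * n)
    idx = rng.permutation(n)
    secreted = set(idx[:n_secreted].tolist())
    rest = [int(i) for i in idx[n_secreted:]]
    n_tm = round(cfg.tm_rate * len(rest))
    n_mito = round(cfg.mito_rate * len(rest))
    tm_set = set(rest[:n_tm])
    mito_set = set(rest[n_tm : n_tm + n_mito])

    sec_list = sorted(secreted)
    n_scr = round(cfg.scr_rate * len(sec_list))
    n_nls = round(cfg.nls_rate * len(sec_list))
    n_rcp = round(cfg.rcp_rate * len(sec_list))
    n_motif = round(cfg.motif_rate * len(sec_list))
    perm = [sec_list[i] for i in rng.permutation(len(sec_list))]
    scr_set = set(perm[:n_scr])
    # NLS / RCP / motif planted on non-SCR secreted proteins first to keep
    # feature classes cleanly separable; overlap is allowed when space runs out
    pool = perm[n_scr:] + perm[:n_scr]
    nls_set = set(pool[:n_nls])
    rcp_list = pool[n_nls : n_nls + n_rcp]
    kex2_cut = round(cfg.rcp_kex2_fraction * len(rcp_list))
    rcp_kex2 = set(rcp_list[:kex2_cut])
    rcp_plain = set(rcp_list[kex2_cut:])
    motif_pool = pool[n_nls + n_rcp : n_nls + n_rcp + n_motif]
    motif_ids = sorted(_PLANTED_MOTIFS)
    motif_map = {g: motif_ids[i % len(motif_ids)] for i, g in enumerate(motif_pool)}

    bg_list = sorted(set(rest) - tm_set - mito_set)
    n_bg_motif = round(cfg.motif_bg_rate * len(rest))
    bg_motif_pool = [bg_list[i] for i in rng.permutation(len(bg_list))[:n_bg_motif]]
    for i, g in enumerate(bg_motif_pool):
        motif_map[g] = motif_ids[i % len(motif_ids)]

    plans = []
    for i in range(n):
        plans.append(
            dict(
                secreted=i in secreted,
                scr=i in scr_set,
                nls=i in nls_set,
                rcp="kex2" if i in rcp_kex2 else ("plain" if i in rcp_plain else ""),
                tm=i in tm_set,
                mito=i in mito_set,
                motif=motif_map.get(i),
            )
        )
    return plans


def _build_protein(rng, cfg, plan: dict):
    if plan["secreted"]:
        seq, cleavage, motif = _build_secreted(
            rng, cfg, scr=plan["scr"], nls=plan["nls"], rcp=plan["rcp"], motif=plan["motif"]
        )
        plan = dict(plan, motif=motif)
    else:
        seq = _build_background(rng, cfg, tm=plan["tm"], mito=plan["mito"], motif=plan["motif"])
        cleavage = None
    return seq, cleavage, plan


def generate_proteomes(config: GeneratorConfig) -> SyntheticStudy:
    """Generate both species' catalogs, the cross-map and the ground truth."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # ---- species 1: two assembly catalogs of the same loci ----
    n = cfg.n_genes
    plans = _plan_features(rng, cfg, n)
    n_a_only = round(cfg.a_only_rate * n)
    n_b_only = round(cfg.b_only_rate * n)
    n_frag = round(cfg.fragment_rate * n)
    n_frag_a = n_frag // 2  # loci fragmented in catalog A (whole gene in B)
    n_frag_b = n_frag - n_frag_a
    order = rng.permutation(n)
    slots = iter(order.tolist())
    a_only = sorted(next(slots) for _ in range(n_a_only))
    b_only = sorted(next(slots) for _ in range(n_b_only))
    frag_a = sorted(next(slots) for _ in range(n_frag_a))
    frag_b = sorted(next(slots) for _ in range(n_frag_b))
    pairs = sorted(slots)
    n_unsup = round(cfg.unsupported_rate * len(pairs))
    unsupported = set(pairs[:n_unsup])  # A definition lacks RNA-seq support

    catalog_a: dict[str, ProteinRecord] = {}
    catalog_b: dict[str, ProteinRecord] = {}
    crossmap: list[CrossMapRow] = []
    feature_rows: list[dict] = []
    consensus: list[str] = []
    secreted_consensus: list[str] = []

    def record_features(pid: str, species: int, plan: dict, cleavage, extra=None, *, aa_length=0):
        row = dict(
            protein_id=pid, species=species, aa_length=aa_length,
            is_secreted=bool(plan["secreted"]), cleavage_pos=cleavage,
            is_scr=bool(plan["secreted"] and plan["scr"]),
            has_nls=bool(plan["secreted"] and plan["nls"]),
            rcp_class={"kex2": "cleavable_rcp", "plain": "non_cleavable_rcp"}.get(plan["rcp"], "not_rcp") if plan["secreted"] else "not_rcp",
            has_tm=bool(plan.get("tm")), is_mito=bool(plan.get("mito")),
            motif_id=plan.get("motif") or "",
            family_id="", duplicate_of="", fragment_of="",
        )
        row.update(extra or {})
        feature_rows.append(row)

    for i in range(n):
        seq, cleavage, plan = _build_protein(rng, cfg, plans[i])
        aid, bid = f"S1A{i:04d}", f"S1B{i:04d}"
        if i in set(a_only):
            catalog_a[aid] = ProteinRecord(aid, "species1", seq, "A")
            consensus.append(aid)
            record_features(aid, 1, plan, cleavage, aa_length=len(seq))
            kept = aid
        elif i in set(b_only):
            catalog_b[bid] = ProteinRecord(bid, "species1", seq, "B")
            consensus.append(bid)
            record_features(bid, 1, plan, cleavage, aa_length=len(seq))
            kept = bid
        elif i in set(frag_a):
            # whole gene in B; two fragments in A
            cut = len(seq) // 2
            catalog_b[bid] = ProteinRecord(bid, "species1", seq, "B")
            fa1, fa2 = f"{aid}f1", f"{aid}f2"
            catalog_a[fa1] = ProteinRecord(fa1, "species1", seq[:cut], "A", has_stop=False)
            catalog_a[fa2] = ProteinRecord(fa2, "species1", seq[cut:], "A", has_start=False)
            crossmap.append(CrossMapRow(fa1, bid, cut / len(seq), 1.0, "query_fragmented"))
            crossmap.append(CrossMapRow(fa2, bid, 1 - cut / len(seq), 1.0, "query_fragmented"))
            consensus.append(bid)
            record_features(bid, 1, plan, cleavage, aa_length=len(seq))
            frag_extra = {"is_secreted": False, "has_tm": False, "is_mito": False,
                          "motif_id": "", "fragment_of": bid}
            record_features(fa1, 1, dict(plan, secreted=False, tm=False, mito=False),
                            None, frag_extra, aa_length=cut)
            record_features(fa2, 1, dict(plan, secreted=False, tm=False, mito=False),
                            None, frag_extra, aa_length=len(seq) - cut)
            kept = bid
        elif i in set(frag_b):
            cut = len(seq) // 2
            catalog_a[aid] = ProteinRecord(aid, "species1", seq, "A")
            fb1, fb2 = f"{bid}f1", f"{bid}f2"
            catalog_b[fb1] = ProteinRecord(fb1, "species1", seq[:cut], "B", has_stop=False)
            catalog_b[fb2] = ProteinRecord(fb2, "species1", seq[cut:], "B", has_start=False)
            crossmap.append(CrossMapRow(aid, fb1, cut / len(seq), 1.0, "target_fragmented"))
            crossmap.append(CrossMapRow(aid, fb2, 1 - cut / len(seq), 1.0, "target_fragmented"))
            consensus.append(aid)
            record_features(aid, 1, plan, cleavage, aa_length=len(seq))
            frag_extra = {"is_secreted": False, "has_tm": False, "is_mito": False,
                          "motif_id": "", "fragment_of": aid}
            record_features(fb1, 1, dict(plan, secreted=False, tm=False, mito=False),
                            None, frag_extra, aa_length=cut)
            record_features(fb2, 1, dict(plan, secreted=False, tm=False, mito=False),
                            None, frag_extra, aa_length=len(seq) - cut)
            kept = aid
        else:
            supported = i not in unsupported
            catalog_a[aid] = ProteinRecord(aid, "species1", seq, "A", rnaseq_supported=supported)
            catalog_b[bid] = ProteinRecord(bid, "species1", seq, "B")
            crossmap.append(CrossMapRow(aid, bid, 1.0, 1.0, "one_to_one"))
            kept = aid if supported else bid
            consensus.append(kept)
            record_features(kept, 1, plan, cleavage, aa_length=len(seq))
        if plan["secreted"]:
            secreted_consensus.append(kept)

    # exact duplicates inside catalog A (removed by the merge dedup step)
    dup_candidates = [g for g in a_only]
    n_dup = round(cfg.duplicate_rate * n)
    for j, src_i in enumerate(rng.choice(dup_candidates, size=min(n_dup, len(dup_candidates)), replace=False)):
        src = f"S1A{int(src_i):04d}"
        did = f"{src}dup"
        catalog_a[did] = ProteinRecord(did, "species1", catalog_a[src].aa_sequence, "A")
        feature_rows.append(dict(
            protein_id=did, species=1, aa_length=len(catalog_a[src].aa_sequence),
            is_secreted=False, cleavage_pos=None,
            is_scr=False, has_nls=False, rcp_class="not_rcp", has_tm=False,
            is_mito=False, motif_id="", family_id="", duplicate_of=src, fragment_of="",
        ))

    # ---- species 2: single catalog with homolog families ----
    plans2 = _plan_features(rng, cfg, n)
    species2: dict[str, ProteinRecord] = {}
    consensus2: list[str] = []
    secreted2: list[str] = []
    for i in range(n):
        seq, cleavage, plan = _build_protein(rng, cfg, plans2[i])
        gid = f"S2G{i:04d}"
        species2[gid] = ProteinRecord(gid, "species2", seq, "A")
        consensus2.append(gid)
        record_features(gid, 2, plan, cleavage, aa_length=len(seq))
        if plan["secreted"]:
            secreted2.append(gid)

    # homolog families: mutate species-1 secreted matures to a target identity
    features = pd.DataFrame(feature_rows).set_index("protein_id")
    fam_sources = sorted(secreted_consensus)
    fam_targets = sorted(secreted2)
    n_fam = min(cfg.n_homolog_families, len(fam_sources), len(fam_targets))
    src_pick = rng.choice(len(fam_sources), size=n_fam, replace=False)
    tgt_pick = rng.choice(len(fam_targets), size=n_fam, replace=False)
    params = cfg.filter_params
    for k in range(n_fam):
        sid = fam_sources[int(src_pick[k])]
        tid = fam_targets[int(tgt_pick[k])]
        cat = catalog_a if sid in catalog_a else catalog_b
        src_seq = cat[sid].aa_sequence
        src_cleave = int(features.loc[sid, "cleavage_pos"])
        src_mature = src_seq[src_cleave:]
        while True:
            sp = _signal_peptide(rng)
            mature = _mutate_to_identity(rng, src_mature, cfg.homolog_identity, cfg.composition)
            seq = sp + mature
            if _passes_as_secreted(seq, len(sp), params):
                break
        species2[tid] = ProteinRecord(tid, "species2", seq, "A")
        fam = f"F{k:03d}"
        from .feature_annotation import classify_scr  # no import cycle the other way

        features.loc[sid, "family_id"] = fam
        features.loc[tid, ["family_id", "cleavage_pos", "aa_length", "is_scr",
                           "has_nls", "rcp_class", "motif_id"]] = [
            fam, len(sp), len(seq), classify_scr(mature).is_scr, False, "not_rcp", "",
        ]

    # ---- expression design ----
    de_sets: dict[int, dict[str, str]] = {}
    true_fc: dict[int, pd.DataFrame] = {}
    baseline: dict[int, pd.Series] = {}
    for species, genes, sec, conds in (
        (1, consensus, secreted_consensus, cfg.conditions),
        (2, consensus2, secreted2, cfg.species2_conditions),
    ):
        hosts = [c for c in conds if c.startswith("IRM_")]
        sec_sorted = sorted(sec)
        perm = [sec_sorted[i] for i in rng.permutation(len(sec_sorted))]
        cursor = 0
        assignment: dict[str, str] = {}
        for gid in perm[cursor : cursor + cfg.n_common_up]:
            assignment[gid] = "common_up"
        cursor += cfg.n_common_up
        for h in hosts:
            for gid in perm[cursor : cursor + cfg.n_host_specific_up]:
                assignment[gid] = f"host_specific:{h}"
            cursor += cfg.n_host_specific_up
        for gid in perm[cursor : cursor + cfg.n_erm_up]:
            assignment[gid] = "erm_up"
        cursor += cfg.n_erm_up
        for gid in perm[cursor : cursor + cfg.n_signal_up]:
            assignment[gid] = "signal_up"
        cursor += cfg.n_signal_up
        de_sets[species] = assignment

        lo, hi = cfg.baseline_pi_range
        pi = pd.Series(
            10 ** rng.uniform(np.log10(lo), np.log10(hi), size=len(genes)),
            index=sorted(genes),
        )
        dlo, dhi = cfg.de_baseline_pi_range
        for gid in assignment:
            pi.loc[gid] = 10 ** rng.uniform(np.log10(dlo), np.log10(dhi))
        baseline[species] = pi

        fc = pd.DataFrame(1.0, index=sorted(genes), columns=list(conds))
        for gid, set_name in assignment.items():
            if set_name == "common_up":
                fc.loc[gid, hosts] = cfg.de_fold_change
            elif set_name.startswith("host_specific:"):
                fc.loc[gid, set_name.split(":", 1)[1]] = cfg.de_fold_change
            elif set_name == "erm_up":
                fc.loc[gid, "ERM"] = cfg.de_fold_change
            elif set_name == "signal_up":
                fc.loc[gid, ["GR24", "exudates"]] = cfg.de_fold_change
        true_fc[species] = fc

    truth = SyntheticTruth(
        features=features,
        consensus_ids={1: sorted(consensus), 2: sorted(consensus2)},
        de_sets=de_sets,
        true_fc=true_fc,
        baseline_pi=baseline,
    )
    return SyntheticStudy(cfg, catalog_a, catalog_b, crossmap, species2, truth)


def generate_counts(
    config: GeneratorConfig, truth: SyntheticTruth, species: int = 1
) -> CountMatrix:
    """Draw the species' count matrix under the planted expression design.

    Per gene and condition the mean proportion is baseline × planted fold
    change; per replicate a proportion is drawn from a Beta with that mean
    and variance φ·mean² and the count from a Binomial over the library
    size (or from a matching negative binomial when
    ``config.noise_model == 'negative_binomial'``).
    """
    rng = np.random.default_rng([config.seed, 1000 + species])
    conds = config.conditions if species == 1 else config.species2_conditions
    genes = truth.consensus_ids[species]
    pi0 = truth.baseline_pi[species].loc[genes].to_numpy()
    fc = truth.true_fc[species].loc[genes, list(conds)].to_numpy()
    n_samples = len(conds) * config.replicates
    libsizes = rng.lognormal(
        np.log(config.library_size_mean), config.library_size_sigma, size=n_samples
    ).astype(np.int64)
    columns, cond_of = [], []
    for c in conds:
        for r in range(1, config.replicates + 1):
            columns.append(f"{c}_rep{r}")
            cond_of.append(c)
    counts = np.zeros((len(genes), n_samples), dtype=np.int64)
    for j, cond in enumerate(cond_of):
        ci = list(conds).index(cond)
        mu = np.clip(pi0 * fc[:, ci], 1e-12, 0.5)
        if config.phi > 0 and config.noise_model == "beta_binomial":
            var = config.phi * mu**2
            s = mu * (1 - mu) / var - 1
            a, b = mu * s, (1 - mu) * s
            p = rng.beta(a, b)
        elif config.phi > 0 and config.noise_model == "negative_binomial":
            shape = 1.0 / config.phi
            p = np.minimum(rng.gamma(shape, mu / shape), 0.9)
        else:
            p = mu
        counts[:, j] = rng.binomial(libsizes[j], p)
    samples = pd.DataFrame(
        {
            "condition": cond_of,
            "replicate": [int(c.rsplit("rep", 1)[1]) for c in columns],
            "library_size": libsizes,
        },
        index=pd.Index(columns, name="sample_id"),
    )
    aa_len = truth.features.loc[genes, "aa_length"].astype(int)
    lengths = pd.Series(3 * (aa_len + 1), index=genes, dtype=np.int64)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=columns),
        samples=samples,
        lengths=lengths,
    )


def generate_crossmap_fixture(
    catalog_a: Mapping[str, ProteinRecord],
    catalog_b: Mapping[str, ProteinRecord],
    truth: SyntheticTruth,
) -> list[CrossMapRow]:
    """Rebuild the cross-map rows from the planted fragment/pair truth."""
    rows: list[CrossMapRow] = []
    frags = truth.features[truth.features["fragment_of"] != ""]
    for fid, row in frags.iterrows():
        whole = row["fragment_of"]
        if fid in catalog_a and whole in catalog_b:
            cov = len(catalog_a[fid].aa_sequence) / len(catalog_b[whole].aa_sequence)
            rows.append(CrossMapRow(fid, whole, cov, 1.0, "query_fragmented"))
        elif fid in catalog_b and whole in catalog_a:
            cov = len(catalog_b[fid].aa_sequence) / len(catalog_a[whole].aa_sequence)
            rows.append(CrossMapRow(whole, fid, cov, 1.0, "target_fragmented"))
    paired = set(catalog_a) & {
        pid.replace("S1B", "S1A") for pid in catalog_b if pid.startswith("S1B")
    }
    for aid in sorted(paired):
        bid = aid.replace("S1A", "S1B")
        if bid in catalog_b and catalog_a[aid].aa_sequence == catalog_b[bid].aa_sequence:
            rows.append(CrossMapRow(aid, bid, 1.0, 1.0, "one_to_one"))
    return sorted(rows, key=lambda r: (r.query_id, r.target_id))


def default_design(config: GeneratorConfig, species: int = 1) -> ComparisonDesign:
    """The study's comparison design: every condition vs germinating spores."""
    conds = config.conditions if species == 1 else config.species2_conditions
    comparisons = [Comparison(c, c) for c in conds if c != "reference"]
    hosts = frozenset(c for c in conds if c.startswith("IRM_"))
    return ComparisonDesign(
        reference_condition="reference",
        comparisons=comparisons,
        host_labels=hosts,
        erm_labels=frozenset({"ERM"} & set(conds)),
        signal_labels=frozenset({"GR24", "exudates"} & set(conds)),
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write FASTA catalogs, cross-map, count matrices and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, cat in (
        ("species1_catalogA", study.catalog_a),
        ("species1_catalogB", study.catalog_b),
        ("species2_catalog", study.species2_catalog),
    ):
        with open(out / f"{name}.fasta", "w") as fh:
            for rec in cat.values():
                fh.write(f">{rec.id}\n{rec.aa_sequence}\n")
    pd.DataFrame(
        [
            {
                "query_id": r.query_id, "target_id": r.target_id,
                "coverage": r.coverage, "identity": r.identity,
                "fragment_flag": r.fragment_flag,
            }
            for r in study.crossmap
        ]
    ).to_csv(out / "crossmap.tsv", sep="\t", index=False)
    study.truth.features.to_csv(out / "truth_features.tsv", sep="\t")
    for sp in (1, 2):
        cm = generate_counts(study.config, study.truth, species=sp)
        cm.counts.to_csv(out / f"species{sp}_counts.tsv", sep="\t")
        cm.samples.to_csv(out / f"species{sp}_samples.tsv", sep="\t")
        cm.lengths.rename("length_nt").to_csv(out / f"species{sp}_lengths.tsv", sep="\t")
        study.truth.true_fc[sp].to_csv(out / f"species{sp}_true_fc.tsv", sep="\t")
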