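"""Annotate a secretome with effector-candidate features.

Scores every retained secreted protein for small-cysteine-rich (SCR)
status, nuclear localization signals, tandem repeats with or without a
conserved KEX2 [KR]R cleavage site, and occurrences of known effector
motifs, then tests motif enrichment against the non-secreted background.
"""

from collections import Counter

from amfsecretome import (
    GeneratorConfig,
    annotate_entry,
    apply_secretome_filter,
    generate_proteomes,
    motif_enrichment,
    resolve_consensus,
    scan_motif_catalog,
)

cfg = GeneratorConfig(seed=1)  # default study scale: 3000 genes/species
study = generate_proteomes(cfg)
merged = resolve_consensus(study.catalog_a, study.catalog_b, study.crossmap)
entries = [annotate_entry(e) for e in apply_secretome_filter(merged)]

n_scr = sum(e.features["scr"].is_scr for e in entries)
n_nls = sum(bool(e.features["nls_hits"]) for e in entries)
rcp = Counter(e.features["rcp_class"] for e in entries)
print(f"secretome size: {len(entries)}")
print(f"  SCR (<200 aa, ≥2 Cys, ≥3% Cys): {n_scr}")
print(f"  NLS-containing: {n_nls}")
print(f"  repeat proteins: {rcp['cleavable_rcp']} KEX2-cleavable, "
      f"{rcp['non_cleavable_rcp']} non-cleavable")

# motif enrichment: secretome vs non-secreted background
feats = study.truth.features
bg_ids = [i for i in merged.ids() if not feats.loc[i, "is_secreted"]]
cat = {r.id: r for r in merged.records}
fg: Counter = Counter()
bg: Counter = Counter()
for e in entries:
    fg.update({h.motif_id for h in e.features["motif_hits"]})
for i in bg_ids:
    bg.update({h.motif_id for h in scan_motif_catalog(cat[i].aa_sequence)})
rows = motif_enrichment(fg, len(entries), bg, len(bg_ids))
print("\nmotifs at q <= 0.05 (id, secretome count, background count, q):")
for r in sorted(rows, key=lambda r: r.q):
    if r.q <= 0.05:
        print(f"  {r.feature_id:10s} {r.k_fg:3d}/{r.n_fg}  {r.k_bg:3d}/{r.n_bg}  q={r.q:.2e}")
# Only the motifs planted at a higher rate in the secretome come out
# enriched; ubiquitous short patterns match both sets at equal rates.
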