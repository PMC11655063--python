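"""Clone sharing and repertoire similarity across organs.

Jaccard compares organs by clone identity only; cosine additionally weights
by clonal frequency.  The overlap degree of a clone is the number of organs
it occupies; binder matching relates antigen specificity to that degree.
"""

from organrep import (
    match_binders,
    organ_overlap_counts,
    pairwise_similarity,
    simulate_repertoire,
    study_config,
    vgene_usage_correlation,
)

rep = simulate_repertoire(study_config("3x", seed=42)).for_mouse("m1")

print("pairwise Jaccard (clone identity):")
print(pairwise_similarity(rep, "jaccard").values.round(3))
print("\npairwise cosine (identity + frequency):")
print(pairwise_similarity(rep, "cosine").values.round(3))

ov = organ_overlap_counts(rep)
print("\nclones by organ-overlap degree:", dict(sorted(ov.degree_histogram.items())))
print("clones in >= 3 organs:", ov.clones_in_at_least(3))

usage = vgene_usage_correlation(
    {organ: rep.clone_keys(organ) for organ in rep.organs}
)
print("\nV-gene usage Pearson r (heatmap leaf order):", usage.leaf_order)

# pretend the 30 most shared clones were recovered by an antigen-binding screen
binders = {c.cdrh3_aa for c in sorted(rep.clones, key=lambda c: -c.degree)[:30]}
res = match_binders(binders, rep)
print("binder/all ratio by overlap degree:", {d: round(r, 3) for d, r in res.ratio_by_degree.items()})
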