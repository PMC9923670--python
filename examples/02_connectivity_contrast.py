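"""Group connectivity matrices and an edge-wise between-group contrast.

Each group's 28 x 28 Spearman matrix is Fisher-transformed and compared
edge by edge with the two-sample Z statistic; Benjamini-Hochberg FDR
controls the 378 tests of the contrast.
"""

from metaconn import compare_groups, default_cohort_config, generate_cohort, spearman_matrix

table = generate_cohort(default_cohort_config(seed=42, n_per_group=40))

pre = spearman_matrix(table, "pre_VEH")
post = spearman_matrix(table, "QA_VEH")
contrast = compare_groups(pre, post, alpha=0.01)

print(f"edges tested: {contrast.n_tested}, significant at q < 0.01: "
      f"{contrast.n_significant}")
print("strongest edge changes (pre_VEH minus QA_VEH, ranked by raw p):")
top = contrast.edges.nsmallest(5, "p")
for _, row in top.iterrows():
    print(f"  {row.region_a} -- {row.region_b}: rho {row.rho_1:+.2f} -> "
          f"{row.rho_2:+.2f}, Z = {row.Z:+.2f}, p = {row.p:.4f}, q = {row.q:.3f}")
# The configured lesion strengthens the right frontal--somatosensory and
# frontal--motor edges and flips two cross-block edges, so those should
# lead this ranking (negative Z: edge weaker in the pre-lesion group).
# At modest group sizes few edges survive q < 0.01 -- mirroring how sparse
# the FDR-significant set is in small-animal cohorts.
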