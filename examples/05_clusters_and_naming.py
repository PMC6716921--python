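"""Cluster organisation, marker labelling and the naming convention.

Emulates the published syntenic block — XKR6, the six-gene ovodefensin
cluster, MTMR9, the intercluster genes, CTSB, then the defensin cluster —
scans it, groups the calls into clusters and names loci by distance from
the anchoring marker (CTSB for defensins, MTMR9 for ovodefensins).  Also
reproduces the published 70.00% identity of the two mature cathelicidins.
"""
from ampminer import (build_clusters, data, global_align, label_clusters,
                      assign_names)
from ampminer.cluster_ortho import GeneLocus
from ampminer.synthetic_data import emulated_cluster_scaffold

scaffold, truth, markers = emulated_cluster_scaffold(seed=0)
loci = [GeneLocus(t.scaffold_id, t.orf_start, t.orf_end, t.strand,
                  t.peptide_id, t.gene_class)
        for t in truth if t.domain_index == 0]
clusters = label_clusters(build_clusters(loci), markers)
for c in clusters:
    print(f"{c.label or 'unlabeled':18s} {len(c.loci):2d} loci  "
          f"flanks: {c.left_marker} / {c.right_marker}")
names = assign_names(clusters, markers)
print("first defensin after CTSB  ->", names["VkBD1_VARKO"])
print("ovodefensin next to MTMR9  ->", names["VkOVOD1_VARKO"])

pep = {r["id"]: r["peptide"] for r in data.load_cathelicidin_peptide_table()}
result = global_align(pep["VK-CATH4.1"], pep["VK-CATH4.2"])
print(f"VK-CATH4.1 vs 4.2: {result.identities} identities, "
      f"{result.percent_identity:.2f}% identity")
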