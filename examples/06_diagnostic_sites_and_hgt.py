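"""Diagnostic alignment columns and the tree-incongruence HGT screen.

Diagnostic sites assign an ambiguous strain to a subspecies: columns where
the query shares a conserved state with some groups while another group is
conserved for a different state.  The Robinson-Foulds screen flags a gene
whose phylogeny disagrees with the reference marker phylogeny — the
signature of horizontal transfer.
"""

import dendropy

from reducto.phylo import MultipleAlignment, diagnostic_sites, rf_incongruence

rows = {
    "lac1": "ACGTACGTTG", "lac2": "ACGTACGTTG",
    "bul1": "ACGTACTTTG", "bul2": "ACGTACTTTG",
    "del1": "TCGAACGTAG", "del2": "TCGAACGTAG",
    "query": "ACGTACGTTG",
}
groups = {"lac1": "lactis", "lac2": "lactis", "bul1": "bulgaricus",
          "bul2": "bulgaricus", "del1": "delbrueckii", "del2": "delbrueckii",
          "query": "query"}
aln = MultipleAlignment(sorted(rows), [rows[k] for k in sorted(rows)])

sites = diagnostic_sites(aln, groups, {"lactis", "bulgaricus"}, "delbrueckii",
                         query="query")
print(f"query shares {len(sites)} conserved sites with lactis+bulgaricus "
      f"against delbrueckii: columns {sites}")
sites2 = diagnostic_sites(aln, groups, {"lactis", "delbrueckii"}, "bulgaricus",
                          query="query")
print(f"and {len(sites2)} with lactis+delbrueckii against bulgaricus: "
      f"columns {sites2}")

species_tree = dendropy.Tree.get(
    data="((lac1,lac2),(bul1,bul2),(del1,del2));", schema="newick")
gene_tree = dendropy.Tree.get(
    data="((lac1,del1),(bul1,bul2),(lac2,del2));", schema="newick")
rf, shared, incongruent = rf_incongruence(species_tree, gene_tree)
print(f"gene tree vs species tree: RF={rf} over {shared} shared leaves, "
      f"incongruent={incongruent}")
print("A supported non-zero RF between a gene tree and the 16S-style "
      "reference is the horizontal-transfer signal.")
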