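"""Generate the two-clade synthetic study set and look at its ground truth.

Ten strains descend from a shared ancestral pangenome; the two clades carry
clade-specific gene complements, per-strain pseudogenizations, an HGT island
in one clade and different IS-element loads.
"""

from collections import Counter

from reducto.simulate import emit_dataset, simulate_clades

dataset = simulate_clades(seed=1)
print(f"{len(dataset.strains)} strains, "
      f"{len(dataset.ancestor.genes)} ancestral genes")
for strain in dataset.strains[:3]:
    statuses = Counter(r.status for r in strain.truth)
    n_is = sum(f.ftype == "mobile_genetic_element" for f in strain.features)
    print(f"  {strain.strain_id}: {len(strain.seq):,} bp, "
          f"{dict(statuses)}, {n_is} IS elements")

out = emit_dataset(dataset, "scratch/example_dataset")
print(f"wrote FASTA/GFF3/protein files and truth.tsv to {out}")
print("Each truth row records a planted fate (intact/pseudogene/absent/hgt), "
      "so every downstream stage can be scored exactly.")
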