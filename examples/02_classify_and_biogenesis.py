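"""Classify circRNA structures and compare biogenesis features.

Retained circRNAs are typed as multi-exonic / single-exonic / intronic
against the gene models; host genes are compared with non-hosts for
exon and isoform counts, and intron-length classes are summarized —
the association between long flanking introns and circRNA production.
"""

import numpy as np

from circscape.annotate import classify_all
from circscape.biogenesis import host_feature_comparison, intron_length_classes, propensity_by_bin
from circscape.filtering import RetentionConfig, apply_retention, merge_unique
from circscape.synth import GeneratorConfig, generate_bundle

bundle = generate_bundle(GeneratorConfig(seed=1))
ann = bundle.annotation
ann.known_contigs |= set(bundle.genome.contigs)
circs = merge_unique(apply_retention(bundle.candidates, RetentionConfig(), ann), ann)
classes = classify_all(circs, ann)

counts = {}
for cls in classes.values():
    counts[cls.circ_type] = counts.get(cls.circ_type, 0) + 1
print("structural types:", counts)

lengths = [c.spliced_length for c in classes.values() if c.spliced_length]
print(f"median spliced length: {np.median(lengths):.0f} nt")

hosts = {g for c in circs for g in c.host_gene_ids}
cmp = host_feature_comparison(ann, hosts)
print(f"host genes average {cmp['exons']['host_mean']:.1f} exons vs "
      f"{cmp['exons']['nonhost_mean']:.1f} for non-hosts (p = {cmp['exons']['p_value']:.2g})")
print(f"host genes average {cmp['isoforms']['host_mean']:.1f} isoforms vs "
      f"{cmp['isoforms']['nonhost_mean']:.1f} (p = {cmp['isoforms']['p_value']:.2g})")

introns = intron_length_classes(circs, classes, ann)
for name, vals in introns.items():
    print(f"median {name.replace('_', ' ')} intron: {np.median(vals):.0f} bp")
print("-> circRNA-flanking introns are longer than the genome-wide background")

rows = propensity_by_bin(ann, hosts, "exons", bin_edges=[1, 4, 7, 10, 13])
print("fraction of genes producing circRNAs by exon count:")
for r in rows:
    frac = f"{r['fraction']:.2f}" if r["fraction"] is not None else "undefined"
    print(f"  {r['bin_left']}-{r['bin_right'] - 1} exons: {frac} ({r['n_hosts']}/{r['n_genes']})")
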