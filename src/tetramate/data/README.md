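# Bundled data

Small plain-text transcriptions of the published strain tables and
crossing results for the European *Serpula lacrymans* population that
this package analyses.

- `european_strain_genotypes.tsv` — 26 dikaryotic environmental strains
  with their locality and the allele content observed at the two
  MAT-linked marker loci. Blank cells are explicit missing data (no
  sequence obtained at that locus), distinct from a locus where a
  single allele was observed.
- `functional_vs_marker_genotypes.tsv` — 10 monokaryons whose
  functional mating factors are known from earlier crossing
  experiments, paired with the marker-proxy genotypes obtained for the
  same strains.
- `spore_family_monokaryons.tsv` — the 16 sib monokaryons (4 per
  genotype class) from the spore family of the dikaryon Lmsa110092 that
  were crossed pairwise in vitro.
- `spore_family_crossings.csv` — the observed upper-triangle crossing
  matrix over those 16 monokaryons. `+` = clamp connections formed
  (compatible), `-` = no dikaryon formed, `?` = the single cross whose
  mycelia never met (unresolved); the diagonal and lower triangle are
  left blank as in the original scoring sheet.

Ambiguous cells are preserved as-is and never normalized: the `?` cell
(R2 x R22) stays unresolved, and blank loci stay blank.
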