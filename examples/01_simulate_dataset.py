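"""Generate a synthetic two-population amplicon dataset with known truth.

Builds the gain design (diploid reference + trisomic population, 7 of 22
chromosomes altered), writes the six standard files, and prints what was made.
"""

from pathlib import Path

from tapcnv import simulate as sim

ds = sim.build_study2(direction="gain", seed=42)
out = Path("scratch/example_dataset")
sim.write_dataset(ds, out)

print(f"wrote {out}/: counts.tsv, baf.tsv, panel.tsv, variants.tsv, reference.json, truth.tsv")
print(f"cells: {ds.counts.n_cells} ({ds.truth.population.value_counts().to_dict()})")
print(f"amplicons: {ds.counts.n_amplicons} across {len(ds.panel.chromosomes)} chromosomes")
print(f"variants: {ds.baf.n_variants} ({ds.config.variants_per_amplicon} per amplicon)")
print(f"altered chromosomes in 'alt': {ds.truth.altered_chromosomes['alt']}")
# Each 'alt' cell carries copy number 3 on those chromosomes and 2 elsewhere;
# the reference population is fully diploid and anchors normalization.
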