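"""Generate a synthetic longitudinal microbiome study.

Five treatment arms of 10 mice each, sampled on Days 0/14/28: an ASV
count table with 8 planted co-abundance guilds, a random phylogeny, and
host phenotypes coupled to food intake and guild abundances.
"""

from guildflow import SimConfig, generate_dataset

cfg = SimConfig(rng_seed=42)
table, samples, tree, truth = generate_dataset(cfg, out_dir="example_data")

print(f"count table: {table.n_samples} samples x {table.n_features} ASVs")
print(f"library sizes: {table.sample_totals().min()}-{table.sample_totals().max()} reads")
print(f"planted guilds: {len(set(truth.guild_of.values()))}")
print(f"tree leaves: {len(tree.leaf_names)}")
print("files written to example_data/: counts.tsv metadata.tsv tree.nwk truth.yaml")
# Each sample row is a multinomial draw whose latent log-abundances share a
# per-guild factor, so ASVs in a guild rise and fall together across samples.
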