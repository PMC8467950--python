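"""Random-Forest regression of fasting glucose on guilds + food + water.

Ranks predictors by permutation importance, eliminates them one at a
time, scores each model size by cross-validated MSE, and evaluates the
best model by leave-one-out prediction.
"""

import numpy as np

from guildflow import SimConfig, generate_dataset, rf_report
from guildflow.core_io import AbundanceTable, samples_to_frame
from guildflow.preprocess import ast_transform

cfg = SimConfig(rng_seed=42)
table, samples, tree, truth = generate_dataset(cfg)
meta = samples_to_frame(samples)

rel = table.counts / table.counts.sum(axis=1, keepdims=True)
guild_rel = np.zeros((table.n_samples, cfg.n_guilds))
for j, asv in enumerate(table.feature_ids):
    guild_rel[:, truth.guild_of[asv]] += rel[:, j]
ast = ast_transform(
    AbundanceTable(list(table.sample_ids), [f"Guild_{i+1}" for i in range(cfg.n_guilds)], guild_rel, scale="relative")
)

day28 = list(meta.index[meta["day"] == 28])
X = ast.select_samples(day28).to_frame()
X["food"] = meta.loc[day28, "food"]
X["water"] = meta.loc[day28, "water"]
y = meta.loc[day28, "glucose"].to_numpy(float)

report = rf_report(X, y, cv=5, seed=0, n_trees=500)
print("permutation importance (top 5):")
print(report.importances.head(5).round(1).to_string())
print(f"\nbest model: {len(report.selected)} predictors -> {report.selected}")
print(f"LOO cross-validation: Pearson r = {report.pearson_r:.3f} (p = {report.pearson_p:.2g})")
# Food intake should top the ranking: the generator plants it as the
# dominant driver of glucose, with two guilds contributing smaller effects.
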