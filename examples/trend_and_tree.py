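"""Trend curves and a partition tree over a small sweep.

Runs 5,000 parameter sets under mixed inheritance for the four compared
strategies, then (a) prints the smoothed trend of the encoded
first-to-break measure across the new insecticide's effectiveness, and
(b) fits the permutation-test partition tree to the winner labels to
show which parameters carve up the strategy landscape.
"""

import pandas as pd

from itnsim import PartitionTree, binned_trend, classify_strategies_table, sample_parameters
from itnsim.experiment import run_sweep_cells
from itnsim.strategies import COMPARED_STRATEGIES

params = sample_parameters(5_000, seed=11)
cells = {s: res for _, s, res in run_sweep_cells(
    params, strategies=COMPARED_STRATEGIES, modes=("MN",))}

trend = binned_trend(params.m1, cells["mixtures"].encode("first"))
picks = trend.iloc[10::20][["x", "n", "smoothed_mean"]]
print("mixtures, encoded first-to-break vs effectiveness of insecticide 1")
print("(values near 500 mix measured times with the 1000/1500/2000 codes):")
print(picks.round(2).to_string(index=False))

encoded = pd.DataFrame({s: cells[s].encode("first") for s in COMPARED_STRATEGIES})
labels = classify_strategies_table(encoded)
tree = PartitionTree(max_depth=2, random_state=0).fit(params.to_frame(), labels.to_numpy())
print("\npartition tree over the winner labels:")
print(tree.render())
print("each split names the parameter, its cutpoint and the permutation p-value;")
print("leaves give the proportion of each winner label in that parameter region.")
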