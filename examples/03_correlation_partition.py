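"""Partitioning genes by binding-expression correlation.

Runs the full chain on one synthetic study: differential binding across
developmental ages, restriction to significant promoter peaks of
protein-coding genes, Pearson correlation of promoter binding with the
expression trajectory, and classification at r > 0.8 / r < -0.8.
"""

from markdyn.pipeline import correlate_study
from markdyn.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=3))
partition, n_db_promoters = correlate_study(study, fdr=0.01)

counts = partition.genes.corr_class.value_counts()
print(f"{n_db_promoters} differentially bound promoter peaks entered the analysis")
print(f"genes with binding-expression r > 0.8:  {counts.get('positive', 0)}")
print(f"genes with binding-expression r < -0.8: {counts.get('negative', 0)}")
print(f"neutral genes:                          {counts.get('neutral', 0)}")

truth = study.truth.gene_table.set_index("gene_id").corr_class
called = partition.genes.set_index("gene_id").corr_class
tp = sum(called.get(g) == "positive" for g in truth.index[truth == "positive"])
print(f"planted positive genes recovered: {tp}/{(truth == 'positive').sum()}")
# Positive genes were planted with expression log-linear in their promoter
# binding ramp; negatives with the opposite slope; null genes have flat
# binding and are removed by the differential-binding filter before
# correlation, which is what keeps the partition precise at 4 timepoints.
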