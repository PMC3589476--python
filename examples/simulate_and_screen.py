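"""Simulate a plasma-miRNA array study and run the full screening pipeline.

Generates a synthetic 1145-probe, 70-sample experiment (20 controls, 20
pre-resection cases, 20 post-resection cases, 10 other cancers) with blood-
cell contamination, hemolysis spikes, low-abundance censoring, and planted
marker classes; then runs background subtraction, quantile normalization,
the two probe filters, the DE screen, and the selection cascade, and checks
the final candidates against the planted truth.
"""

from mirscreen.pipeline import PipelineConfig, run_pipeline
from mirscreen.simulate import SimConfig

config = PipelineConfig(out_dir="scratch/example_run", seed=42, sim=SimConfig())
result = run_pipeline(config)

stages = result.manifest["stages"]
print(f"simulated probes:            {stages['simulate']['n_probes']}")
print(f"after blood-cell filter:     {stages['blood_cell_filter']['kept']}")
print(f"after low-abundance filter:  {stages['low_abundance_filter']['kept']}")
print(f"pass DE thresholds:          {stages['cascade']['n_de']}")
print(f"normalize post-resection:    {stages['cascade']['n_normalizing']}")
print(f"final candidates:            {stages['cascade']['n_final']}")

truth = result.truth.set_index("probe_id")
classes = truth.loc[result.cascade.final_candidates, "class"].value_counts()
print("\ntruth classes of the final candidates:")
print(classes.to_string())
print("\nA well-behaved cascade recovers mostly 'bc_specific_regressing'")
print("probes: the planted markers that regress after resection and are")
print("absent from other cancers.")
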