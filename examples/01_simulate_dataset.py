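"""Simulate a study-like dataset with known ground truth.

Generates RNA counts for four populations x two sexes, RNA/DNA genotype
tables and a truth table, then prints the per-compartment gene counts and
the configured Y-degeneration mix.  The compensation factor c is the male
single-X output in units of one autosomal gene copy (c = 2 would be full
compensation); the female factor h scales the two-X female output.
"""

from dosagecomp import SimulationConfig, simulate_dataset, write_fixture

config = SimulationConfig(
    n_autosomal_genes=600,
    n_par_genes=60,
    n_stratum_i_genes=120,
    n_stratum_ii_genes=120,
    seed=42,
)
dataset = simulate_dataset(config)

print("genes per compartment:")
print(dataset.truth["compartment"].value_counts().to_string())
print("\nY-status mix on the sex chromosome:")
sex = dataset.truth[dataset.truth["compartment"] != "autosome"]
print(sex["y_status"].value_counts().to_string())
print(f"\nstratum II compensation c = {config.stratum_ii.compensation}"
      f" -> expected male X-linked : autosome ratio "
      f"{config.stratum_ii.compensation / 2:.2f}")

paths = write_fixture(dataset, "scratch/example_fixture")
print("\nfixture files written:")
for name, path in paths.items():
    print(f"  {name}: {path}")
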