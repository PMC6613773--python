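"""End-to-end run of the gene-based association pipeline on synthetic data.

A single YAML config drives everything: a two-cohort study is simulated
(a discovery cohort reduced to summary statistics, and a target cohort
with individual-level imputed genotypes), then the pipeline hard-calls
the dosages, applies the four variant QC filters, harmonizes effect
alleles, assigns SNPs to extended gene windows, computes the LD-adjusted
per-gene scores and runs the logistic gene scan.

Gene 3 is simulated as causal (three liability SNPs, per-allele effect
0.5), so the scan should put it far below every null gene.
"""

import tempfile
from pathlib import Path

import yaml

from polaris.cli_pipeline import run_pipeline, validate_config
from polaris.io_formats import read_results

workdir = Path(tempfile.mkdtemp(prefix="polaris_demo_"))
config = {
    "seed": 42,
    "output_dir": str(workdir / "out"),
    "simulate": {
        "n_target": 1500,          # target cohort (genotypes + phenotype)
        "n_discovery": 3000,       # discovery cohort (summary stats only)
        "blocks": [{"n_snps": 8, "rho": 0.6}] * 6,   # 6 LD blocks = 6 genes
        "causal": [{"gene_index": 2, "n_causal": 3, "effect_size": 0.5}],
        "dosage_noise": 0.1,       # imputation uncertainty (INFO < 1)
    },
}
config_path = workdir / "config.yaml"
config_path.write_text(yaml.safe_dump(config))

out = run_pipeline(validate_config(config_path))
results = read_results(out / "results.tsv")

print("Gene scan results (sorted by p-value):\n")
cols = ["gene_id", "chrom", "n_snps", "beta", "se", "p", "significant"]
print(results.sort_values("p")[cols].to_string(index=False,
                                               float_format=lambda v: f"{v:.3g}"))
print("\nThe causal gene is GENE0003; every other gene is null.")
print(f"All reports written under {out}")
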