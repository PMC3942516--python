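"""Quality control on a noisy cohort: filters, LD pruning, file round-trip.

Simulates a cohort with missingness, genotype errors and planted Mendelian
violations, writes it to PED/MAP text files, reloads, and runs the QC
cascade (missingness -> HWE -> MAF -> Mendelian cap) followed by LD pruning
of the linkage panel.
"""

import tempfile
from pathlib import Path

from famlink import (
    ChromosomeSpec,
    SimulationConfig,
    load_ped_map,
    simulate_cohort,
    snp_qc_filter,
    validate_pedigrees,
    write_cohort,
)
from famlink.qc import ld_prune

cfg = SimulationConfig(
    n_families=200,
    chromosomes=[ChromosomeSpec("1", 20, 5.0)],
    baseline_penetrance=0.3,
    target_mo_fraction=None,
    missingness=0.02,
    genotype_error_rate=0.002,
    n_mendel_errors=30,
    seed=4,
)
cohort = simulate_cohort(cfg)

with tempfile.TemporaryDirectory() as tmp:
    prefix = str(Path(tmp) / "cohort")
    write_cohort(cohort, prefix)
    dataset = load_ped_map(prefix + ".ped", prefix + ".map")
print(f"loaded {dataset.n_individuals} individuals x {dataset.n_markers} markers")

report = validate_pedigrees(dataset)
print(f"informative families: {report['informative'].sum()} / {len(report)}")

filtered, qc_report = snp_qc_filter(dataset)
for key, count in qc_report.counts().items():
    print(f"  {key}: {count}")

kept = ld_prune(filtered, r2_threshold=0.1)
print(f"LD pruning at r2 <= 0.1: {len(kept)} of {filtered.n_markers} markers retained")
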