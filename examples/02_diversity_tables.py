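"""Marker QC and diversity statistics: MAF, He, gene diversity, PIC,
transition/transversion accounting, per-genome marker density.

Run examples/01_simulate_panel.py first.
"""

from eigensel import grouped_summary, marker_stats, qc_filter, read_vcf, substitution_summary

matrix = read_vcf("scratch/example_panel/panel.vcf", "scratch/example_panel/panel.meta.tsv")
matrix, report = qc_filter(matrix)  # missing<=50%, mapped, MAF>0.05, het<0.2
print(f"QC: retained {report.retained}/{report.n_input} "
      f"(removed: {report.removed_missing} missing, {report.removed_unmapped} unmapped, "
      f"{report.removed_maf} MAF, {report.removed_het} het)")

stats = marker_stats(matrix)
print(f"\nmean MAF {stats.maf.mean():.3f}, mean GD {stats.gd.mean():.3f}, "
      f"mean PIC {stats.pic.mean():.3f}  (PIC is capped at 0.375 for biallelic SNPs)")

ts = substitution_summary(matrix.variants)
print(f"Ts/Tv ratio {ts.ts_tv_ratio:.2f} "
      f"({100 * ts.transition_fraction:.1f}% transitions, wheat GBS panels sit near 2.7)")

genome = grouped_summary(matrix, by="genome")
print("\nper-genome marker table (density = markers per Mb):")
print(genome[["group", "n_markers", "pct_snps", "length_mb", "density", "mean_gd"]]
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))
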