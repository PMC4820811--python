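"""Sequencing QC arithmetic on the bundled published run summary.

Derives mapping/duplication percentages, sequenced megabases and approximate
transcriptome coverage from raw per-sample read counts of a 24-library
HiSeq run (two lanes, 3 conditions x 4 replicates each).
"""

from omicscreen.rnaseq import load_qc_table1, load_qc_table1_lane_totals, qc_summary

per_sample, _ = qc_summary(load_qc_table1(), read_length_bp=100, transcriptome_size_mb=65)
cols = ["sample_id", "pct_mapped_wo_dup", "pct_properly_paired", "sequenced_mb", "coverage_x"]
print(per_sample[cols].head(6).round(2).to_string(index=False))

_, totals = qc_summary(load_qc_table1_lane_totals())
combined = totals.set_index("sample_id").loc["combined-total"]
print(f"\ncombined run: {combined['total_reads']:.2f}M reads, "
      f"{combined['mapped_wo_dup']:.2f}M mapped without PCR duplicates "
      f"({combined['pct_mapped_wo_dup']:.2f}%)")
# coverage_x approximates how many times over the ~65 Mb human transcriptome
# each library was sequenced; ~25-35x per replicate is typical for bulk DE
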