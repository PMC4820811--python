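lane	sample_id	total_reads	mapped_reads	mapped_wo_dup	properly_paired
1	lane-1-total	348.13	294.95	286.61	229.53
2	lane-2-total	364.35	307.79	299.91	234.56
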