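consequence	impact
transcript_ablation	high
splice_acceptor_variant	high
splice_donor_variant	high
stop_gained	high
frameshift_variant	high
stop_lost	high
start_lost	high
transcript_amplification	high
feature_elongation	high
feature_truncation	high
missense_variant	moderate
inframe_insertion	moderate
inframe_deletion	moderate
protein_altering_variant	protein_altering
coding_sequence_variant	protein_altering
splice_region_variant	synonymous_or_lower
splice_donor_5th_base_variant	synonymous_or_lower
incomplete_terminal_codon_variant	synonymous_or_lower
start_retained_variant	synonymous_or_lower
stop_retained_variant	synonymous_or_lower
synonymous_variant	synonymous_or_lower
mature_miRNA_variant	synonymous_or_lower
5_prime_UTR_variant	synonymous_or_lower
3_prime_UTR_variant	synonymous_or_lower
non_coding_transcript_exon_variant	synonymous_or_lower
intron_variant	synonymous_or_lower
non_coding_transcript_variant	synonymous_or_lower
upstream_gene_variant	synonymous_or_lower
downstream_gene_variant	synonymous_or_lower
TFBS_ablation	synonymous_or_lower
TF_binding_site_variant	synonymous_or_lower
regulatory_region_variant	synonymous_or_lower
intergenic_variant	synonymous_or_lower
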