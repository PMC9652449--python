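# Demo: simulate a nuclease-edited amplicon sample and quantify it.
mode: nuclease
sample_id: demo_nuclease
amplicon_name: demo_site1
seed: 7
out_dir: demo_out
simulate: true
n_reads: 500
indel_freq: 0.30
seq_error_rate: 0.001
read_len: 150
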