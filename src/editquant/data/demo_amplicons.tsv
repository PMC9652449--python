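name	protospacer_start	strand	pam
demo_site1	40	+	AGG
demo_site2	40	+	AGG
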