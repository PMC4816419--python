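as_type	n_24h	n_48h	turnover
A3S	299	228	155
IR	229	213	105
A5S	141	108	80
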