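% 6-node worked-example graph: n=6 m=6
v1 v2
v1 v3
v1 v6
v2 v3
v2 v4
v4 v5
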