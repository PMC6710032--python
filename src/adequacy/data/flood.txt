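0.26
0.27
0.30
0.32
0.32
0.34
0.38
0.38
0.39
0.40
0.41
0.42
0.42
0.42
0.45
0.48
0.49
0.61
0.65
0.74
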