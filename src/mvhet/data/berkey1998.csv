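study,Y1,S11,Y2,S22,S12
1,0.47,0.0075,-0.32,0.0077,0.0030
2,0.20,0.0057,-0.60,0.0008,0.0009
3,0.40,0.0021,-0.12,0.0014,0.0007
4,0.26,0.0029,-0.31,0.0015,0.0009
5,0.56,0.0148,-0.39,0.0304,0.0072
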