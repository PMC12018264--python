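level,ssp,x,x0,x1
1.5,SSP1-2.6,2033,2031,2051
2,SSP2-4.5,2053,2051,2071
3,SSP3-7.0,2076,2071,2091
4,SSP5-8.5,2085,2071,2091
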