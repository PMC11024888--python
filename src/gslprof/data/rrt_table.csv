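rrt_class,rrt
SM,1.000
Hex,0.987
Lac,0.961
Gb3,0.940
GA1,0.928
Fuc-GA1,0.925
GA0,0.904
SHex,0.868
GM3,0.861
GM1,0.839
GM2,0.833
SLac,0.822
GD3,0.771
GD2,0.764
GD1,0.755
Fuc-GD1,0.753
GT1,0.724
GQ1,0.700
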