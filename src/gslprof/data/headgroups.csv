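name,hex,hexnac,fuc,neu5ac,modifications,rrt_class,core_sia,terminal_sia
SM,0,0,0,0,phosphocholine,SM,,
1P,0,0,0,0,phosphate,,,
Hex,1,0,0,0,,Hex,,
Lac,2,0,0,0,,Lac,,
Gb3,3,0,0,0,,Gb3,,
GA1,3,1,0,0,,GA1,,
Fuc-GA1,3,1,1,0,,Fuc-GA1,,
SHex,1,0,0,0,sulfate,SHex,,
SLac,2,0,0,0,sulfate,SLac,,
GM3,2,0,0,1,,GM3,1,0
GM2,2,1,0,1,,GM2,1,0
GM1,3,1,0,1,,GM1,1,0
GD3,2,0,0,2,,GD3,2,0
GD2,2,1,0,2,,GD2,2,0
GD1,3,1,0,2,,GD1,1,1
Fuc-GD1,3,1,1,2,,Fuc-GD1,1,1
GT1,3,1,0,3,,GT1,2,1
GQ1,3,1,0,4,,GQ1,2,2
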