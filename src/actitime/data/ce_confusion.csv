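,walking,sitting,running,lying_down,dynamic_standing
walking,1334,0,36,0,24
sitting,0,2552,0,55,10
running,60,0,478,0,0
lying_down,9,43,0,1057,15
dynamic_standing,96,9,0,0,734
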