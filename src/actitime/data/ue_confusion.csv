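,walking,sitting,running,lying_down,dynamic_standing
walking,7663,318,60,17,1471
sitting,515,80640,0,6495,2307
running,260,0,780,0,0
lying_down,22,3855,0,69878,89
dynamic_standing,2418,1454,0,266,19937
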