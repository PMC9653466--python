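# as_of: 2016-12-31
# breed: None
# farm: None
breed,TOTAL,EWES,RAMS,WETHERS,LAMBS,HOGGETS
AWASSI,6,3,2,1,0,0
MERINO,3,1,1,1,0,0
TOTAL,9,4,3,2,0,0
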