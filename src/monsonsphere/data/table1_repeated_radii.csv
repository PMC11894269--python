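model_id,r1_mm,r2_mm
m01,71.421,70.571
m02,77.826,77.585
m03,72.482,73.004
m04,75.685,75.898
m05,88.282,87.047
m06,76.537,75.919
m07,76.635,76.325
m08,100.793,100.773
m09,115.798,115.992
m10,71.838,70.615
m11,70.570,73.120
m12,66.758,66.981
m13,72.310,69.706
m14,84.234,84.346
m15,99.077,96.170
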