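sorbent,compound,kd,half_range
Char350,PCE,1.4,0.5
Char350,TCE,0.8,0.1
Char350,cis-DCE,0.4,0.1
Char350,VC,0.2,0.0
Char350,ethene,0.1,0.0
Char500,PCE,2.0,0.3
Char500,TCE,1.2,0.1
Char500,cis-DCE,0.6,0.1
Char500,VC,0.3,0.0
Char500,ethene,0.15,0.0
Char700,PCE,3.9,0.4
Char700,TCE,2.5,0.2
Char700,cis-DCE,1.5,0.1
Char700,VC,0.8,0.1
Char700,ethene,0.3,0.0
Char900,PCE,36.0,5.9
Char900,TCE,10.0,1.0
Char900,cis-DCE,5.2,0.0
Char900,VC,2.0,0.2
Char900,ethene,0.5,0.1
sand,PCE,0.0,0.0
sand,TCE,0.0,0.0
sand,cis-DCE,0.0,0.0
sand,VC,0.0,0.0
sand,ethene,0.0,0.0
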