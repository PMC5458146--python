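name,start_ma,end_ma
Tr1,251.9,241.8
Tr2,241.8,231.7
Tr3,231.7,221.6
Tr4,221.6,211.4
Tr5,211.4,201.3
J1,201.3,191.9
J2,191.9,182.5
J3,182.5,173.2
J4,173.2,163.8
J5,163.8,154.4
J6,154.4,145.0
K1,145.0,135.1
K2,135.1,125.3
K3,125.3,115.4
K4,115.4,105.5
K5,105.5,95.6
K6,95.6,85.8
K7,85.8,75.9
K8,75.9,66.0
Pg1,61.6,56.0
Pg2,56.0,47.8
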