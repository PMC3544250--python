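plant_id,M1,M2,M3,M4,M5,M6
P1,A,A,A,A,-,H
P2,A,A,A,A,A,A
P3,A,H,H,A,A,A
P4,A,A,B,A,A,A
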