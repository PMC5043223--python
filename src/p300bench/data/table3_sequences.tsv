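participant	hydrogel	tap_water	dry
P1	8	8	8
P2	15	13	13
P3	14	9	15
P4	13	11	15
P5	8	NA	8
P6	8	8	15
P7	8	14	15
P8	NA	10	NA
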