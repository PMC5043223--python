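participant	hydrogel_Sp1	hydrogel_MmP	hydrogel_WeB	hydrogel_Sp2	tap_water_Sp1	tap_water_MmP	tap_water_WeB	tap_water_Sp2	dry_Sp1	dry_MmP	dry_WeB	dry_Sp2
P1	100	100	70	100	100	100	91	90	80	90	60	50
P2	100	100	100	100	90	100	90	100	90	80	60	90
P3	90	80	100	90	100	100	100	100	50	80	40	60
P4	100	70	80	100	80	64	73	70	90	60	30	30
P5	100	100	100	100	NA	NA	NA	NA	100	100	100	80
P6	100	100	100	100	100	100	91	100	100	100	100	90
P7	100	100	100	100	100	100	100	90	100	100	60	90
P8	NA	NA	NA	NA	100	92	100	90	NA	NA	NA	NA
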