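# Per-tumor mutational burden, hand-transcribed from the published variant
# table (16 tumors; the printed column mean is 29.71 mut/Mbp).
sample	tmb_mut_per_mbp
CRC_1	40.71
CRC_2	42.66
CRC_3	50.36
CRC_4	19.71
CRC_5	23.72
CRC_6	31.03
CRC_7	13.38
CRC_8	15.52
CRC_9	41.38
CRC_10	47.47
CRC_11	19.74
CRC_12	32.17
CRC_13	25.85
CRC_14	30.98
CRC_15	17.66
CRC_16	22.98
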