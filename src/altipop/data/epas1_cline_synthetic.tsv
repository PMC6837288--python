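# SYNTHETIC stand-in for the deposited Epas1 sampling table (regenerate with scripts/make_synthetic_reference.py)
# seed=1008420 center=1399.5 width=800.0 pmin=0.04 pmax=0.86
locality	elevation_m	allele_H_count	total_alleles	transect
lincoln_ne	430	1	28	1
plains_low1	600	0	22	0
plains_mid1	760	1	24	1
plains_mid2	950	2	24	1
foothills_1	1150	6	24	1
foothills_2	1300	6	22	0
front_range_1	1450	13	24	1
front_range_2	1600	16	24	1
front_range_3	1850	18	22	0
montane_1	2100	17	24	1
montane_2	2400	21	22	0
montane_3	2700	20	24	1
subalpine_1	3000	19	22	0
subalpine_2	3300	21	24	1
alpine_1	3700	20	24	0
mt_evans_co	4350	21	24	1
great_basin_1	800	3	22	0
great_basin_2	1250	6	22	0
wasatch_1	2000	19	22	0
wasatch_2	2600	19	22	0
sierra_low	320	0	22	0
sierra_mid	1500	9	22	0
sierra_high	3200	19	22	0
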