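species	pipeline	gene	transcript	exon
Arabidopsis_thaliana	multi_donor	75.32	60.09	84.82
Bombus_terrestris	multi_donor	53.89	45.19	82.82
Caenorhabditis_elegans	multi_donor	53.51	42.28	80.99
Danio_rerio	multi_donor	40.16	30.07	77.53
Drosophila_melanogaster	multi_donor	71.07	55.05	82.74
Medicago_truncatula	multi_donor	42.44	40.90	73.57
Parasteatoda_tepidariorum	multi_donor	15.17	13.17	56.26
Populus_trichocarpa	multi_donor	60.26	46.39	77.75
Rhodnius_prolixus	multi_donor	11.75	11.16	53.64
Tetraodon_nigroviridis	multi_donor	9.52	7.70	58.57
Gallus_gallus	multi_donor	43.03	35.07	69.29
Mus_musculus	multi_donor	37.62	31.45	62.75
Solanum_lycopersicum	multi_donor	38.37	36.46	71.55
Xenopus_tropicalis	multi_donor	48.93	39.23	83.77
Arabidopsis_thaliana	single_donor	71.15	57.16	84.16
Bombus_terrestris	single_donor	49.57	41.65	81.80
Caenorhabditis_elegans	single_donor	47.16	38.31	78.40
Danio_rerio	single_donor	32.10	25.43	75.58
Drosophila_melanogaster	single_donor	68.09	52.74	81.50
Medicago_truncatula	single_donor	43.32	42.45	74.81
Parasteatoda_tepidariorum	single_donor	15.19	13.70	59.07
Populus_trichocarpa	single_donor	53.44	46.28	78.86
Rhodnius_prolixus	single_donor	11.29	11.05	53.53
Tetraodon_nigroviridis	single_donor	8.50	7.29	58.20
Gallus_gallus	single_donor	40.59	34.76	70.10
Mus_musculus	single_donor	30.05	27.23	61.72
Solanum_lycopersicum	single_donor	38.54	37.24	72.71
Xenopus_tropicalis	single_donor	39.83	32.87	81.34
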