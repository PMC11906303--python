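# Metagenome-assembled genomes of the two enrichments: bin size (contig-length
# proxy), raw mapped read counts, and the printed read and metaproteome
# percentages for cross-checking.
# units: bin_size_mbp [Mbp]; mapped_reads [reads]; printed percentages [%]
regime	bin_id	bin_size_mbp	mapped_reads	printed_reads_pct	spectra_pct
N2Oexc	AZO_exc	2.7	62591220	83.2	75.8
N2Oexc	Bin.2_exc	3.2	1470411	2.0	5.4
N2Oexc	Bin.24_exc	3.3	1160565	1.5	5.1
N2Oexc	Bin.15_exc	3.5	4181484	5.6	3.7
N2Oexc	Bin.3_exc	3.1	328268	0.4	0.8
N2Oexc	Bin.12_exc	3.1	245691	0.3	0.3
N2Oexc	Bin.18_exc	2.7	547907	0.7	0.3
N2Oexc	Bin.16_exc	2.5	213672	0.3	0.2
N2Oexc	Bin.17_exc	2.9	241612	0.3	0.1
N2Oexc	Bin.9_exc	2.5	131267	0.2	0.0
N2Oexc	unbinned	26.4	4099244	5.5	8.4
N2Olim	AZO_lim	2.7	43300280	67.1	50.8
N2Olim	THA_lim	4.2	1247092	1.9	13.5
N2Olim	Bin.14_lim	2.0	78531	0.1	2.1
N2Olim	Bin.21_lim	2.6	520671	0.8	1.8
N2Olim	Bin.6_lim	2.5	243575	0.4	0.7
N2Olim	Bin.24_lim	1.3	486035	0.8	0.5
N2Olim	Bin.20_lim	3.1	141837	0.2	0.4
N2Olim	Bin.26_lim	2.4	134723	0.2	0.2
N2Olim	Bin.11_lim	3.9	214463	0.3	0.1
N2Olim	Bin.2_lim	1.7	233247	0.4	0.1
N2Olim	Bin.8_lim	2.6	101235	0.2	0.1
N2Olim	Bin.10_lim	2.9	262567	0.4	0.1
N2Olim	Bin.1_lim	1.1	43318	0.1	0.1
N2Olim	Bin.27_lim	3.4	142977	0.2	0.0
N2Olim	Bin.23_lim	2.4	461252	0.7	0.0
N2Olim	Bin.22_lim	1.3	53843	0.1	0.0
N2Olim	Bin.18_lim	2.4	140114	0.2	0.0
N2Olim	unbinned	14.9	16727548	25.9	29.5
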