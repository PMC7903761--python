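species	reference_proteins	reference_sproteins	extensions_to_reference_sproteins	additional_prodigal_sproteins	additional_chemgenome_sproteins	additional_insilico_sproteins	total_clusters	total_sprotein_clusters
A. caccae	3440	295	129	106	2398	78654	90548	81582
B. longum	1728	85	55	175	1338	43506	59156	45159
B. producta	5682	577	305	306	3749	140819	165184	145756
B. thetaiotaomicron	4941	463	274	279	3814	128815	146729	133645
C. butyricum	4148	391	131	187	282	68564	75453	69555
C. ramosum	3025	281	131	110	218	52203	56936	52943
E. coli K-12	4411	551	295	128	3485	106268	123548	110727
L. plantarum	3067	384	176	92	1611	72764	80137	75027
Combined	30442	3027	1496	1383	16895	691593	797691	714394
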