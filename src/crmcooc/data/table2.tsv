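# Published CRM activity/conservation score matrix: 13 tested regions,
# activity label (+: drove reporter expression, -: did not), and eight
# conservation metrics. "nd" marks undefined cells: the DME4 row has no
# pairwise alignment, and DME3 is shorter than 500 bp so its 500-bp
# peak-window score is undefined.
region_id	activity	avid	avid_dialign	phastcons_mean	peak100	peak200	peak500	tfbs_presence	tfbs_mismatch
cooc164	+	0.6002	0.7710	0.5532	0.6651	0.6337	0.6431	0.8	0.21
cooc102	+	0.6345	0.8230	0.4246	0.4836	0.5038	0.5325	0.8	0.15
DME2	+	0.6694	0.7860	0.4472	0.5416	0.5296	0.5133	0.8	0.19
cooc310	+	0.6766	0.5250	0.6649	0.7616	0.7459	0.8099	0.8	0.26
cooc404	+	0.6874	0.7530	0.6466	0.6718	0.6740	0.6778	0.8	0.29
cooc110	+	0.6867	0.7150	0.5072	0.5808	0.5767	0.5930	0.8	0.34
DME31	-	0.5037	0.5010	0.4509	0.6249	0.4786	0.4628	0.6	0.38
DME30	-	0.5597	0.5840	0.5403	0.6183	0.5900	0.5292	0.4	0.35
DME7	-	0.5819	0.5350	0.5822	0.5609	0.5103	0.4809	0.6	0.20
DME3	-	0.6095	0.6920	0.5168	0.4784	0.4826	nd	0.8	0.22
DME25	-	0.7401	0.8830	0.4480	0.5255	0.4964	0.4640	1	0.14
cooc437	-	0.6430	0.7840	0.5899	0.5970	0.5971	0.6145	0.6	0.12
DME4	-	nd	nd	0.5025	0.6021	0.5307	0.5200	nd	nd
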