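protein_id	bladder	liver	colorectal	lung
BRCA1	11.5863	6.8236	10.8636	12.5188
CDK2	16.7366	14.069	14.4739	9.942
CEBPB	5.2303	4.433	5.4262	7.2717
CREBBP	12.0995	9.5856	11.5906	11.1892
CTNNB1	7.6796	9.5993	9.304	4.8015
CUL1	13.2669	11.2802	5.5283	8.5044
CUL3	13.0117	12.9519	16.3169	11.5249
EP300	12.1078	13.2218	8.3187	7.1278
ESR1	5.6189	10.3758	6.3873	8.6696
HDAC1	19.2879	19.5736	11.7823	19.9208
HDAC2	11.0938	9.7752	18.9463	7.7916
HDAC4	5.8659	5.8397	9.7845	6.2225
IRAK1	4.1157	6.646	7.0177	5.1777
ISG15	4.4856	6.0239	5.8124	4.943
KIAA0101	15.8188	16.7663	19.1403	20.2633
MDM2	4.5647	4.753	11.5648	6.2816
MYC	13.0423	10.7821	20.0595	9.4508
PCNA	13.3217	15.1438	9.6282	14.8108
PRKDC	4.0781	5.9369	8.5589	5.6736
PSMA3	5.8022	7.7978	8.0875	5.2831
RB1	6.8922	5.5531	5.9763	8.3205
SRC	8.8026	4.0767	9.1407	6.3707
TERF1	5.4642	4.9046	6.2595	8.0708
TP53	19.5883	18.7422	25.9329	15.1811
TRAF2	9.2003	4.7703	7.365	6.4281
UBC	158.5321	137.284	80.3851	120.121
XRCC6	5.2871	9.5585	6.0231	4.8671
YWHAZ	8.7995	12.6421	7.9038	6.5798
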