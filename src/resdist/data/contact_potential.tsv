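# Rank-one hydrophobic-attraction quasi-potential: U(a,b) = -kd(a)*kd(b)/25
# Rows/columns in alphabet order (20 standard residues, alphabetical).
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.1296	-0.1800	0.2520	0.2520	-0.2016	0.0288	0.2304	-0.3240	0.2808	-0.2736	-0.1368	0.2520	0.1152	0.2520	0.3240	0.0576	0.0504	-0.3024	0.0648	0.0936
C	-0.1800	-0.2500	0.3500	0.3500	-0.2800	0.0400	0.3200	-0.4500	0.3900	-0.3800	-0.1900	0.3500	0.1600	0.3500	0.4500	0.0800	0.0700	-0.4200	0.0900	0.1300
D	0.2520	0.3500	-0.4900	-0.4900	0.3920	-0.0560	-0.4480	0.6300	-0.5460	0.5320	0.2660	-0.4900	-0.2240	-0.4900	-0.6300	-0.1120	-0.0980	0.5880	-0.1260	-0.1820
E	0.2520	0.3500	-0.4900	-0.4900	0.3920	-0.0560	-0.4480	0.6300	-0.5460	0.5320	0.2660	-0.4900	-0.2240	-0.4900	-0.6300	-0.1120	-0.0980	0.5880	-0.1260	-0.1820
F	-0.2016	-0.2800	0.3920	0.3920	-0.3136	0.0448	0.3584	-0.5040	0.4368	-0.4256	-0.2128	0.3920	0.1792	0.3920	0.5040	0.0896	0.0784	-0.4704	0.1008	0.1456
G	0.0288	0.0400	-0.0560	-0.0560	0.0448	-0.0064	-0.0512	0.0720	-0.0624	0.0608	0.0304	-0.0560	-0.0256	-0.0560	-0.0720	-0.0128	-0.0112	0.0672	-0.0144	-0.0208
H	0.2304	0.3200	-0.4480	-0.4480	0.3584	-0.0512	-0.4096	0.5760	-0.4992	0.4864	0.2432	-0.4480	-0.2048	-0.4480	-0.5760	-0.1024	-0.0896	0.5376	-0.1152	-0.1664
I	-0.3240	-0.4500	0.6300	0.6300	-0.5040	0.0720	0.5760	-0.8100	0.7020	-0.6840	-0.3420	0.6300	0.2880	0.6300	0.8100	0.1440	0.1260	-0.7560	0.1620	0.2340
K	0.2808	0.3900	-0.5460	-0.5460	0.4368	-0.0624	-0.4992	0.7020	-0.6084	0.5928	0.2964	-0.5460	-0.2496	-0.5460	-0.7020	-0.1248	-0.1092	0.6552	-0.1404	-0.2028
L	-0.2736	-0.3800	0.5320	0.5320	-0.4256	0.0608	0.4864	-0.6840	0.5928	-0.5776	-0.2888	0.5320	0.2432	0.5320	0.6840	0.1216	0.1064	-0.6384	0.1368	0.1976
M	-0.1368	-0.1900	0.2660	0.2660	-0.2128	0.0304	0.2432	-0.3420	0.2964	-0.2888	-0.1444	0.2660	0.1216	0.2660	0.3420	0.0608	0.0532	-0.3192	0.0684	0.0988
N	0.2520	0.3500	-0.4900	-0.4900	0.3920	-0.0560	-0.4480	0.6300	-0.5460	0.5320	0.2660	-0.4900	-0.2240	-0.4900	-0.6300	-0.1120	-0.0980	0.5880	-0.1260	-0.1820
P	0.1152	0.1600	-0.2240	-0.2240	0.1792	-0.0256	-0.2048	0.2880	-0.2496	0.2432	0.1216	-0.2240	-0.1024	-0.2240	-0.2880	-0.0512	-0.0448	0.2688	-0.0576	-0.0832
Q	0.2520	0.3500	-0.4900	-0.4900	0.3920	-0.0560	-0.4480	0.6300	-0.5460	0.5320	0.2660	-0.4900	-0.2240	-0.4900	-0.6300	-0.1120	-0.0980	0.5880	-0.1260	-0.1820
R	0.3240	0.4500	-0.6300	-0.6300	0.5040	-0.0720	-0.5760	0.8100	-0.7020	0.6840	0.3420	-0.6300	-0.2880	-0.6300	-0.8100	-0.1440	-0.1260	0.7560	-0.1620	-0.2340
S	0.0576	0.0800	-0.1120	-0.1120	0.0896	-0.0128	-0.1024	0.1440	-0.1248	0.1216	0.0608	-0.1120	-0.0512	-0.1120	-0.1440	-0.0256	-0.0224	0.1344	-0.0288	-0.0416
T	0.0504	0.0700	-0.0980	-0.0980	0.0784	-0.0112	-0.0896	0.1260	-0.1092	0.1064	0.0532	-0.0980	-0.0448	-0.0980	-0.1260	-0.0224	-0.0196	0.1176	-0.0252	-0.0364
V	-0.3024	-0.4200	0.5880	0.5880	-0.4704	0.0672	0.5376	-0.7560	0.6552	-0.6384	-0.3192	0.5880	0.2688	0.5880	0.7560	0.1344	0.1176	-0.7056	0.1512	0.2184
W	0.0648	0.0900	-0.1260	-0.1260	0.1008	-0.0144	-0.1152	0.1620	-0.1404	0.1368	0.0684	-0.1260	-0.0576	-0.1260	-0.1620	-0.0288	-0.0252	0.1512	-0.0324	-0.0468
Y	0.0936	0.1300	-0.1820	-0.1820	0.1456	-0.0208	-0.1664	0.2340	-0.2028	0.1976	0.0988	-0.1820	-0.0832	-0.1820	-0.2340	-0.0416	-0.0364	0.2184	-0.0468	-0.0676
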