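# State-wise mean net irrigated area (million hectares, mha), 2000-2010 period means.
# Columns: ground-survey net irrigated area (DES), the 250 m MODIS-NDVI-derived
# product, and the IWMI 250 m product, one row per federal state.
state	des_mha	modis_mha	iwmi_mha
Andhra Pradesh	4.40	6.08	19.60
Arunachal Pradesh	0.05	0.12	0.11
Assam	0.15	1.17	1.65
Bihar	3.29	2.71	10.71
Chandigarh	0.001	0.001	0.002
Chhattisgarh	1.25	3.34	10.05
Dadra & Nagar Haveli	0.006	0.005	0.037
Delhi	0.02	0.02	0.07
Goa	0.03	0.05	0.14
Gujarat	3.79	4.42	12.06
Haryana	2.98	3.09	5.56
Himachal Pradesh	0.11	0.28	0.72
Jammu & Kashmir	0.31	0.36	2.12
Jharkhand	0.13	1.40	6.70
Karnataka	2.99	3.95	13.55
Kerala	0.39	0.58	0.59
Madhya Pradesh	6.19	5.60	27.00
Maharashtra	3.25	3.59	23.26
Manipur	0.05	0.06	0.12
Meghalaya	0.06	0.12	0.24
Mizoram	0.01	0.07	0.005
Nagaland	0.07	0.12	0.01
Orissa	1.66	3.37	10.65
Pondicherry	0.02	0.02	0.04
Punjab	4.06	4.38	6.44
Rajasthan	6.03	8.34	20.6
Sikkim	0.01	0.03	0.01
Tamil Nadu	2.75	3.27	10.34
Tripura	0.06	0.13	0.29
Uttaranchal	0.34	0.48	1.00
Uttar Pradesh	13.19	14.28	28.13
West Bengal	3.08	2.57	8.28
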