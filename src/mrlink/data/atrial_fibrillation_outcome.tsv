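rsid	chr_pos	ea	nea	eaf	beta	se	pval	n
rs3755967	4:72828262	T	C	0.28	0.0056	0.0074	0.45	1030836
rs12785878	11:70845097	T	G	0.70	0.0011	0.0075	0.89	1030836
rs10741657	11:14871454	G	A	0.58	-0.0117	0.0067	0.08	1030836
rs17216707	20:52165769	C	T	0.19	-0.0156	0.0087	0.07	1030836
rs10745742	12:94882660	T	C	0.38	-0.0074	0.0068	0.28	1030836
rs8018720	14:38625936	C	G	0.81	0.0058	0.0088	0.51	1030836
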