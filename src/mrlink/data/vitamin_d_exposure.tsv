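rsid	chr_pos	ea	nea	eaf	beta	se	pval	n
rs3755967	4:72828262	T	C	0.28	-0.089	0.0023	4.74e-343	79366
rs12785878	11:70845097	T	G	0.75	0.036	0.0022	3.80e-62	79366
rs10741657	11:14871454	A	G	0.40	0.031	0.0022	2.05e-46	79366
rs17216707	20:52165769	T	C	0.79	0.026	0.0027	8.14e-23	79366
rs10745742	12:94882660	T	C	0.39	0.019	0.0020	2.10e-20	79366
rs8018720	14:38625936	C	G	0.82	-0.019	0.0027	1.11e-11	79366
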