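# Heptad propensity matrix for windowed coiled-coil scanning (MTIDK-style
# residue propensities, reconstructed; zero entries floored at 0.01).
# Calibration constants are derived by simulation — see
# scripts/build_matrix_calibration.py and docs/methods.md.  The globular
# reference population is composition-matched, register-incoherent heptad
# sequence, so register coherence rather than composition drives the call.
name	mtidk-like-v1
ad_weight	2.5
[propensity]
aa	a	b	c	d	e	f	g
L	3.167	0.297	0.398	3.902	0.585	0.501	0.483
I	2.597	0.098	0.345	0.894	0.514	0.471	0.431
V	1.665	0.403	0.386	0.949	0.211	0.342	0.360
M	2.240	0.370	0.480	1.409	0.541	0.772	0.663
F	0.531	0.076	0.403	0.662	0.189	0.106	0.013
Y	1.417	0.090	0.122	1.659	0.190	0.130	0.155
G	0.045	0.275	0.578	0.216	0.211	0.426	0.156
A	1.297	1.551	1.084	2.612	0.377	1.248	0.877
K	1.375	2.639	1.763	0.191	1.815	1.961	2.795
R	0.659	1.163	1.210	0.031	1.358	1.937	1.798
H	0.347	0.275	0.679	0.395	0.294	0.579	0.213
E	0.262	3.496	3.108	0.998	5.685	2.494	3.048
D	0.030	2.352	2.268	0.237	0.663	1.620	1.448
Q	0.179	2.114	1.778	0.631	2.550	1.578	2.526
N	0.835	1.475	1.534	0.039	1.722	2.456	2.280
S	0.382	0.583	1.052	0.419	0.525	0.916	0.628
T	0.169	0.702	0.955	0.654	0.791	0.843	0.647
C	0.824	0.022	0.308	0.152	0.180	0.156	0.044
W	0.240	0.010	0.010	0.456	0.019	0.010	0.010
P	0.010	0.008	0.010	0.013	0.010	0.010	0.010
[calibration]
window	weighted	mean_cc	sd_cc	mean_glob	sd_glob	prior_ratio
14	0	3.0310	0.3325	1.9972	0.3325	30
14	1	3.0911	0.3612	1.9327	0.3612	30
21	0	3.0212	0.2721	1.8624	0.2721	30
21	1	3.0793	0.3038	1.7692	0.3038	30
28	0	3.0175	0.2370	1.7867	0.2370	30
28	1	3.0731	0.2648	1.6840	0.2648	30
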