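# X-ray atomic scattering factors, 4-Gaussian parameterization
# f(s) = sum_i a_i * exp(-b_i * s^2) + c,  s = sin(theta)/lambda in 1/A.
# Coefficients from International Tables for Crystallography Vol. C,
# Table 6.1.1.4 (neutral atoms). f(0) = sum(a_i) + c = Z within 0.1.
# element	a1	b1	a2	b2	a3	b3	a4	b4	c
H	0.489918	20.6593	0.262003	7.74039	0.196767	49.5519	0.049879	2.20159	0.001305
B	2.05450	23.2185	1.33260	1.02100	1.09790	60.3498	0.706800	0.140300	-0.193200
C	2.31000	20.8439	1.02000	10.2075	1.58860	0.568700	0.865000	51.6512	0.215600
N	12.2126	0.005700	3.13220	9.89330	2.01250	28.9975	1.16630	0.582600	-11.5290
O	3.04850	13.2771	2.28680	5.70110	1.54630	0.323900	0.867000	32.9089	0.250800
F	3.53920	10.2825	2.64120	4.29440	1.51700	0.261500	1.02430	26.1476	0.277600
Na	4.76260	3.28500	3.17360	8.84220	1.26740	0.313600	1.11280	129.424	0.676000
Mg	5.42040	2.82750	2.17350	79.2611	1.22690	0.380800	2.30730	7.19370	0.858400
Al	6.42020	3.03870	1.90020	0.742600	1.59360	31.5472	1.96460	85.0886	1.11510
Si	6.29150	2.43860	3.03530	32.3337	1.98910	0.678500	1.54100	81.6937	1.14070
P	6.43450	1.90670	4.17910	27.1570	1.78000	0.526000	1.49080	68.1645	1.11490
S	6.90530	1.46790	5.20340	22.2151	1.43790	0.253600	1.58630	56.1720	0.866900
Cl	11.4604	0.010400	7.19640	1.16620	6.25560	18.5194	1.64550	47.7784	-9.55740
K	8.21860	12.7949	7.43980	0.774800	1.05190	213.187	0.865900	41.6841	1.42280
Ca	8.62660	10.4421	7.38730	0.659900	1.58990	85.7484	1.02110	178.437	1.37510
Sc	9.18900	9.02130	7.36790	0.572900	1.64090	136.108	1.46800	51.3531	1.33290
Ti	9.75950	7.85080	7.35580	0.500000	1.69910	35.6338	1.90210	116.105	1.28070
V	10.2971	6.86570	7.35110	0.438500	2.07030	26.8938	2.05710	102.478	1.21990
Cr	10.6406	6.10380	7.35370	0.392000	3.32400	20.2626	1.49220	98.7399	1.18320
Mn	11.2819	5.34090	7.35730	0.343200	3.01930	17.8674	2.24410	83.7543	1.08960
Fe	11.7695	4.76110	7.35730	0.307200	3.52220	15.3535	2.30450	76.8805	1.03690
Co	12.2841	4.27910	7.34090	0.278400	4.00340	13.5359	2.34880	71.1692	1.01180
Ni	12.8376	3.87850	7.29200	0.256500	4.44380	12.1763	2.38000	66.3421	1.03410
Cu	13.3380	3.58280	7.16760	0.247000	5.61580	11.3966	1.67350	64.8126	1.19100
Zn	14.0743	3.26550	7.03180	0.233300	5.16520	10.3163	2.41000	58.7097	1.30410
Br	17.1789	2.17230	5.23580	16.5796	5.63770	0.260900	3.98510	41.4328	2.95570
I	20.1472	4.34700	18.9949	0.381400	7.51380	27.7660	2.27350	66.8776	4.07120
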