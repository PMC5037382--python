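#provenance: synthetic default scale compiled from typical random-coil protein chemical-shift statistics (ppm) for 1Ha, 1HN, 15N, 13Ca; proline HN is a placeholder value (proline has no amide proton); intended as a reasonable default only and fully user-overridable via --scale-file
residue	HA	HN	N15	CA13
A	4.32	8.24	123.8	52.5
C	4.55	8.32	118.8	58.2
D	4.64	8.34	120.4	54.2
E	4.35	8.42	120.2	56.6
F	4.62	8.30	120.3	57.7
G	3.96	8.33	108.8	45.1
H	4.73	8.42	118.2	55.0
I	4.17	8.00	119.9	61.1
K	4.32	8.29	120.4	56.2
L	4.34	8.16	121.8	55.1
M	4.48	8.28	119.6	55.4
N	4.74	8.40	118.7	53.1
P	4.42	8.30	135.8	63.3
Q	4.34	8.32	119.8	55.7
R	4.34	8.23	120.5	56.0
S	4.47	8.31	115.7	58.3
T	4.35	8.15	113.6	61.8
V	4.12	8.03	119.2	62.2
W	4.66	8.25	121.3	57.5
Y	4.55	8.12	120.3	57.9
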