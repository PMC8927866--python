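# Minimal synthetic rotamer library for tests and desk-scale runs.
# Backbone-independent; chi angles are common rotameric values, probabilities
# are round numbers summing to 1 per amino acid. Native TSV dialect:
# aa	rotamer	prob	chi1	chi2	chi3	chi4
aa	rotamer	prob	chi1	chi2	chi3	chi4
A	1	1.00
G	1	1.00
S	1	0.48	-65
S	2	0.29	178
S	3	0.23	64
C	1	0.55	-65
C	2	0.26	180
C	3	0.19	62
T	1	0.50	-60
T	2	0.43	60
T	3	0.07	180
V	1	0.73	175
V	2	0.20	-60
V	3	0.07	63
L	1	0.62	-65	175
L	2	0.30	180	65
L	3	0.08	65	175
I	1	0.60	-65	170
I	2	0.15	-57	-60
I	3	0.15	180	165
I	4	0.10	62	170
M	1	0.40	-65	-65	-70
M	2	0.30	-65	180	75
M	3	0.30	180	180	75
P	1	0.55	30	-35
P	2	0.45	-25	35
F	1	0.50	-65	90
F	2	0.35	180	80
F	3	0.15	62	90
Y	1	0.50	-65	90
Y	2	0.35	180	80
Y	3	0.15	62	90
W	1	0.40	-65	95
W	2	0.35	180	90
W	3	0.25	62	-90
D	1	0.55	-70	-15
D	2	0.30	180	15
D	3	0.15	62	-10
N	1	0.50	-65	-20
N	2	0.30	180	30
N	3	0.20	62	-75
E	1	0.45	-65	180	-10
E	2	0.35	180	180	0
E	3	0.20	62	180	0
Q	1	0.45	-65	180	-10
Q	2	0.35	180	180	0
Q	3	0.20	62	180	0
K	1	0.40	-65	180	180	180
K	2	0.35	180	180	180	180
K	3	0.25	62	180	180	180
R	1	0.35	-65	180	180	85
R	2	0.35	180	180	180	180
R	3	0.30	62	180	180	85
H	1	0.45	-65	-70
H	2	0.35	180	60
H	3	0.20	62	80
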