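# Default disease-category taxonomy: pattern<TAB>kind<TAB>target<TAB>window<TAB>min_rx
# kind: icd|atc. target: a category name, or UNSPECIFIC / EXCLUDE / PSYCH.
# window/min_rx apply to named categories; use - for sentinel targets.
# cluster is carried on named-category rows (col 6); sentinel rows use -.
pattern	kind	target	window	min_rx	cluster
I10	icd	Hypertension	ever	0	Circulatory system
I11	icd	Hypertension	ever	0	Circulatory system
I12	icd	Hypertension	ever	0	Circulatory system
I13	icd	Hypertension	ever	0	Circulatory system
I15	icd	Hypertension	ever	0	Circulatory system
E78	icd	Dyslipidemia	last_2y	2	Circulatory system
C10AA	atc	Dyslipidemia	last_2y	2	Circulatory system
C10BA	atc	Dyslipidemia	last_2y	2	Circulatory system
C10AX	atc	Dyslipidemia	last_2y	2	Circulatory system
C10AB	atc	Dyslipidemia	last_2y	2	Circulatory system
C10AC	atc	Dyslipidemia	last_2y	2	Circulatory system
C10AD	atc	Dyslipidemia	last_2y	2	Circulatory system
I20	icd	Ischemic heart disease	ever	2	Circulatory system
I21	icd	Ischemic heart disease	ever	2	Circulatory system
I22	icd	Ischemic heart disease	ever	2	Circulatory system
I23	icd	Ischemic heart disease	ever	2	Circulatory system
I24	icd	Ischemic heart disease	ever	2	Circulatory system
I25	icd	Ischemic heart disease	ever	2	Circulatory system
C01DA	atc	Ischemic heart disease	ever	2	Circulatory system
I48	icd	Atrial fibrillation	ever	0	Circulatory system
I42	icd	Heart failure	ever	0	Circulatory system
I50	icd	Heart failure	ever	0	Circulatory system
I70	icd	Peripheral artery occlusive disease	ever	0	Circulatory system
I73	icd	Peripheral artery occlusive disease	ever	0	Circulatory system
I74	icd	Peripheral artery occlusive disease	ever	0	Circulatory system
G45	icd	Stroke	ever	0	Circulatory system
I60	icd	Stroke	ever	0	Circulatory system
I61	icd	Stroke	ever	0	Circulatory system
I63	icd	Stroke	ever	0	Circulatory system
I64	icd	Stroke	ever	0	Circulatory system
E10	icd	Diabetes mellitus	ever	2	Endocrine system
E11	icd	Diabetes mellitus	ever	2	Endocrine system
E12	icd	Diabetes mellitus	ever	2	Endocrine system
E13	icd	Diabetes mellitus	ever	2	Endocrine system
E14	icd	Diabetes mellitus	ever	2	Endocrine system
A10A	atc	Diabetes mellitus	ever	2	Endocrine system
A10B	atc	Diabetes mellitus	ever	2	Endocrine system
E03	icd	Thyroid disorder	last_2y	2	Endocrine system
E05	icd	Thyroid disorder	last_2y	2	Endocrine system
E06	icd	Thyroid disorder	last_2y	2	Endocrine system
H03	atc	Thyroid disorder	last_2y	2	Endocrine system
M10	icd	Gout	ever	0	Endocrine system
J40	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J41	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J42	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J43	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J44	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J45	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J47	icd	Chronic pulmonary disease	ever	0	Pulmonary system and allergy
J30	icd	Allergy	last_2y	0	Pulmonary system and allergy
L20	icd	Allergy	last_2y	0	Pulmonary system and allergy
L23	icd	Allergy	last_2y	0	Pulmonary system and allergy
K25	icd	Ulcer/chronic gastritis	ever	0	Gastrointestinal system
K26	icd	Ulcer/chronic gastritis	ever	0	Gastrointestinal system
K27	icd	Ulcer/chronic gastritis	ever	0	Gastrointestinal system
K28	icd	Ulcer/chronic gastritis	ever	0	Gastrointestinal system
K29	icd	Ulcer/chronic gastritis	ever	0	Gastrointestinal system
K70	icd	Chronic liver disease	ever	0	Gastrointestinal system
K71	icd	Chronic liver disease	ever	0	Gastrointestinal system
K72	icd	Chronic liver disease	ever	0	Gastrointestinal system
K73	icd	Chronic liver disease	ever	0	Gastrointestinal system
K74	icd	Chronic liver disease	ever	0	Gastrointestinal system
K76	icd	Chronic liver disease	ever	0	Gastrointestinal system
K50	icd	Inflammatory bowel disease	ever	0	Gastrointestinal system
K51	icd	Inflammatory bowel disease	ever	0	Gastrointestinal system
K57	icd	Diverticular disease of intestine	ever	0	Gastrointestinal system
N03	icd	Chronic kidney disease	ever	0	Urogenital system
N11	icd	Chronic kidney disease	ever	0	Urogenital system
N18	icd	Chronic kidney disease	ever	0	Urogenital system
N19	icd	Chronic kidney disease	ever	0	Urogenital system
N40	icd	Prostate disorders	ever	0	Urogenital system
N41	icd	Prostate disorders	ever	0	Urogenital system
N42	icd	Prostate disorders	ever	0	Urogenital system
M05	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M06	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M32	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M33	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M34	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M35	icd	Connective tissue disorders	ever	0	Musculoskeletal system
M80	icd	Osteoporosis	ever	2	Musculoskeletal system
M81	icd	Osteoporosis	ever	2	Musculoskeletal system
M82	icd	Osteoporosis	ever	2	Musculoskeletal system
M05B	atc	Osteoporosis	ever	2	Musculoskeletal system
H05AA	atc	Osteoporosis	ever	2	Musculoskeletal system
G03XC01	atc	Osteoporosis	ever	2	Musculoskeletal system
N02BA51	atc	Painful condition	last_1y	4	Musculoskeletal system
N02BE	atc	Painful condition	last_1y	4	Musculoskeletal system
M01A	atc	Painful condition	last_1y	4	Musculoskeletal system
M02A	atc	Painful condition	last_1y	4	Musculoskeletal system
D50	icd	Anemias	last_2y	0	Hematological system
D51	icd	Anemias	last_2y	0	Hematological system
D52	icd	Anemias	last_2y	0	Hematological system
D53	icd	Anemias	last_2y	0	Hematological system
D55	icd	Anemias	last_2y	0	Hematological system
D64	icd	Anemias	last_2y	0	Hematological system
C	icd	Cancer	last_5y	0	Cancers
H25	icd	Vision problem	ever	0	Neurological system
H26	icd	Vision problem	ever	0	Neurological system
H33	icd	Vision problem	ever	0	Neurological system
H40	icd	Vision problem	ever	0	Neurological system
H54	icd	Vision problem	ever	0	Neurological system
H90	icd	Hearing problem	ever	0	Neurological system
H91	icd	Hearing problem	ever	0	Neurological system
G43	icd	Migraine	last_2y	2	Neurological system
N02C	atc	Migraine	last_2y	2	Neurological system
G40	icd	Epilepsy	ever	0	Neurological system
G41	icd	Epilepsy	ever	0	Neurological system
G20	icd	Parkinson's disease	ever	0	Neurological system
G35	icd	Multiple sclerosis	ever	0	Neurological system
G50	icd	Neuropathies	last_2y	0	Neurological system
G56	icd	Neuropathies	last_2y	0	Neurological system
G57	icd	Neuropathies	last_2y	0	Neurological system
G60	icd	Neuropathies	last_2y	0	Neurological system
G62	icd	Neuropathies	last_2y	0	Neurological system
G63	icd	Neuropathies	last_2y	0	Neurological system
R	icd	UNSPECIFIC	-	-	-
A	icd	EXCLUDE	-	-	-
B	icd	EXCLUDE	-	-	-
O	icd	EXCLUDE	-	-	-
P	icd	EXCLUDE	-	-	-
S	icd	EXCLUDE	-	-	-
T	icd	EXCLUDE	-	-	-
V	icd	EXCLUDE	-	-	-
W	icd	EXCLUDE	-	-	-
X	icd	EXCLUDE	-	-	-
Y	icd	EXCLUDE	-	-	-
Z	icd	EXCLUDE	-	-	-
F	icd	PSYCH	-	-	-
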