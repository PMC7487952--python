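# Weight-related ICD-9-CM / ICD-10-CM diagnosis code dictionary, v1.
# Granular codes denote narrow BMI ranges; nonspecific codes denote obesity
# status without a usable BMI level. Edit or extend, then load with
# claimsbmi.codes.CodeDictionary.from_tsv().
code	system	granularity	level_label
V85.0	ICD9CM	granular	<=19.9
V85.1	ICD9CM	granular	20.0-24.9
V85.21	ICD9CM	granular	25.0-29.9
V85.22	ICD9CM	granular	25.0-29.9
V85.23	ICD9CM	granular	25.0-29.9
V85.24	ICD9CM	granular	25.0-29.9
V85.25	ICD9CM	granular	25.0-29.9
V85.30	ICD9CM	granular	30.0-34.9
V85.31	ICD9CM	granular	30.0-34.9
V85.32	ICD9CM	granular	30.0-34.9
V85.33	ICD9CM	granular	30.0-34.9
V85.34	ICD9CM	granular	30.0-34.9
V85.35	ICD9CM	granular	35.0-39.9
V85.36	ICD9CM	granular	35.0-39.9
V85.37	ICD9CM	granular	35.0-39.9
V85.38	ICD9CM	granular	35.0-39.9
V85.39	ICD9CM	granular	35.0-39.9
V85.41	ICD9CM	granular	40.0-44.9
V85.42	ICD9CM	granular	45.0-49.9
V85.43	ICD9CM	granular	50.0-59.9
V85.44	ICD9CM	granular	60.0-69.9
V85.45	ICD9CM	granular	>=70.0
Z68.1	ICD10CM	granular	<=19.9
Z68.20	ICD10CM	granular	20.0-24.9
Z68.21	ICD10CM	granular	20.0-24.9
Z68.22	ICD10CM	granular	20.0-24.9
Z68.23	ICD10CM	granular	20.0-24.9
Z68.24	ICD10CM	granular	20.0-24.9
Z68.25	ICD10CM	granular	25.0-29.9
Z68.26	ICD10CM	granular	25.0-29.9
Z68.27	ICD10CM	granular	25.0-29.9
Z68.28	ICD10CM	granular	25.0-29.9
Z68.29	ICD10CM	granular	25.0-29.9
Z68.30	ICD10CM	granular	30.0-34.9
Z68.31	ICD10CM	granular	30.0-34.9
Z68.32	ICD10CM	granular	30.0-34.9
Z68.33	ICD10CM	granular	30.0-34.9
Z68.34	ICD10CM	granular	30.0-34.9
Z68.35	ICD10CM	granular	35.0-39.9
Z68.36	ICD10CM	granular	35.0-39.9
Z68.37	ICD10CM	granular	35.0-39.9
Z68.38	ICD10CM	granular	35.0-39.9
Z68.39	ICD10CM	granular	35.0-39.9
Z68.41	ICD10CM	granular	40.0-44.9
Z68.42	ICD10CM	granular	45.0-49.9
Z68.43	ICD10CM	granular	50.0-59.9
Z68.44	ICD10CM	granular	60.0-69.9
Z68.45	ICD10CM	granular	>=70.0
278.00	ICD9CM	nonspecific
278.01	ICD9CM	nonspecific
278.03	ICD9CM	nonspecific
E66.9	ICD10CM	nonspecific
E66.01	ICD10CM	nonspecific
E66.2	ICD10CM	nonspecific
E66.09	ICD10CM	nonspecific
E66.1	ICD10CM	nonspecific
E66.8	ICD10CM	nonspecific
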