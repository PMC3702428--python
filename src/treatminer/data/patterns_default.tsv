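orientation	infix
DRUG_FIRST	in
DRUG_FIRST	in the treatment of
DRUG_FIRST	for
DRUG_FIRST	in patients with
DRUG_FIRST	for the treatment of
DRUG_FIRST	treatment of
DRUG_FIRST	therapy for
DRUG_FIRST	therapy in
DRUG_FIRST	for treatment of
DRUG_FIRST	against
DRUG_FIRST	in the management of
DRUG_FIRST	therapy of
DRUG_FIRST	treatment for
DRUG_FIRST	treatment in
DRUG_FIRST	in a patient with
DRUG_FIRST	in treatment of
DRUG_FIRST	in children with
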