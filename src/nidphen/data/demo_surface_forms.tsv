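# Literal surface realization for each demo-lexicon pattern, used by the
# synthetic corpus generator (a regex is not a generator; each pattern needs
# at least one concrete phrase that it matches).
# pattern_id <TAB> surface phrase
pos01	CSF positive for Streptococcus pneumoniae antigen
pos02	Findings are diagnostic of bacterial meningitis
pos03	MRI and clinical course support viral encephalitis
pos04	Course complicated by meningoencephalitis
pos05	Imaging demonstrates ventriculitis
pos06	CSF pleocytosis noted on repeat sampling
pos07	HSV-1 PCR positive from the fluid sample
pos08	Presentation is consistent with CNS infection
pos09	India ink stain confirms cryptococcal meningitis
pos10	Panel returned enteroviral meningitis
pos11	Serology confirms West Nile virus encephalitis
pos12	Fluid was positive for VZV by PCR
pos13	Patient is being treated for neurosyphilis
pos14	Infectious disease service documents confirmed CNS infection
pos15	Epstein-Barr virus detected in CSF by quantitative PCR
neg01	There are no signs of any infectious process on review
neg02	Serial LPs have been negative to date
neg03	Repeat studies show no evidence of meningitis
neg04	CSF cultures remain negative at five days
neg05	Working diagnosis is autoimmune encephalitis
neg06	CNS infection ruled out by the consulting team
neg07	There is no evidence of CNS infection at this time
neg08	PCR negative for HSV on two samples
neg09	Low suspicion for meningitis given the benign profile
neg10	Picture favors toxic metabolic encephalopathy without infection
drug01	Continue ceftriaxone two grams twice daily
drug02	Empiric acyclovir was started on admission
drug03	Vancomycin dosed by level
drug04	Ampicillin added for listeria coverage
drug05	Trimethoprim-sulfamethoxazole at treatment dose
drug06	Cefepime for broadened gram negative coverage
drug07	Transitioned to meropenem per sensitivities
drug08	Induction with liposomal amphotericin
drug09	Consolidation fluconazole planned
drug10	Completing doxycycline course
drug11	Ganciclovir started pending confirmation
drug12	Metronidazole for anaerobic coverage
kw01	Reports persistent frontal headache
kw02	Intermittent fevers overnight
kw03	Underwent bedside lumbar puncture without complication
kw04	Examination notable for nuchal rigidity
kw05	Endorses photophobia in bright light
kw06	Presented with altered mental status
kw07	CSF sent for routine studies
kw08	Witnessed generalized seizure in the emergency department
kw09	Complains of neck stiffness since yesterday
kw10	WBC count trended this morning
kw11	Opening pressure measured at the bedside
kw12	Exam shows mild meningismus
kw13	Differential includes causes of pleocytosis
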