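# Demo neuroinfectious-disease lexicon: pattern_id <TAB> category <TAB> regex
# Categories: positive_nid, negative_nid, nid_drug, nid_likely_keyword.
# A small curated stand-in for a full institutional expression library.
pos01	positive_nid	csf positive for
pos02	positive_nid	bacterial meningitis
pos03	positive_nid	viral encephalitis
pos04	positive_nid	meningoencephalitis
pos05	positive_nid	ventriculitis
pos06	positive_nid	csf pleocytosis noted
pos07	positive_nid	hsv[- ]?1 pcr positive
pos08	positive_nid	consistent with cns infection
pos09	positive_nid	cryptococcal meningitis
pos10	positive_nid	enterovir(?:us|al) meningitis
pos11	positive_nid	west nile virus encephalitis
pos12	positive_nid	positive for vzv
pos13	positive_nid	treated for neurosyphilis
pos14	positive_nid	confirmed cns infection
pos15	positive_nid	epstein[- ]barr virus detected in csf
neg01	negative_nid	no signs of any infectious
neg02	negative_nid	lps? have been negative
neg03	negative_nid	no evidence of meningitis
neg04	negative_nid	csf cultures (?:remain )?negative
neg05	negative_nid	autoimmune encephalitis
neg06	negative_nid	cns infection ruled out
neg07	negative_nid	no evidence of cns infection
neg08	negative_nid	pcr negative for hsv
neg09	negative_nid	low suspicion for meningitis
neg10	negative_nid	encephalopathy without infection
drug01	nid_drug	ceftriaxone
drug02	nid_drug	acyclovir
drug03	nid_drug	vancomycin
drug04	nid_drug	ampicillin
drug05	nid_drug	trimethoprim[- ]sulfamethoxazole
drug06	nid_drug	cefepime
drug07	nid_drug	meropenem
drug08	nid_drug	amphotericin
drug09	nid_drug	fluconazole
drug10	nid_drug	doxycycline
drug11	nid_drug	ganciclovir
drug12	nid_drug	metronidazole
kw01	nid_likely_keyword	headache
kw02	nid_likely_keyword	\bfevers?\b
kw03	nid_likely_keyword	lumbar puncture
kw04	nid_likely_keyword	nuchal rigidity
kw05	nid_likely_keyword	photophobia
kw06	nid_likely_keyword	altered mental status
kw07	nid_likely_keyword	\bcsf\b
kw08	nid_likely_keyword	seizure
kw09	nid_likely_keyword	neck stiffness
kw10	nid_likely_keyword	wbc count
kw11	nid_likely_keyword	opening pressure
kw12	nid_likely_keyword	meningismus
kw13	nid_likely_keyword	pleocytosis
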