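# Default irAE preferred-term list (synthetic placeholder).
# The curated 106-term MedDRA list used for a real analysis is a required,
# versioned input; this short list only covers the synthetic vocabulary and
# common, well-established irAE preferred terms.
colitis
pneumonitis
hypophysitis
hypothyroidism
hyperthyroidism
hepatitis
adrenal insufficiency
myocarditis
nephritis
rash maculo-papular
vitiligo
uveitis
thyroiditis
myositis
encephalitis
diabetic ketoacidosis
pancreatitis
guillain-barre syndrome
pruritus immune
arthritis immune
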