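# Medical specialty and subspecialty names used as bio inclusion terms
# (graduate-medical-education specialty taxonomy; matched case-insensitively
# on whole-token sequences). One term per line; '#' starts a comment.
allergy and immunology
anesthesiology
cardiology
cardiothoracic surgery
child neurology
colon and rectal surgery
dermatology
emergency medicine
endocrinology
family medicine
gastroenterology
general surgery
geriatrics
hematology
hospital medicine
infectious disease
internal medicine
interventional radiology
medical genetics
neonatology
nephrology
neurological surgery
neurology
nuclear medicine
obstetrics and gynecology
oncology
ophthalmology
orthopaedic surgery
otolaryngology
pathology
pediatrics
physical medicine and rehabilitation
plastic surgery
preventive medicine
psychiatry
pulmonology
radiation oncology
radiology
rheumatology
sports medicine
thoracic surgery
urology
vascular surgery
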