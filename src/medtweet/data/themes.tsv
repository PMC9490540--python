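general health care	health
general health care	healthcare
general health care	doctor
general health care	medtwitter
general health care	medicine
covid19 and public health	covid19
covid19 and public health	coronavirus
covid19 and public health	sarscov2
covid19 and public health	covid19coronavirus
covid19 and public health	maskup
covid19 and public health	socialdistancing
covid19 and public health	flattenthecurve
politics	trump
politics	vote
politics	election2020
politics	tcot
politics	newsmax
politics	realdonaldtrump
politics	backfiretrump
social activism	blacklivesmatter
social activism	blm
social activism	diversity
social activism	inclusion
mental health and well-being	mentalhealth
mental health and well-being	wellness
mental health and well-being	depression
mental health and well-being	mindfulness
health technology	digitalhealth
health technology	healthtech
health technology	telehealth
health technology	healthit
conferences	aap18
conferences	acc19
conferences	asco20
patient groups	bcsm
patient groups	lcsm
patient groups	btsm
specialties and subspecialties	cardiology
specialties and subspecialties	dermatology
specialties and subspecialties	plasticsurgery
specialties and subspecialties	radiology
specialties and subspecialties	oncology
specialties and subspecialties	pediatrics
specialties and subspecialties	psychiatry
medical conditions and procedures	diabetes
medical conditions and procedures	cancer
medical conditions and procedures	stroke
medical conditions and procedures	hypertension
medical conditions and procedures	obesity
medical education	meded
medical education	foamed
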