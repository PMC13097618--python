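code,description
97605,"Negative pressure wound therapy, total wound surface area <= 50 sq cm"
67228,"Treatment of extensive or progressive retinopathy, photocoagulation"
92316,"Prescription of optical and physical characteristics of contact lens, corneoscleral"
99213,"Office or other outpatient visit, established patient, low complexity"
99214,"Office or other outpatient visit, established patient, moderate complexity"
99223,"Initial hospital inpatient care, high complexity"
99232,"Subsequent hospital inpatient care, moderate complexity"
99238,"Hospital inpatient discharge day management, 30 minutes or less"
99284,"Emergency department visit, moderate complexity"
99285,"Emergency department visit, high complexity"
99291,"Critical care, first 30-74 minutes"
10060,"Incision and drainage of abscess, simple or single"
12001,"Simple repair of superficial wounds of scalp, neck, axillae, 2.5 cm or less"
29881,"Arthroscopy, knee, surgical; with meniscectomy"
36415,Collection of venous blood by venipuncture
43239,Esophagogastroduodenoscopy with biopsy
45380,"Colonoscopy, flexible; with biopsy"
47562,"Laparoscopy, surgical; cholecystectomy"
64483,"Injection, anesthetic agent; transforaminal epidural, lumbar, single level"
66984,Extracapsular cataract removal with insertion of intraocular lens prosthesis
70450,"Computed tomography, head or brain; without contrast material"
71046,"Radiologic examination, chest; 2 views"
72148,"Magnetic resonance imaging, spinal canal, lumbar; without contrast"
74177,"Computed tomography, abdomen and pelvis; with contrast material"
76700,"Ultrasound, abdominal, real time with image documentation; complete"
77067,"Screening mammography, bilateral"
80048,"Basic metabolic panel (calcium, total)"
80053,Comprehensive metabolic panel
80061,Lipid panel
81001,"Urinalysis, automated, with microscopy"
82947,"Glucose; quantitative, blood"
83036,Hemoglobin; glycosylated (A1C)
84443,Thyroid stimulating hormone (TSH)
85025,"Blood count; complete (CBC), automated with differential"
85610,Prothrombin time
86900,"Blood typing, serologic; ABO"
87086,"Culture, bacterial; quantitative colony count, urine"
88305,"Surgical pathology, gross and microscopic examination, level IV"
90471,"Immunization administration, one vaccine"
90686,"Influenza virus vaccine, quadrivalent, preservative free"
93000,"Electrocardiogram, routine ECG with at least 12 leads; with interpretation"
93010,Electrocardiogram; interpretation and report only
93306,"Echocardiography, transthoracic, complete, with Doppler"
94640,Pressurized or nonpressurized inhalation treatment for acute airway obstruction
96372,"Therapeutic, prophylactic, or diagnostic injection; subcutaneous or intramuscular"
97110,"Therapeutic procedure, therapeutic exercises, each 15 minutes"
99406,"Smoking and tobacco use cessation counseling visit, 3-10 minutes"
A0428,"Ambulance service, basic life support, non-emergency transport"
J0696,"Injection, ceftriaxone sodium, per 250 mg"
J1100,"Injection, dexamethasone sodium phosphate, 1 mg"
J1885,"Injection, ketorolac tromethamine, per 15 mg"
J2785,"Injection, regadenoson, 0.1 mg"
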