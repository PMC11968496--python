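drug,n_articles,n_disease_articles,tf_printed,idf_printed,tfidf_printed
Nilotinib,2686,0,0,2.392,0
Trovafloxacin,677,0,0,2.99,0
Apratoxin a,39,0,0,4.23,0
Carboplatin,15922,0,0,1.619,0
Clinafloxacin,230,0,0,3.459,0
Decitabine,2074,1,0.003,2.504,0.0075
Antimony,7003,2,0.006,1.975,0.0118
Luteolin,6265,2,0.006,2.024,0.0121
Lapatinib,2502,2,0.006,2.422,0.0145
Actinomycin d,14122,3,0.009,1.671,0.015
Sulforaphane,2522,3,0.009,2.419,0.0217
Hydrocortisone,19255,5,0.015,1.536,0.0229
Dexamethasone,63333,11,0.033,1.019,0.0335
Nicotine,43943,11,0.033,1.178,0.0387
Sevoflurane,10326,10,0.03,1.807,0.0539
Arachidonic acid,36896,15,0.045,1.254,0.0561
Pioglitazone,5335,10,0.03,2.094,0.0625
Propofol,23143,19,0.057,1.456,0.0826
Insulin,361574,191,0.57,0.263,0.1496
Mercury,43833,50,0.149,1.179,0.1759
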