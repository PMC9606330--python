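smq_code,smq_name,scope,parent_code,pt_name
20000049,Cardiac arrhythmias,narrow,,
20000004,Cardiac failure,narrow,,
20000150,Cardiomyopathy,narrow,,
20000081,Embolic and thrombotic events,narrow,,
20000147,Hypertension,narrow,,
20000043,Ischaemic heart disease,narrow,,
20000239,Noninfectious myocarditis/pericarditis,narrow,,
20000130,Pulmonary hypertension,narrow,,
20000001,Torsade de pointes/QT prolongation,narrow,,
20000082,"Embolic and thrombotic events, arterial",narrow,20000081,
20000083,"Embolic and thrombotic events, vessel type unspecified and mixed arterial and venous",narrow,20000081,
20000084,"Embolic and thrombotic events, venous",narrow,20000081,
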