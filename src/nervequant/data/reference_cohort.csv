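study_id,age,sex,clinical_dx,path_dx,timecourse,delta_days_to_biopsy,cns_disease,vasculitis
P1,54,f,Immuncomplex vasculitis,Perivasculitis,subacute,-1,no,definite_or_probable
P2,75,m,Hepatitis B-associated vasculitis,Vasculitis,subacute,6,no,definite_or_probable
P3,48,f,Systemic sclerosis and vasculitic neuropathy,Perivasculitis,acute,16,no,definite_or_probable
P4,73,m,Vasculitic neuropathy,Vasculitis,subacute,0,no,definite_or_probable
P5,53,m,ANCA-associated vasculitis with polyneuropathy,Vasculitis,chronic,5,no,definite_or_probable
P6,58,f,Vasculitic polyneuropathy,Vasculitis,chronic,-7,no,definite_or_probable
P7,32,f,Acute motoric axonal neuropathy,Perivasculitis,subacute,8,yes,definite_or_probable
P8,62,f,Suspected vasculitic neuropathy,Mild axonal neuropathy,chronic,-2,no,definite_or_probable
P9,66,m,Suspected vasculitic neuropathy,Perivasculitis,subacute,3,yes,definite_or_probable
P10,55,f,Suspected isolated vasculitic neuropathy,Perivasculitis,chronic,1,no,definite_or_probable
P11,82,f,Unclear inflammatory polyneuropathy,Perivasculitis,subacute,4,no,other
P12,61,m,Unclear axonal polyneuropathy,Perivasculitis,chronic,-2,unclear,other
P13,65,m,Demyelinating polyneuropathy,Neuritis,subacute,2,no,other
P14,26,f,Suspected autoimmune encephalitis and polyneuropathy,Neuritis,subacute,8,yes,other
P15,65,m,"Axonal neuropathy, most likely because of diabetes",Neuritis,subacute,16,unclear,other
P16,41,m,Small fiber neuropathy,No pathological findings,chronic,16,no,other
P17,76,f,Amyotrophic lateralsclerosis,No pathological findings,chronic,2,yes,other
P18,35,m,Polyneuropathy,Mild axonal neuropathy,acute,6,unclear,other
P19,71,m,Chronic inflammatory demyelinating polyneuropathy (CIDP),Mild axonal neuropathy,subacute,4,no,other
P20,75,f,Mixed polyneuropathy,Mild axonal neuropathy,subacute,9,no,other
P21,37,m,Unclear myelitis and encephalitis,Mild axonal neuropathy,subacute,6,yes,other
P22,50,f,Muscular dystrophy,Mild axonal neuropathy,chronic,6,no,other
P23,60,m,Unclear polyneuropathy,Mild axonal neuropathy,chronic,0,yes,other
P24,48,m,Diabetes mellitus polyneuropathy,Mild axonal neuropathy,chronic,7,no,other
P25,44,m,Unclear axonal polyneuropathy,Mild axonal neuropathy,chronic,1,no,other
P26,26,m,Cerebellar ataxia,Mild axonal neuropathy,chronic,3,unclear,other
P27,57,f,MGUS-associated CIDP,Mild axonal neuropathy,chronic,1,no,other
P28,75,m,CIDP versus paraproteinemic polyneuropathy,Severe axonal neuropathy,subacute,21,no,other
P29,60,m,Guillian-Barré syndrome,Severe axonal neuropathy,chronic,-16,yes,other
P30,32,m,Chronic inflammatory demyelinating polyneuropathy (CIDP),Severe axonal neuropathy,chronic,25,no,other
P31,47,m,Suspected toxic and diabetic neuropathy,Severe axonal neuropathy,chronic,12,no,other
P32,70,m,Paraneoplastic neuropathy,Severe axonal neuropathy,chronic,4,no,other
P33,63,m,Suspected chronic inflammatory axonal polyneuropathy (CIAP),Severe axonal neuropathy,chronic,1,yes,other
P34,67,m,Unclear polyneuropathy,Severe axonal neuropathy,chronic,-1,no,other
P35,80,m,Amyotrophic lateralsclerosis,Severe axonal neuropathy,chronic,6,yes,other
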