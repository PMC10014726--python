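marker,clone,is_totalseqc,n_donors,n_replicates,pct_sensitive,pct_partial,pct_not
CD4,OKT4,0,4,16,0,0,100
CD4,RPA-T4,1,2,3,67,33,0
CD8a,RPA-T8,1,2,3,100,0,0
CD8a,SK1,0,3,9,22,22,56
CD25,2A3,0,2,2,100,0,0
CD25,4E3,0,2,2,0,0,100
CD25,B1.49.9,0,2,2,0,50,50
CD25,BC96,1,3,3,67,0,33
CD25,M-A251,0,3,5,20,20,60
CD27,O323,1,2,4,75,25,0
CD120b,3G7A02,1,2,2,100,0,0
CCR4,1G1,0,2,2,0,50,50
CCR4,L291H4,1,3,4,75,0,25
CCR6,11A9,0,2,2,50,0,50
CCR6,G034E3,1,3,4,75,25,0
CCR6,R6H1,0,2,2,100,0,0
PD1,eBioJ105,0,2,2,100,0,0
PD1,EH12.1,0,2,2,100,0,0
PD1,EH12.2H7,1,3,3,100,0,0
PD1,PD1.3,0,2,2,50,0,50
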