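abbreviation,pred_koa,pred_mlr,pred_svm
TH-NAPH,-5.231,-5.184,-4.867
NAPH,-5.038,-5.239,-5.093
2-MNAPH,-4.729,-4.738,-4.920
1-MNAPH,-4.716,-4.789,-4.932
BIPH,-4.484,-4.469,-4.851
"1,3DMNAPH",-4.407,-4.330,-4.680
ACEY,-4.253,-4.476,-4.766
ACEN,-4.401,-4.511,-4.750
FLUO,-4.047,-4.163,-4.599
PHE,-3.642,-3.724,-4.268
ANT,-3.725,-3.459,-3.967
2-MPHE,-3.461,-3.205,-3.614
"3,6-DMPHE",-3.120,-2.728,-2.930
FLUA,-2.754,-2.946,-3.266
PYR,-3.017,-2.950,-3.300
RET,-2.689,-1.919,-1.743
BaA,-2.451,-1.828,-1.593
BeP,-0.984,-1.513,-1.130
BaP,-1.300,-1.016,-0.482
IcdP,-0.856,-0.284,0.192
DahA,-0.708,-0.094,0.352
BghiP,-0.888,-0.702,-0.127
1-IND,-4.542,-4.235,-3.784
"1,4-NQ",-2.625,-4.261,-3.834
1-NALD,-3.680,-3.506,-3.224
2-BPCA,-3.236,-2.760,-2.615
9-FLU,-3.050,-2.959,-2.748
"1,2-ACEQ",-2.625,-3.180,-2.953
"9,10-AQ",-2.233,-2.902,-2.718
"1,8-NA",-3.243,-3.140,-2.912
4-CPHE,-2.110,-2.345,-2.201
2-MAQ,-1.383,-2.362,-2.194
BAFLU,-1.660,-1.322,-1.442
BdeAQ,-1.608,-1.328,-1.527
BaAQ,-0.373,-1.231,-1.211
"5,12-NQ",-0.296,-1.006,-1.105
BcdPQ,-0.701,-0.592,-1.231
1-NNAP,-3.571,-3.635,-3.333
2-NBP,-3.301,-3.184,-2.993
5-NACE,-3.017,-2.867,-2.671
2-NFLU,-3.178,-2.501,-2.329
9-NPHE,-2.342,-2.324,-2.158
9-NANT,-1.943,-1.660,-1.703
1-NPYR,-1.255,-1.048,-1.295
"2,7-DNFLU",-1.647,-2.037,-1.888
6-NCHR,-0.933,-0.604,-0.879
QUI,-4.298,-3.731,-3.475
BhQ,-2.767,-2.483,-2.417
ACR,-2.522,-1.969,-2.222
CAR,-2.471,-4.071,-4.423
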