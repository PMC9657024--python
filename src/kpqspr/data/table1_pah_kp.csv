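abbreviation,name,class,log_kp_exp,log_koa,alpha,vsmin_x100,is_validation
TH-NAPH,"1,2,3,4-Tetrahydronaphthalene",PAH,-4.060,4.75,108.571,-3.397,0
NAPH,Naphthalene,PAH,-4.392,5.05,112.345,-2.698,1
2-MNAPH,2-Methylnaphthalene,PAH,-5.001,5.53,126.847,-2.924,1
1-MNAPH,1-Methylnaphthalene,PAH,-4.617,5.55,125.047,-2.944,0
BIPH,Biphenyl,PAH,-4.955,5.91,137.036,-2.739,0
"1,3DMNAPH","1,3-Dimethylnaphthalene",PAH,-4.837,6.03,139.231,-3.030,1
ACEY,Acenaphthylene,PAH,-4.921,6.27,134.493,-3.034,0
ACEN,Acenaphthene,PAH,-4.821,6.04,132.491,-3.141,0
FLUO,Fluorene,PAH,-4.756,6.59,145.606,-2.912,0
PHE,Phenanthrene,PAH,-4.500,7.22,162.006,-2.643,0
ANT,Anthracene,PAH,-3.811,7.09,170.616,-2.639,0
2-MPHE,2-Methylphenanthrene,PAH,-3.747,7.50,177.433,-2.820,0
"3,6-DMPHE","3,6-Dimethylphenanthrene",PAH,-3.847,8.03,191.260,-3.031,0
FLUA,Fluoranthene,PAH,-3.223,8.60,186.008,-2.796,0
PYR,Pyrene,PAH,-3.027,8.19,187.779,-2.555,1
RET,Retene,PAH,-2.703,8.70,217.138,-3.080,0
BaA,Benzo[a]anthracene,PAH,-1.592,9.07,223.989,-2.590,1
BeP,Benzo[e]pyrene,PAH,-0.316,11.35,234.532,-2.550,0
BaP,Benzo[a]pyrene,PAH,0.028,10.86,250.507,-2.568,0
IcdP,"Indeno[1,2,3-cd]pyrene",PAH,0.255,11.55,272.695,-2.774,0
DahA,"Dibenzo[a,h]anthracene",PAH,-0.687,11.78,280.623,-2.553,0
BghiP,"Benzo[g,h,i]perylene",PAH,0.028,11.50,261.269,-2.498,0
1-IND,1-Indanone,O-PAH,-3.998,5.82,99.753,-8.388,0
"1,4-NQ","1,4-Naphthoquinone",O-PAH,-3.990,8.80,113.590,-6.535,0
1-NALD,1-Naphthaldehyde,O-PAH,-4.111,7.16,127.809,-7.844,1
2-BPCA,2-Biphenylcarboxaldehyde,O-PAH,-3.491,7.85,149.944,-8.101,1
9-FLU,9-Fluorenone,O-PAH,-3.630,8.14,148.889,-7.418,0
"1,2-ACEQ","1,2-Acenaphthenequinone",O-PAH,-3.196,8.80,138.303,-7.854,0
"9,10-AQ","9,10-Anthraquinone",O-PAH,-2.382,9.41,159.881,-6.271,1
"1,8-NA","1,8-Naphtalic anhydride",O-PAH,-3.033,7.84,141.118,-7.659,1
4-CPHE,"4H-Cyclopenta[d,e,f]phenanthrenone",O-PAH,-2.739,9.60,170.679,-7.191,1
2-MAQ,"2-Meth-9,10-anthraquinone",O-PAH,-1.944,10.73,175.048,-6.566,0
BAFLU,Benzo[a]florenone,O-PAH,-1.590,10.30,203.092,-7.291,1
BdeAQ,"7H-Benzo[d,e]anthracene-7-one",O-PAH,-0.682,10.38,199.470,-7.715,1
BaAQ,"Benzo[a]anthracene-7,12-dione",O-PAH,-1.112,12.30,214.077,-6.284,0
"5,12-NQ","5,12-Naphthacenequinone",O-PAH,-0.949,12.42,219.462,-6.523,0
BcdPQ,"6H-Benzo[c,d]pyren-6-one",O-PAH,-0.635,11.79,222.901,-7.780,1
1-NNAP,1-Nitronaphthalene,N-PAH,-3.703,7.33,129.792,-7.060,0
2-NBP,2-Nitrobiphenyl,N-PAH,-2.352,7.75,151.356,-6.187,0
5-NACE,5-Nitroacenaphthene,N-PAH,-2.219,8.19,151.022,-7.526,0
2-NFLU,2-Nitrofluorene,N-PAH,-1.932,7.94,167.360,-6.969,0
9-NPHE,9-Nitrophenanthrene,N-PAH,-2.098,9.24,177.214,-6.454,0
9-NANT,9-Nitroanthracene,N-PAH,-1.858,9.86,190.063,-7.545,0
1-NPYR,1-Nitropyrene,N-PAH,-1.496,10.93,211.741,-7.317,0
"2,7-DNFLU","2,7-Dinitrofluorene",N-PAH,-1.595,10.32,187.649,-6.309,0
6-NCHR,6-Nitrochrysene,N-PAH,-1.696,11.43,232.917,-6.475,0
QUI,Quinoline,AZA,-3.127,6.20,107.069,-9.535,0
BhQ,Benzo[h]quinoline,AZA,-2.804,8.58,156.877,-8.358,1
ACR,Acridine,AZA,-2.275,8.96,165.008,-9.437,0
CAR,Carbazole,AZA,-3.372,9.04,145.738,-3.265,1
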