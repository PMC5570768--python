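compound,hmdb,compound_class,pcorr_batch1,pcorr_batch2,pcorr_batch3,avg_pcorr,avg_ci
1-5-Anhydro-d-glucitol,HMDB03911,Carbohydrate,0.324,-0.106,-0.045,,
2-Oxoisocaproic acid,HMDB00695,Organic acid,-0.560,-0.527,-0.652,-0.579,0.387
3-Hydroxybutanoic acid,HMDB00357,Organic acid,-0.308,-0.122,-0.104,-0.178,0.614
4-Hydroxyphenylacetic acid,HMDB00020,Organic acid,0.212,0.196,0.078,0.162,0.340
Adenosine-5-monophosphate,HMDB00045,Nucleotide,-0.318,-0.395,-0.039,-0.251,0.497
Alanine,HMDB00161,Amino acid,0.150,0.267,-0.335,,
Allothreonine,HMDB60878,Amino acid,0.126,0.251,-0.492,,
alpha-Aminobutyric acid,HMDB00452,Organic acid,-0.027,-0.080,-0.350,-0.152,0.412
alpha-Ketoglutaric acid,HMDB00208,Organic acid,0.297,-0.104,0.169,,
alpha-Linolenic acid (ALA),HMDB02181,Fatty acid,-0.647,-0.268,-0.159,-0.358,0.684
alpha-Tocopherol,HMDB01893,Sterol,0.048,-0.088,0.046,,
Arachidonic acid,HMDB01043,Fatty acid,-0.411,-0.343,-0.176,-0.310,0.526
Arginine,HMDB00517,Amino acid,0.382,0.320,0.147,0.283,0.352
Asparagine,HMDB00168,Amino acid,0.090,0.098,-0.293,,
beta-Sitosterol,HMDB00852,Sterol,0.100,0.050,0.207,0.119,0.383
Caffeine,HMDB01847,Nucleotide,0.105,-0.182,0.138,,
Campesterol,HMDB02869,Sterol,0.247,0.050,0.091,0.129,0.418
Cholesterol,HMDB00067,Sterol,0.004,0.090,0.004,0.033,0.465
Citric acid,HMDB00094,Organic acid,-0.189,-0.183,-0.315,-0.229,0.498
Creatinine,HMDB00562,Amino ketone,0.384,0.241,0.201,0.275,0.388
Cystathionine,HMDB00099,Amino acid,0.216,0.161,0.087,0.155,0.370
Cysteine,HMDB00574,Amino acid,-0.275,-0.050,-0.124,-0.150,0.548
Cystine,HMDB00192,Amino acid,0.313,0.409,0.156,0.293,0.379
Docosahexaenoic acid (DHA),HMDB03581,Fatty acid,-0.292,-0.540,-0.201,-0.344,0.565
Elaidic acid,HMDB00573,Fatty acid,-0.682,-0.301,-0.178,-0.387,0.626
Erythronic acid,HMDB00613,Carbohydrate,-0.043,-0.267,0.258,,
Galactitol,HMDB00107,Carbohydrate,0.388,0.317,0.103,0.269,0.430
gamma-Tocopherol,HMDB01492,Sterol,-0.152,0.332,0.180,,
Gluconic acid,HMDB00625,Organic acid,-0.029,-0.034,-0.514,-0.193,0.363
Glucosamine,HMDB01514,Carbohydrate,-0.010,0.051,-0.280,,
Glucose,HMDB00122,Carbohydrate,-0.403,-0.108,-0.307,-0.272,0.335
Glutamic acid,HMDB00148,Amino acid,0.096,0.056,0.280,0.144,0.259
Glutamine,HMDB00641,Amino acid,0.176,0.338,0.108,0.208,0.282
Glyceric acid,HMDB00139,Organic acid,0.388,0.023,0.210,0.207,0.445
Glycerol,HMDB00131,Polyol,-0.122,-0.218,0.246,,
Glycerol-3-phosphate,HMDB35909,Organic acid,0.154,-0.041,0.248,,
Glycine,HMDB00123,Amino acid,0.264,0.256,0.097,0.206,0.340
Hexadecanoic acid,HMDB00220,Fatty acid,-0.640,-0.385,-0.278,-0.434,0.620
Hippuric acid,HMDB00714,Amino acid,0.299,-0.194,0.332,,
Histidine,HMDB00177,Amino acid,-0.045,0.185,-0.633,,
Inosine,HMDB00195,Nucleoside,-0.104,-0.370,-0.203,-0.225,0.535
Lactic acid,HMDB00190,Organic acid,0.159,0.037,0.034,0.077,0.361
Lactose,HMDB00186,Carbohydrate,-0.418,0.240,0.235,,
Lauric acid,HMDB00638,Fatty acid,-0.550,-0.236,-0.133,-0.307,0.391
Linoleic acid,HMDB00673,Fatty acid,-0.509,-0.233,-0.330,-0.357,0.698
Lysine,HMDB00182,Amino acid,0.162,0.347,-0.371,,
Malic acid,HMDB00156,Organic acid,0.114,-0.216,-0.037,,
Maltose,HMDB00163,Carbohydrate,-0.632,-0.307,-0.013,-0.317,0.637
Methionine,HMDB00696,Amino acid,0.170,0.174,-0.445,,
Methyl linoleate,HMDB34381,Fatty acid methyl ester,0.391,0.162,0.289,0.281,0.313
Nonanoic acid,HMDB00847,Fatty acid,-0.039,-0.066,0.057,,
o-Phosphoethanolamine,HMDB00224,Organic phosphoric acid,-0.391,-0.341,-0.060,-0.264,0.475
Ornithine,HMDB00214,Amino acid,0.431,0.489,0.093,0.338,0.323
Oxalic acid,HMDB02329,Organic acid,-0.218,0.180,0.033,,
Palmitoleic acid,HMDB03229,Fatty acid,0.289,0.205,-0.037,,
Phenylalanine,HMDB00159,Amino acid,0.062,-0.021,-0.212,,
Phosphoric acid,HMDB02142,Inorganic acid,-0.105,-0.032,0.209,,
Proline,HMDB00162,Amino acid,0.102,0.476,-0.065,,
Pyroglutamic acid,HMDB00267,Amino acid,-0.053,0.215,0.181,,
Scyllo-inositol,HMDB06088,Polyol,0.275,0.312,0.085,0.224,0.410
Serine,HMDB00187,Amino acid,0.192,0.069,0.254,0.172,0.240
Squalene,HMDB00256,Carbohydrate,-0.114,0.336,0.015,,
Stearic acid,HMDB00827,Fatty acid,-0.592,-0.495,-0.073,-0.387,0.497
Sucrose,HMDB00258,Carbohydrate,0.165,0.355,0.040,0.187,0.407
Taurine,HMDB00251,Amino acid,-0.340,-0.577,0.103,,
Threonic acid,HMDB00943,Organic acid,-0.003,-0.050,0.262,,
Threonine,HMDB00167,Amino acid,0.251,-0.130,0.332,,
Tryptophan,HMDB00929,Amino acid,-0.197,-0.364,-0.448,-0.336,0.258
Tyrosine,HMDB00158,Amino acid,0.097,0.242,-0.118,,
Uric acid,HMDB00289,Purine,0.309,0.250,0.186,0.248,0.508
Valine,HMDB00883,Amino acid,-0.168,0.022,-0.436,,
Xylitol,HMDB02917,Polyol,0.430,0.416,0.054,0.300,0.385
Xylose,HMDB00098,Carbohydrate,0.180,0.475,0.238,0.298,0.304
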