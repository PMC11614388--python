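metabolite,FC,log2FC,p_value,minus_log10_p,enrichment
Kynurenic acid,3.56,1.83,0.24,0.62,Not Sig
Hexadecanoic acid,2.27,1.18,0.01,2.11,HFD 3d
Nicotinamide-N-oxide,0.45,-1.14,0.02,1.71,CT
Octadecanoic acid,2.17,1.12,0.02,1.64,HFD 3d
Serotonin,0.51,-0.98,0.95,0.02,Not Sig
N-Methyl-4-pyridone-3-carboxamide,1.81,0.85,0.06,1.21,Not Sig
Methylmalonate,1.80,0.85,0.01,1.86,Not Sig
Tetradecanoic acid,1.78,0.83,0.29,0.53,Not Sig
Octanoylcarnitine,0.60,-0.73,0.99,0.00,Not Sig
Propionylcarnitine,1.65,0.73,0.45,0.35,Not Sig
Isovalerylcarnitine,1.65,0.72,0.02,1.74,Not Sig
Nicotinic acid,1.60,0.68,0.04,1.39,Not Sig
Glutarylcarnitine,1.60,0.68,0.004,2.40,Not Sig
Nicotinamide,0.63,-0.66,0.07,1.13,Not Sig
1-Methylnicotinamide,0.66,-0.59,0.31,0.51,Not Sig
Ophthalmic acid,0.68,-0.56,0.24,0.62,Not Sig
N-Methylserotonin,1.41,0.49,0.17,0.77,Not Sig
O-Acetylcarnitine,1.38,0.47,0.62,0.21,Not Sig
Tryptophan,1.35,0.43,0.10,1.02,Not Sig
3-Hydroxyanthranillic acid,1.34,0.43,0.20,0.69,Not Sig
Butyrylcarnitine,1.33,0.42,0.28,0.55,Not Sig
Nudifloramide,1.27,0.34,0.04,1.41,Not Sig
Quinolinic acid,1.21,0.27,0.22,0.66,Not Sig
S-Adenosyl-L-homocysteine,0.84,-0.26,0.44,0.35,Not Sig
Isobutyrylcarnitine,1.15,0.21,0.62,0.20,Not Sig
2-Methylbutyrylcarnitine,1.15,0.20,0.64,0.19,Not Sig
Nicotinic acid mononucleotide,0.90,-0.15,0.33,0.49,Not Sig
Hexanoylcarnitine,1.10,0.14,0.69,0.16,Not Sig
Nicotinamide mononucleotide,1.10,0.14,0.95,0.02,Not Sig
Carnitine,1.06,0.08,0.88,0.06,Not Sig
S-Adenosyl-L-methionine,1.06,0.08,0.61,0.21,Not Sig
3-Hydroxykynurenine,1.04,0.06,0.87,0.06,Not Sig
Nicotinuric acid,0.96,-0.06,0.64,0.19,Not Sig
Anthranillic acid,1.04,0.05,0.96,0.02,Not Sig
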