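analyte,hmdb_id,class_label,coa_uM
Linoleic Acid,HMDB0000673,Fatty Acids,2838
DHA,HMDB0002183,Fatty Acids,118
Alanine,HMDB0000161,Amino Acids,300
Glycine,HMDB0000123,Amino Acids,245
Histidine,HMDB0000177,Amino Acids,72.6
Isoleucine,HMDB0000172,Amino Acids,55.5
Leucine,HMDB0000687,Amino Acids,100.4
Lysine,HMDB0000182,Amino Acids,140
Methionine,HMDB0000696,Amino Acids,22.3
Proline,HMDB0000162,Amino Acids,177
Serine,HMDB0000187,Amino Acids,95.9
Threonine,HMDB0000167,Amino Acids,119.5
Tyrosine,HMDB0000158,Amino Acids,57.3
Valine,HMDB0000883,Amino Acids,182.2
Arginine,HMDB0000517,Amino Acids,81.4
Cysteine,HMDB0000574,Amino Acids,44.3
Cystine,HMDB0000192,Amino Acids,7.8
Phenylalanine,HMDB0000159,Amino Acids,51
Creatinine,HMDB0000562,Clinical Markers,60
Glucose,HMDB0000122,Clinical Markers,4560
Homocysteine,HMDB0000742,Clinical Markers,8.5
Cortisol,HMDB0000063,Clinical Markers,0.23
Cholesterol,HMDB0000067,Clinical Markers,3917
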