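platform,analyte,reported_uM,printed_percent_diff
Biocrates,Alanine,331,10.17
Biocrates,Glycine,288,17.72
Biocrates,Histidine,80,10.08
Biocrates,Isoleucine,66,18.92
Biocrates,Leucine,114,13.05
Biocrates,Lysine,151,7.73
Biocrates,Methionine,22,-0.94
Biocrates,Proline,199,12.30
Biocrates,Serine,98,2.14
Biocrates,Threonine,127,6.10
Biocrates,Tyrosine,61,6.48
Biocrates,Valine,174,-4.40
Biocrates,Arginine,95,16.45
Biocrates,Cysteine,46,4.50
Biocrates,Cystine,8.0,2.76
Biocrates,Phenylalanine,57,12.54
Biocrates,Creatinine,65,7.69
Biocrates,Homocysteine,8.5,0.58
Biocrates,Cortisol,0.19,-17.92
HMT,Alanine,211,-29.61
HMT,Glycine,250,1.97
HMT,Histidine,59,-18.25
HMT,Isoleucine,46,-17.02
HMT,Leucine,102,1.25
HMT,Lysine,129,-7.60
HMT,Methionine,14,-38.50
HMT,Proline,138,-22.19
HMT,Serine,69,-27.57
HMT,Threonine,92,-23.08
HMT,Tyrosine,49,-13.95
HMT,Valine,152,-16.30
HMT,Phenylalanine,47,-8.27
HMT,Creatinine,43,-28.14
Nightingale,Linoleic Acid,2960,4.30
Nightingale,DHA,136,15.25
Nightingale,Alanine,312.246,4.08
Nightingale,Glycine,240.87,-1.69
Nightingale,Histidine,70.0707,-3.48
Nightingale,Isoleucine,44.604,-19.63
Nightingale,Leucine,87.7893,-12.56
Nightingale,Tyrosine,61.8318,7.91
Nightingale,Valine,185.06,1.57
Nightingale,Phenylalanine,53.0223,3.97
Nightingale,Creatinine,58.1642,-3.06
Nightingale,Glucose,4679.41,2.62
Nightingale,Cholesterol,3620,-7.58
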