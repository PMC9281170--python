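rank,gene,direction,alpha,gene_split,tpr,tnr,fc,ranking_score,db_source,evidence,antibody_registry_id,vendor_link
1,G0001,positive,0.5,20916,0.93,1,23.5314,1.0771e+07,synthetic fixture,user,,
2,G0002,positive,0.4,18760.2,0.88,1,21.3735,7.54171e+06,synthetic fixture,user,,
3,G0000,positive,0.44,20344.6,0.91,1,19.1022,6.75546e+06,synthetic fixture,user,,
4,G0096,positive,0.33,2044.12,0.16,0.916667,1.84777,1023.61,synthetic fixture,user,,
5,G0188,positive,0.38,1768.03,0.15,0.926667,1.69305,704.443,synthetic fixture,user,,
6,G0076,positive,0.33,1515.74,0.18,0.91,1.4121,495.071,synthetic fixture,user,,
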