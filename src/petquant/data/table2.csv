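patient,organ,method,value
1,Breast_R,MIM,12.03
1,Breast_L,MIM,1.59
1,Liver,MIM,2.51
1,Spleen,MIM,1.68
1,Bone marrow,MIM,1.50
1,Breast_R,contour,11.97
1,Breast_L,contour,1.65
1,Liver,contour,2.48
1,Spleen,contour,1.56
1,Bone marrow,contour,1.65
2,Breast_R,MIM,4.67
2,Breast_L,MIM,0.66
2,Liver,MIM,3.10
2,Spleen,MIM,1.43
2,Bone marrow,MIM,1.13
2,Breast_R,contour,4.31
2,Breast_L,contour,0.68
2,Liver,contour,3.66
2,Spleen,contour,1.25
2,Bone marrow,contour,1.23
3,Breast_R,MIM,10.96
3,Breast_L,MIM,1.96
3,Liver,MIM,5.43
3,Spleen,MIM,4.47
3,Bone marrow,MIM,2.60
3,Breast_R,contour,10.79
3,Breast_L,contour,2.18
3,Liver,contour,5.98
3,Spleen,contour,4.71
3,Bone marrow,contour,2.74
4,Breast_R,MIM,7.03
4,Breast_L,MIM,1.14
4,Liver,MIM,6.12
4,Spleen,MIM,2.15
4,Bone marrow,MIM,2.46
4,Breast_R,contour,6.92
4,Breast_L,contour,1.36
4,Liver,contour,6.44
4,Spleen,contour,1.95
4,Bone marrow,contour,2.63
5,Breast_R,MIM,1.05
5,Breast_L,MIM,7.38
5,Liver,MIM,2.87
5,Spleen,MIM,2.46
5,Bone marrow,MIM,2.32
5,Breast_R,contour,0.96
5,Breast_L,contour,7.37
5,Liver,contour,3.06
5,Spleen,contour,2.51
5,Bone marrow,contour,2.68
6,Breast_R,MIM,7.89
6,Breast_L,MIM,1.99
6,Liver,MIM,2.92
6,Spleen,MIM,2.05
6,Bone marrow,MIM,2.70
6,Breast_R,contour,7.15
6,Breast_L,contour,1.77
6,Liver,contour,2.06
6,Spleen,contour,2.00
6,Bone marrow,contour,2.61
7,Breast_R,MIM,6.91
7,Breast_L,MIM,2.54
7,Liver,MIM,2.38
7,Spleen,MIM,2.14
7,Bone marrow,MIM,2.29
7,Breast_R,contour,7.55
7,Breast_L,contour,2.77
7,Liver,contour,2.18
7,Spleen,contour,2.10
7,Bone marrow,contour,2.18
8,Breast_R,MIM,5.29
8,Breast_L,MIM,1.50
8,Liver,MIM,3.09
8,Spleen,MIM,2.20
8,Bone marrow,MIM,3.90
8,Breast_R,contour,5.45
8,Breast_L,contour,1.60
8,Liver,contour,3.12
8,Spleen,contour,2.18
8,Bone marrow,contour,4.14
9,Breast_R,MIM,4.68
9,Breast_L,MIM,2.58
9,Liver,MIM,6.60
9,Spleen,MIM,3.69
9,Bone marrow,MIM,3.19
9,Breast_R,contour,5.47
9,Breast_L,contour,2.68
9,Liver,contour,6.99
9,Spleen,contour,3.68
9,Bone marrow,contour,3.56
10,Breast_R,MIM,1.58
10,Breast_L,MIM,3.61
10,Liver,MIM,4.54
10,Spleen,MIM,1.93
10,Bone marrow,MIM,2.10
10,Breast_R,contour,1.83
10,Breast_L,contour,3.32
10,Liver,contour,4.19
10,Spleen,contour,1.73
10,Bone marrow,contour,2.30
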