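patient,organ,method,value
1,Breast (right),MIM,0.76
1,Breast (left),MIM,0.74
1,Liver,MIM,2.18
1,Spleen,MIM,1.30
1,Bone marrow,MIM,1.23
1,Breast (right),one VOI,0.84
1,Breast (left),one VOI,0.71
1,Liver,one VOI,1.96
1,Spleen,one VOI,1.30
1,Bone marrow,one VOI,1.21
1,Breast (right),contour,1.14
1,Breast (left),contour,0.81
1,Liver,contour,1.73
1,Spleen,contour,1.16
1,Bone marrow,contour,0.98
2,Breast (right),MIM,0.57
2,Breast (left),MIM,0.32
2,Liver,MIM,1.14
2,Spleen,MIM,0.98
2,Bone marrow,MIM,0.45
2,Breast (right),one VOI,0.49
2,Breast (left),one VOI,0.27
2,Liver,one VOI,0.98
2,Spleen,one VOI,0.89
2,Bone marrow,one VOI,0.44
2,Breast (right),contour,0.47
2,Breast (left),contour,0.30
2,Liver,contour,1.11
2,Spleen,contour,0.77
2,Bone marrow,contour,0.61
3,Breast (right),MIM,1.24
3,Breast (left),MIM,1.53
3,Liver,MIM,1.80
3,Spleen,MIM,2.15
3,Bone marrow,MIM,1.13
3,Breast (right),one VOI,1.28
3,Breast (left),one VOI,1.40
3,Liver,one VOI,1.85
3,Spleen,one VOI,2.02
3,Bone marrow,one VOI,1.17
3,Breast (right),contour,0.60
3,Breast (left),contour,0.43
3,Liver,contour,2.34
3,Spleen,contour,1.38
3,Bone marrow,contour,1.10
4,Breast (right),MIM,0.64
4,Breast (left),MIM,0.45
4,Liver,MIM,2.06
4,Spleen,MIM,1.97
4,Bone marrow,MIM,2.08
4,Breast (right),one VOI,0.54
4,Breast (left),one VOI,0.51
4,Liver,one VOI,1.69
4,Spleen,one VOI,1.71
4,Bone marrow,one VOI,1.72
4,Breast (right),contour,0.59
4,Breast (left),contour,0.45
4,Liver,contour,1.67
4,Spleen,contour,1.48
4,Bone marrow,contour,1.37
5,Breast (right),MIM,0.55
5,Breast (left),MIM,0.45
5,Liver,MIM,2.19
5,Spleen,MIM,2.12
5,Bone marrow,MIM,1.32
5,Breast (right),one VOI,0.36
5,Breast (left),one VOI,0.41
5,Liver,one VOI,1.79
5,Spleen,one VOI,1.90
5,Bone marrow,one VOI,1.07
5,Breast (right),contour,0.44
5,Breast (left),contour,0.34
5,Liver,contour,2.02
5,Spleen,contour,1.62
5,Bone marrow,contour,1.19
6,Breast (right),MIM,0.94
6,Breast (left),MIM,0.76
6,Liver,MIM,2.23
6,Spleen,MIM,1.59
6,Bone marrow,MIM,1.67
6,Breast (right),one VOI,0.86
6,Breast (left),one VOI,0.86
6,Liver,one VOI,1.92
6,Spleen,one VOI,1.56
6,Bone marrow,one VOI,1.40
6,Breast (right),contour,0.59
6,Breast (left),contour,0.40
6,Liver,contour,1.94
6,Spleen,contour,1.39
6,Bone marrow,contour,1.39
7,Breast (right),MIM,1.09
7,Breast (left),MIM,0.96
7,Liver,MIM,1.56
7,Spleen,MIM,1.49
7,Bone marrow,MIM,0.90
7,Breast (right),one VOI,1.13
7,Breast (left),one VOI,1.58
7,Liver,one VOI,1.80
7,Spleen,one VOI,1.66
7,Bone marrow,one VOI,0.80
7,Breast (right),contour,0.69
7,Breast (left),contour,0.65
7,Liver,contour,1.83
7,Spleen,contour,1.40
7,Bone marrow,contour,1.32
8,Breast (right),MIM,0.88
8,Breast (left),MIM,0.54
8,Liver,MIM,2.44
8,Spleen,MIM,1.90
8,Bone marrow,MIM,0.70
8,Breast (right),one VOI,0.89
8,Breast (left),one VOI,0.53
8,Liver,one VOI,2.23
8,Spleen,one VOI,1.70
8,Bone marrow,one VOI,0.60
8,Breast (right),contour,0.50
8,Breast (left),contour,0.38
8,Liver,contour,2.13
8,Spleen,contour,1.45
8,Bone marrow,contour,1.34
9,Breast (right),MIM,0.32
9,Breast (left),MIM,0.41
9,Liver,MIM,2.42
9,Spleen,MIM,1.90
9,Bone marrow,MIM,1.77
9,Breast (right),one VOI,0.39
9,Breast (left),one VOI,0.44
9,Liver,one VOI,2.24
9,Spleen,one VOI,2.00
9,Bone marrow,one VOI,1.76
9,Breast (right),contour,0.40
9,Breast (left),contour,0.35
9,Liver,contour,2.30
9,Spleen,contour,1.84
9,Bone marrow,contour,1.68
10,Breast (right),MIM,1.02
10,Breast (left),MIM,1.07
10,Liver,MIM,1.38
10,Spleen,MIM,0.52
10,Bone marrow,MIM,0.73
10,Breast (right),one VOI,1.02
10,Breast (left),one VOI,1.07
10,Liver,one VOI,1.09
10,Spleen,one VOI,0.44
10,Bone marrow,one VOI,0.94
10,Breast (right),contour,0.58
10,Breast (left),contour,0.68
10,Liver,contour,1.32
10,Spleen,contour,0.58
10,Bone marrow,contour,0.75
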