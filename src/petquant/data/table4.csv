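patient,organ,method,value,location
1,Breast tumor,TLG 40%,5794,Right breast cancer in the inner pericentral area
1,Breast tumor,TLG 50%,4551,Right breast cancer in the inner pericentral area
2,Breast tumor,TLG 40%,1714,Right breast cancer in the upper pericentral area
2,Breast tumor,TLG 50%,1382,Right breast cancer in the upper pericentral area
3,Breast tumor,TLG 40%,1185,Right breast cancer in the upper outer area
3,Breast tumor,TLG 50%,889,Right breast cancer in the upper outer area
4,Breast tumor,TLG 40%,1898,Right breast cancer in the lower center area
4,Breast tumor,TLG 50%,1296,Right breast cancer in the lower center area
5,Breast tumor,TLG 40%,2052,Left breast cancer in the upper outer area
5,Breast tumor,TLG 50%,1004,Left breast cancer in the upper outer area
6,Breast tumor,TLG 40%,3098,Right breast cancer in the lower pericentral area
6,Breast tumor,TLG 50%,1893,Right breast cancer in the lower pericentral area
7,Breast tumor,TLG 40%,3513,Right breast cancer in the lower pericentral area
7,Breast tumor,TLG 50%,2586,Right breast cancer in the lower pericentral area
8,Breast tumor,TLG 40%,1358,Right breast cancer in the upper outer area
8,Breast tumor,TLG 50%,733,Right breast cancer in the upper outer area
9,Breast tumor,TLG 40%,383,Metastatic lymph node in the right axilla
9,Breast tumor,TLG 50%,275,Metastatic lymph node in the right axilla
10,Breast tumor,TLG 40%,2909,Left breast cancer in the upper outer area
10,Breast tumor,TLG 50%,2216,Left breast cancer in the upper outer area
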