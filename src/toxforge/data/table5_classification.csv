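target,task,n_samples,catboost_fp,xgb_fragments,benchmark,benchmark_source
Cardiotoxicity (hERG binary),classification,324010,0.888,0.926,0.930,CardioTox
Ames test,classification,14168,0.845,0.894,0.88,Syntelly
SR-HSE,classification,7281,0.839,0.836,0.736,TranGRU
NR-AR,classification,7263,0.724,0.797,0.824,TranGRU
NR-AR-LBD,classification,7133,0.843,0.835,0.847,TranGRU
NR-PPAR-gamma,classification,6942,0.727,0.809,0.838,TranGRU
NR-aromatase,classification,6929,0.831,0.875,0.784,TranGRU
NR-ER-LBD,classification,6920,0.858,0.878,0.843,TranGRU
SR-ATAD5,classification,6893,0.75,0.862,0.727,TranGRU
SR-ARE,classification,6822,0.825,0.845,0.701,TranGRU
SR-p53,classification,6749,0.748,0.877,0.81,TranGRU
NR-ER,classification,6585,0.852,0.866,0.691,TranGRU
NR-AhR,classification,6446,0.816,0.871,0.833,TranGRU
SR-MMP,classification,6361,0.853,0.896,0.816,TranGRU
Eye irritation,classification,5040,0.977,0.98,0.966,TOXRIC
Hepatotoxicity,classification,3413,0.785,0.811,0.741,TOXRIC
Carcinogenicity,classification,2726,0.757,0.787,0.68,TOXRIC
Eye corrosion,classification,2190,0.993,0.99,0.948,TOXRIC
Blood-brain barrier penetration,classification,1961,0.925,0.936,0.919,Wang et al.
Developmental toxicity,classification,640,0.85,0.857,0.918,TOXRIC
DILI,classification,475,0.874,0.901,0.691,Lim et al.
Reproductive toxicity,classification,146,0.489,0.739,0.927,TOXRIC
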