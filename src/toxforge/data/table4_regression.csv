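target,task,n_samples,catboost_fp,xgb_fragments,benchmark,benchmark_source
Mouse intraperitoneal LD50,regression,91162,0.562,0.486,0.473,TOXRIC
Mouse oral LD50,regression,57307,0.543,0.445,0.445,TOXRIC
Mouse intravenous LD50,regression,41630,0.498,0.415,0.491,TOXRIC
Rat oral LD50,regression,23409,0.589,0.466,0.592,Syntelly
Mouse subcutaneous LD50,regression,19457,0.696,0.652,0.55,Syntelly
Rat intraperitoneal LD50,regression,12769,0.71,0.618,0.61,Syntelly
Rat intravenous LD50,regression,7461,0.894,0.853,0.644,TOXRIC
Rat subcutaneous LD50,regression,5376,0.829,0.743,0.69,Syntelly
Tetrahymena pyriformis IGC50 40 h,regression,3516,0.524,0.46,0.518,TOXRIC
Mouse intraperitoneal LDLo,regression,3500,0.495,0.435,0.52,Syntelly
Rabbit skin LD50,regression,3429,0.521,0.479,0.58,Syntelly
Rabbit oral LD50,regression,2969,0.626,0.588,0.588,Syntelly
Guinea pig oral LD50,regression,1778,0.703,0.659,0.69,Syntelly
Fathead minnow LC50 96 h,regression,1739,0.78,0.72,0.864,TOXRIC
Rat skin LD50,regression,1673,0.665,0.63,0.62,Syntelly
Rabbit intravenous LD50,regression,1604,0.898,0.83,0.67,Syntelly
Rat intraperitoneal LDLo,regression,1568,0.512,0.482,0.63,Syntelly
Mouse intramuscular LD50,regression,1518,0.894,0.866,0.715,TOXRIC
Rat oral LDLo,regression,1464,0.997,0.99,0.71,Syntelly
Bioconcentration factor,regression,1321,0.699,0.626,0.71,Syntelly
Dog intravenous LD50,regression,1215,0.995,0.927,0.838,TOXRIC
Chicken oral LD50,regression,743,0.906,0.941,0.916,TOXRIC
Quail oral LD50,regression,735,0.816,0.852,0.817,TOXRIC
Dog intravenous LDLo,regression,703,0.84,0.834,0.894,TOXRIC
Daphnia magna LC50,regression,699,0.866,0.817,1.109,TOXRIC
Rabbit intravenous LDLo,regression,690,0.783,0.749,1.031,TOXRIC
Guinea pig intraperitoneal LD50,regression,631,0.745,0.786,0.818,TOXRIC
Cat intravenous LD50,regression,542,0.877,0.851,0.836,TOXRIC
Mouse skin LD50,regression,426,0.838,0.815,0.917,TOXRIC
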