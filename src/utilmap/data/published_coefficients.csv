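target,method,spec,term,value,stars
EQ5D,OLS,1,FACT-G,0.006,***
EQ5D,OLS,1,Constant,0.345,
EQ5D,OLS,2,PWB,0.009,***
EQ5D,OLS,2,FWB,0.008,***
EQ5D,OLS,2,EWB,0.005,*
EQ5D,OLS,2,Constant,0.391,
EQ5D,OLS,3,PWB,0.010,***
EQ5D,OLS,3,FWB,0.006,**
EQ5D,OLS,3,EWB,0.006,*
EQ5D,OLS,3,Colorectal,0.018,
EQ5D,OLS,3,Lung,-0.022,
EQ5D,OLS,3,Stage-2,-0.018,
EQ5D,OLS,3,Stage-3,0.019,
EQ5D,OLS,3,Stage-4,0.026,
EQ5D,OLS,3,Constant,0.267,
EQ5D,GLM,1,FACT-G,0.008,***
EQ5D,GLM,1,Constant,-0.798,
EQ5D,GLM,2,PWB,0.012,***
EQ5D,GLM,2,FWB,0.010,***
EQ5D,GLM,2,EWB,0.006,*
EQ5D,GLM,2,Constant,-0.746,
EQ5D,GLM,3,PWB,0.013,***
EQ5D,GLM,3,FWB,0.007,**
EQ5D,GLM,3,EWB,0.008,*
EQ5D,GLM,3,Colorectal,0.019,
EQ5D,GLM,3,Lung,-0.023,
EQ5D,GLM,3,Stage-2,-0.021,
EQ5D,GLM,3,Stage-3,0.025,
EQ5D,GLM,3,Stage-4,0.034,
EQ5D,GLM,3,Constant,-0.867,
EQ5D,CLAD,1,FACT-G,0.005,***
EQ5D,CLAD,1,Constant,0.380,
EQ5D,CLAD,2,PWB,0.006,***
EQ5D,CLAD,2,FWB,0.007,***
EQ5D,CLAD,2,EWB,0.005,**
EQ5D,CLAD,2,Constant,0.481,
EQ5D,CLAD,3,PWB,0.012,***
EQ5D,CLAD,3,FWB,0.005,***
EQ5D,CLAD,3,EWB,0.002,***
EQ5D,CLAD,3,Colorectal,0.012,
EQ5D,CLAD,3,Lung,0.019,
EQ5D,CLAD,3,Stage-2,-0.030,
EQ5D,CLAD,3,Stage-3,0.016,
EQ5D,CLAD,3,Stage-4,-0.009,
EQ5D,CLAD,3,Constant,0.281,
SF6D,OLS,1,FACT-G,0.005,***
SF6D,OLS,1,Constant,0.278,
SF6D,OLS,2,PWB,0.011,***
SF6D,OLS,2,FWB,0.007,***
SF6D,OLS,2,EWB,0.001,
SF6D,OLS,2,Constant,0.343,
SF6D,OLS,3,PWB,0.011,***
SF6D,OLS,3,FWB,0.007,***
SF6D,OLS,3,EWB,0.002,
SF6D,OLS,3,Colorectal,0.006,
SF6D,OLS,3,Lung,-0.009,
SF6D,OLS,3,Stage-2,-0.015,
SF6D,OLS,3,Stage-3,0.028,
SF6D,OLS,3,Stage-4,-0.006,
SF6D,OLS,3,Constant,0.281,
SF6D,GLM,1,FACT-G,0.008,***
SF6D,GLM,1,Constant,-0.982,
SF6D,GLM,2,PWB,0.016,***
SF6D,GLM,2,FWB,0.011,***
SF6D,GLM,2,EWB,0.001,
SF6D,GLM,2,Constant,-0.895,
SF6D,GLM,3,PWB,0.0159,***
SF6D,GLM,3,FWB,0.0096,***
SF6D,GLM,3,EWB,0.003,
SF6D,GLM,3,Colorectal,0.002,
SF6D,GLM,3,Lung,-0.016,
SF6D,GLM,3,Stage-2,-0.023,
SF6D,GLM,3,Stage-3,0.039,
SF6D,GLM,3,Stage-4,-0.005,
SF6D,GLM,3,Constant,-0.956,
SF6D,CLAD,1,FACT-G,0.005,***
SF6D,CLAD,1,Constant,0.331,
SF6D,CLAD,2,PWB,0.009,***
SF6D,CLAD,2,FWB,0.008,***
SF6D,CLAD,2,EWB,0.005,**
SF6D,CLAD,2,Constant,0.282,
SF6D,CLAD,3,PWB,0.012,***
SF6D,CLAD,3,FWB,0.007,***
SF6D,CLAD,3,EWB,-0.004,***
SF6D,CLAD,3,Colorectal,-0.027,
SF6D,CLAD,3,Lung,-0.050,
SF6D,CLAD,3,Stage-2,-0.031,
SF6D,CLAD,3,Stage-3,0.016,
SF6D,CLAD,3,Stage-4,-0.022,
SF6D,CLAD,3,Constant,0.438,
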