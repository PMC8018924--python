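model,group,rmse,mae,mse,m_prime,b_prime,r2
SAMPL6/Z,obscure,1.59,1.26,1.26,1.21,2.19,0.95
SAMPL6/Z,explanatory,3.36,3.08,2.78,0.02,2.00,0.00
SAMPL6/Z,all,2.69,2.24,2.04,1.00,2.04,0.79
SAMPL6/CCSD(T),obscure,1.52,1.13,0.62,1.31,2.02,0.93
SAMPL6/CCSD(T),explanatory,2.62,2.39,2.39,0.82,2.24,0.46
SAMPL6/CCSD(T),all,2.20,1.83,1.32,1.03,1.38,0.79
SAMPL2/min,obscure,2.90,2.67,-2.67,1.10,-2.20,0.89
SAMPL2/min,explanatory,0.58,0.46,0.12,0.83,-0.02,0.78
SAMPL2/min,all,1.98,1.49,-1.00,1.18,-0.64,0.86
SAMPL2/Z,obscure,2.78,2.53,-2.53,1.10,-2.10,0.89
SAMPL2/Z,explanatory,0.66,0.52,0.21,0.84,0.09,0.74
SAMPL2/Z,all,1.93,1.47,-0.94,1.16,-0.63,0.86
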