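setup,observable,model,rmse,mse,mae,r2,m_prime,b_prime
SAMPL6,logP,1-par,3.40,1.25,2.59,0.52,1.76,1.60
SAMPL6,logP,2-par,4.36,3.38,3.67,0.56,1.65,3.69
SAMPL6,logP,2-par-I,2.33,-0.01,1.76,0.54,1.40,0.18
SAMPL6,logP,3-par,3.18,2.21,2.68,0.57,1.45,2.42
SAMPL6,logD,1-par,3.23,0.59,2.50,0.63,2.02,1.07
SAMPL6,logD,2-par,3.97,2.72,3.40,0.65,1.92,3.15
SAMPL6,logD,2-par-I,2.46,-0.67,1.71,0.67,1.69,-0.35
SAMPL6,logD,3-par,2.88,1.55,2.44,0.66,1.72,1.89
SAMPL5,logP,2-par-I(5),2.33,0.55,1.79,0.55,1.39,0.73
SAMPL5,logP,3-par(5),3.63,2.85,3.10,0.57,1.43,3.04
SAMPL5,logD,2-par-I(5),2.32,-0.37,1.76,0.68,1.69,-0.05
SAMPL5,logD,3-par(5),3.11,1.92,2.74,0.66,1.73,2.27
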