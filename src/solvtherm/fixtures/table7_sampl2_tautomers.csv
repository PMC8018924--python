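reaction_id,compound,group,dG_exp,exp_error,dG:SAMPL2/min,dG:SAMPL2/Z,dG:SAMPL6/Z,dG:SAMPL6/CCSD(T)
1A->1B,1,obscure,-4.8,0.3,-7.73,-7.57,-3.38,-4.52
2A->2B,2,obscure,-6.1,0.3,-9.66,-9.29,-5.40,-6.74
3A->3B,3,obscure,-7.2,0.3,-11.17,-11.12,-7.04,-8.12
4A->4B,4,obscure,-2.3,0.4,-4.57,-4.43,0.96,-0.52
5A->5B,5,obscure,-4.8,0.5,-6.16,-5.83,-3.28,-4.19
5B->5C,5,obscure,0.5,0.2,-0.51,-0.51,1.50,1.25
6A->6B,6,obscure,-9.2,0.4,-11.15,-11.12,-9.05,-9.59
6A->6Z,6,obscure,-2.4,0.3,-6.72,-6.69,-0.43,1.17
7A->7B,7,diketo,7.0,1.5,5.11,4.71,6.50,3.94
8A->8B,8,diketo,-3.0,3.0,-1.01,-1.38,0.38,-2.34
10B->10C,10,explanatory,-2.9,0.4,-2.84,-2.83,0.91,-0.20
10D->10C,10,explanatory,-1.2,0.2,-0.55,-0.45,3.54,2.70
11D->11C,11,explanatory,-0.5,0.2,-0.39,-0.23,3.64,2.96
12D->12C,12,explanatory,-1.8,0.7,-0.79,-0.60,2.73,1.57
13D->13C,13,explanatory,0.1,0.1,0.81,1.09,4.31,3.20
13D->14C,13,explanatory,0.3,0.3,0.16,0.32,1.64,0.84
15A->15B,15,explanatory,0.9,0.3,0.02,0.01,-0.62,2.65
15A->15C,15,explanatory,-1.2,0.3,-1.87,-1.87,0.53,1.18
15B->15C,15,explanatory,-2.2,0.3,-1.88,-1.88,1.15,-1.47
16A->16C,16,explanatory,0.5,0.1,0.56,0.56,1.90,2.46
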