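solvent,model,rmse,mae,mse,m_prime,b_prime,r2,c_mu,c_V,c_q,d
water,All,2.04,1.43,-0.26,1.00,-0.35,1.00,,,,
water,Neutrals,1.56,1.13,-0.36,0.97,-0.47,0.89,,,,
water,Anions,3.07,2.46,0.01,1.10,7.18,0.94,,,,
water,Cations,2.98,2.10,0.02,0.96,-2.62,0.85,,,,
cyclohexane,Uncorrected,5.86,5.60,5.60,0.13,1.53,0.05,,,,
cyclohexane,1-par,1.07,0.86,0.20,0.73,-1.04,0.62,,-0.14923,,
cyclohexane,2-par,0.77,0.58,0.11,0.99,0.06,0.83,2.0184,-0.17795,,
cyclohexane,2-par-I,0.90,0.73,0.00,0.57,-2.00,0.76,,-0.10894,,-1.6593
cyclohexane,2-par-I(5),0.88,0.70,0.00,0.59,-1.94,0.77,,-0.10811,,-1.6566
cyclohexane,3-par,0.68,0.50,0.00,0.84,-0.75,0.83,1.8516,-0.14692,,-1.0842
cyclohexane,3-par(5),0.76,0.56,0.00,0.84,-0.73,0.84,1.8444,-0.14703,,-1.0479
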