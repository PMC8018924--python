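compound_id,batch,logD_exp,logP:2-par-I(5),logP:3-par(5),logP:1-par,logP:2-par,logP:2-par-I,logP:3-par,logD:2-par-I(5),logD:3-par(5),logD:1-par,logD:2-par,logD:2-par-I,logD:3-par,missing_reason
SAMPL5_003,0,1.90,1.17,3.19,2.09,4.22,1.54,3.51,1.17,3.19,2.09,4.22,1.54,3.51,
SAMPL5_015,0,-2.20,-5.28,-2.87,-4.76,-1.92,-4.79,-2.41,-8.08,-5.67,-7.07,-4.23,-7.10,-4.72,
SAMPL5_017,0,2.50,3.39,6.39,3.20,6.14,1.81,4.75,3.39,6.39,3.20,6.14,1.81,4.75,
SAMPL5_020,0,1.60,1.98,3.83,3.83,5.12,2.28,3.91,1.98,3.83,3.83,5.12,2.28,3.91,
SAMPL5_037,0,-1.50,-3.79,-2.31,-3.91,-2.29,-4.27,-2.79,-3.95,-2.47,-4.92,-3.30,-5.27,-3.80,
SAMPL5_045,0,-2.10,-2.42,-0.64,-2.26,-0.22,-2.43,-0.67,-2.42,-0.64,-2.26,-0.22,-2.43,-0.67,
SAMPL5_055,0,-1.50,-3.13,-1.31,-3.91,-1.53,-3.50,-1.65,-3.13,-1.31,-3.91,-1.53,-3.50,-1.65,
SAMPL5_058,0,0.80,-0.83,1.16,0.47,2.64,0.03,2.00,-0.83,1.16,0.47,2.64,0.03,2.00,
SAMPL5_059,0,-1.30,-0.25,1.32,-2.17,-0.17,-1.96,-0.36,-0.25,1.32,-2.17,-0.17,-1.96,-0.36,
SAMPL5_061,0,-1.45,-1.19,0.08,-2.76,-1.37,-3.22,-1.89,-1.91,-0.65,-3.39,-2.00,-3.86,-2.53,
SAMPL5_068,0,1.40,0.95,3.33,0.91,2.99,-0.76,1.57,0.95,3.33,0.91,2.99,-0.76,1.57,
SAMPL5_070,0,1.60,7.32,8.25,8.76,8.52,5.84,6.65,3.56,4.48,6.40,6.16,3.48,4.29,
SAMPL5_080,0,-2.20,-3.42,-0.71,-4.69,-1.21,-4.11,-1.40,-3.42,-0.71,-4.69,-1.21,-4.11,-1.40,
SAMPL5_004,1,2.20,2.60,4.96,3.85,6.12,2.64,4.96,2.60,4.96,3.84,6.12,2.63,4.95,
SAMPL5_005,1,-0.86,-1.44,1.68,-1.17,2.41,-1.54,1.58,-1.44,1.68,-1.18,2.41,-1.54,1.58,
SAMPL5_007,1,1.40,2.91,4.90,3.73,5.59,2.22,4.30,2.91,4.90,3.73,5.59,2.22,4.30,
SAMPL5_010,1,-1.70,-3.45,-1.43,-3.60,-1.38,-4.05,-2.03,-5.88,-3.85,-5.77,-3.55,-6.23,-4.21,
SAMPL5_011,1,-2.96,1.03,3.43,1.36,4.05,0.95,3.34,-1.67,0.74,-2.48,0.21,-2.89,-0.50,
SAMPL5_021,1,1.20,1.22,3.72,-0.28,2.65,-0.48,2.04,1.22,3.72,-0.28,2.65,-0.48,2.04,
SAMPL5_026,1,-2.60,-2.08,-0.82,-0.31,0.77,-1.18,0.02,-5.02,-3.76,-2.82,-1.74,-3.69,-2.49,
SAMPL5_027,1,-1.87,-3.44,-1.16,-4.29,-1.48,-4.12,-1.83,-3.44,-1.16,-4.34,-1.53,-4.17,-1.88,
SAMPL5_042,1,-1.10,0.40,2.63,0.01,2.12,-1.44,0.83,0.40,2.63,0.01,2.12,-1.44,0.83,
SAMPL5_044,1,1.00,-0.74,2.97,1.00,5.21,0.50,4.19,-0.74,2.97,1.00,5.21,0.50,4.19,
SAMPL5_046,1,0.20,0.70,3.38,1.79,4.42,0.53,3.17,0.70,3.38,1.79,4.42,0.53,3.17,
SAMPL5_047,1,-0.40,-0.35,2.53,1.26,4.48,0.79,3.64,-0.35,2.53,1.26,4.48,0.79,3.64,
SAMPL5_048,1,0.90,1.47,5.07,2.08,5.86,1.28,4.74,1.47,5.07,2.08,5.86,1.28,4.74,
SAMPL5_056,1,-2.50,-1.10,1.12,-3.02,-0.63,-3.56,-1.37,-1.10,1.12,-3.63,-1.24,-4.17,-1.98,
SAMPL5_060,1,-3.90,-4.19,-1.79,-4.17,-1.21,-3.99,-1.58,-6.86,-4.45,-6.13,-3.17,-5.95,-3.54,
SAMPL5_063,1,-3.00,-6.93,-5.06,-6.88,-5.15,-7.86,-6.08,-8.77,-6.90,-9.41,-7.68,-10.39,-8.61,
SAMPL5_071,1,-0.10,-0.99,1.02,-1.03,0.61,-2.47,-0.60,-1.02,0.99,-1.04,0.61,-2.48,-0.60,
SAMPL5_072,1,0.60,3.49,4.30,4.53,4.55,2.27,3.09,-0.05,0.76,3.04,3.07,0.78,1.60,
SAMPL5_081,1,-2.20,-6.02,-4.20,-4.41,-2.96,-5.72,-4.05,-7.69,-5.86,-6.68,-5.23,-7.99,-6.32,
SAMPL5_090,1,0.80,2.04,4.46,1.87,3.82,-0.08,2.23,2.04,4.46,1.87,3.82,-0.08,2.23,
SAMPL5_002,2,1.40,2.17,4.35,3.07,5.22,2.06,4.21,2.17,4.35,3.07,5.22,2.06,4.21,
SAMPL5_006,2,-1.02,0.20,1.41,-0.28,0.71,-1.26,-0.09,0.20,1.41,-0.28,0.71,-1.26,-0.09,
SAMPL5_013,2,-1.50,-2.53,1.28,-0.44,3.64,-1.45,2.31,-2.53,1.28,-0.44,3.64,-1.45,2.31,
SAMPL5_019,2,1.20,2.81,5.61,3.74,6.59,2.61,5.38,2.77,5.57,3.74,6.59,2.61,5.38,
SAMPL5_024,2,1.00,3.46,6.75,5.40,8.43,3.51,6.70,3.46,6.75,5.40,8.43,3.51,6.70,
SAMPL5_033,2,1.80,5.06,6.72,9.80,10.24,6.33,7.90,5.06,6.72,9.80,10.24,6.33,7.90,
SAMPL5_049,2,1.30,1.80,3.81,2.50,4.79,2.25,4.25,1.80,3.81,2.50,4.79,2.25,4.25,
SAMPL5_050,2,-3.20,-0.11,2.49,-1.00,2.12,-0.91,1.67,-5.58,-2.98,-4.36,-1.24,-4.27,-1.69,
SAMPL5_065,2,0.70,1.88,7.06,6.16,9.79,0.54,5.53,1.88,7.06,6.16,9.79,0.54,5.53,
SAMPL5_067,2,-1.30,1.40,3.15,3.23,4.54,1.59,3.26,0.17,1.94,3.23,4.54,1.59,3.26,
SAMPL5_069,2,-1.30,2.34,5.18,2.01,4.64,0.28,3.08,0.95,3.79,1.86,4.49,0.13,2.93,
SAMPL5_074,2,-1.90,-6.61,-3.04,-9.85,-5.62,-9.76,-6.25,-6.61,-3.04,-9.85,-5.62,-9.76,-6.26,
SAMPL5_075,2,-2.80,1.35,3.07,1.22,2.46,-0.48,1.15,-0.36,1.37,-1.05,0.18,-2.75,-1.13,
SAMPL5_082,2,2.50,8.17,9.06,12.15,10.96,7.34,8.02,4.94,5.84,9.88,8.69,5.06,5.75,
SAMPL5_083,2,-1.90,,,,,,,,,,,,,MP2 energies could not be calculated
SAMPL5_084,2,0.00,3.79,6.52,4.66,6.42,1.77,4.25,1.25,3.97,3.90,5.67,1.02,3.50,
SAMPL5_085,2,-2.20,-2.33,-0.57,-1.24,0.39,-2.29,-0.56,-8.14,-6.39,-1.24,0.39,-2.29,-0.56,
SAMPL5_086,2,0.70,4.15,6.59,7.23,7.80,3.74,5.52,2.89,5.32,5.58,6.15,2.09,3.87,
SAMPL5_088,2,-1.90,-1.46,-0.62,2.19,2.02,-0.41,0.35,-1.46,-0.62,2.19,2.02,-0.41,0.35,
SAMPL5_092,2,-0.40,-0.71,3.52,2.91,5.61,-1.51,2.33,-0.71,3.52,2.87,5.56,-1.55,2.28,
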