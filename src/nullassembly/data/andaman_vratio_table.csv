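island,richness,observed_v,null_mean,null_var,p_lower,p_upper,ses
South Andaman,14,0.20,0.51,0.26,0.18,0.82,-0.61
North Andaman,12,0.34,0.81,1.68,0.28,0.72,-0.37
Long Island,11,0.24,1.04,2.02,0.07,0.93,-0.56
Neil,11,0.53,1.01,2.23,0.45,0.55,-0.32
Rutland,11,0.27,1.06,2.55,0.10,0.90,-0.50
Camorta,10,2.25,1.49,4.45,0.81,0.19,0.36
Great Nicobar,10,0.35,1.45,4.75,0.16,0.84,-0.51
Havelock,10,0.60,1.48,7.57,0.44,0.56,-0.32
Katchal,9,4.18,2.10,20.27,0.91,0.09,0.46
Car Nicobar,7,3.37,5.30,218.31,0.62,0.38,-0.13
Little Nicobar,7,1.97,5.71,584.77,0.47,0.53,-0.15
Menchal,7,0.25,5.28,169.91,0.03,0.97,-0.39
Nancowry,7,3.02,5.40,243.16,0.60,0.40,-0.15
Tarmugli,7,2.13,5.44,206.44,0.48,0.52,-0.23
Tillanchong,7,3.02,5.80,326.13,0.59,0.41,-0.15
Trinkat,7,3.02,5.63,220.58,0.60,0.40,-0.18
Teressa,7,3.02,5.03,152.10,0.60,0.40,-0.16
Bompoka,7,3.02,5.02,175.84,0.60,0.40,-0.15
Chowra,6,0.17,10.75,1448.80,0.02,0.98,-0.28
Pilo Milo,6,0.33,10.64,1398.70,0.06,0.94,-0.28
Kondul,5,0.15,20.80,9789.50,0.02,0.98,-0.21
Alexandria,4,0.88,61.50,68522.00,0.19,0.81,-0.23
Chester,4,13.23,61.72,73813.00,0.64,0.36,-0.18
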