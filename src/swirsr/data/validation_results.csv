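gel_id,il_pct,mu_s_prime_1450,mu_s_prime_1650,f_w_true,f_w_hat,abs_err_pct
AW70,10,2.085,1.485,0.780,0.754,3.333
AW73.68,10,2.033,1.683,0.817,0.800,2.081
AW75,10,1.959,1.810,0.830,0.824,0.723
AW80,10,2.108,1.629,0.880,0.851,3.295
AW62,20,3.959,2.933,0.780,0.771,1.154
AW65.68,20,4.165,2.925,0.817,0.811,0.734
AW67,20,4.247,3.093,0.830,0.823,0.843
AW72,20,4.497,3.491,0.880,0.882,0.227
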